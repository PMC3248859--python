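"""Contig-graph data model and readers/writers.

The central container is :class:`ContigGraph`: nodes are assembled contigs
(length, mean read depth, optional sequence), edges join contig *ends*
(5' or 3') and carry the number of spanning reads that support the join,
plus an optional one-base gap observed at the junction.

Supported formats:

* GFA 1 (``S``/``L`` records; per-contig depth in a ``DP:f:`` tag,
  spanning-read support in ``RC:i:``) — read and write.
* A tab-separated "AllContigGraph" dialect as emitted alongside 454/Newbler
  assemblies (``C`` rows for contigs, ``L``/``I`` rows for links) — read only.
* FASTA for contig sequences (attached onto an existing graph).
* A TSV table of candidate mate-pair links flanking repetitive contigs.

Edges are stored unordered: the edge joining end X of contig a to end Y of
contig b is identical to its reverse. Orientation is a property of walks,
not of storage.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .seqs import normalize

logger = logging.getLogger(__name__)

__all__ = [
    "End",
    "EndRef",
    "ContigNode",
    "ContigEdge",
    "ContigGraph",
    "LinkRecord",
    "LinkTable",
    "StatsRecord",
    "read_gfa",
    "write_gfa",
    "read_454_graph",
    "read_link_table",
    "attach_sequences",
    "graph_stats",
]


class End(str, Enum):
    """One of the two ends of a contig."""

    FIVE_PRIME = "5"
    THREE_PRIME = "3"

    @property
    def other(self) -> "End":
        return End.THREE_PRIME if self is End.FIVE_PRIME else End.FIVE_PRIME


@dataclass(frozen=True, order=True)
class EndRef:
    """A reference to a specific end of a specific contig."""

    contig_id: str
    end: End


@dataclass
class ContigNode:
    contig_id: str
    length: int
    read_depth: float
    sequence: str | None = None
    num_reads: int | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.contig_id}: length must be >= 1")
        if not self.read_depth > 0:
            raise ValueError(f"contig {self.contig_id}: read_depth must be > 0")
        if self.sequence is not None:
            self.sequence = normalize(self.sequence, context=f"contig {self.contig_id}")
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"contig {self.contig_id}: sequence length {len(self.sequence)} "
                    f"does not match stated length {self.length}"
                )
        if self.num_reads is not None and self.num_reads < 0:
            raise ValueError(f"contig {self.contig_id}: num_reads must be >= 0")


EdgeKey = tuple[tuple[str, End], tuple[str, End]]


@dataclass
class ContigEdge:
    """An unordered join between two contig ends.

    ``gap`` bases (``gap_base`` when gap == 1) are inserted between the two
    contigs when the join is traversed; most Newbler-style joins are
    zero-gap.
    """

    a: EndRef
    b: EndRef
    support: int = 0
    gap: int = 0
    gap_base: str | None = None

    def __post_init__(self) -> None:
        if self.support < 0:
            raise ValueError("edge support must be >= 0")
        if self.gap < 0:
            raise ValueError("edge gap must be >= 0")
        if (self.gap_base is not None) != (self.gap >= 1):
            raise ValueError("gap_base must be present iff gap >= 1")
        if self.gap_base is not None:
            self.gap_base = normalize(self.gap_base, context="gap base")
            if len(self.gap_base) != 1:
                raise ValueError("gap_base must be a single nucleotide")

    @property
    def key(self) -> EdgeKey:
        pair = sorted(
            [(self.a.contig_id, self.a.end), (self.b.contig_id, self.b.end)]
        )
        return (pair[0], pair[1])

    def other(self, ref: EndRef) -> EndRef:
        if ref == self.a:
            return self.b
        if ref == self.b:
            return self.a
        raise KeyError(f"{ref} is not an endpoint of this edge")

    def touches(self, ref: EndRef) -> bool:
        return ref in (self.a, self.b)


class ContigGraph:
    """Contigs as nodes, spanning reads between contig ends as edges."""

    def __init__(self) -> None:
        self.nodes: dict[str, ContigNode] = {}
        self._edges: dict[EdgeKey, ContigEdge] = {}

    # -- construction -------------------------------------------------------

    def add_node(self, node: ContigNode) -> None:
        if node.contig_id in self.nodes:
            raise ValueError(f"duplicate contig id {node.contig_id!r}")
        self.nodes[node.contig_id] = node

    def add_edge(self, edge: ContigEdge, *, merge: bool = True) -> None:
        for ref in (edge.a, edge.b):
            if ref.contig_id not in self.nodes:
                raise KeyError(
                    f"edge endpoint {ref.contig_id!r} is not a node of the graph"
                )
        key = edge.key
        if key in self._edges:
            if not merge:
                raise ValueError(f"duplicate edge {key}")
            self._edges[key].support += edge.support
        else:
            self._edges[key] = edge

    def remove_node(self, contig_id: str) -> None:
        del self.nodes[contig_id]
        for key in [k for k in self._edges if contig_id in (k[0][0], k[1][0])]:
            del self._edges[key]

    def remove_edge(self, key: EdgeKey) -> None:
        del self._edges[key]

    # -- queries ------------------------------------------------------------

    @property
    def edges(self) -> list[ContigEdge]:
        return [self._edges[k] for k in sorted(self._edges)]

    def find_edge(self, a: EndRef, b: EndRef) -> ContigEdge | None:
        return self._edges.get(ContigEdge(a=a, b=b).key)

    def edges_at(self, ref: EndRef) -> list[ContigEdge]:
        return [e for e in self.edges if e.touches(ref)]

    def degree(self, ref: EndRef) -> int:
        return len(self.edges_at(ref))

    def subgraph(self, contig_ids: Iterable[str]) -> "ContigGraph":
        keep = set(contig_ids)
        missing = keep - set(self.nodes)
        if missing:
            raise KeyError(f"contigs not in graph: {sorted(missing)}")
        sub = ContigGraph()
        for cid in sorted(keep):
            sub.add_node(replace(self.nodes[cid]))
        for edge in self.edges:
            if edge.a.contig_id in keep and edge.b.contig_id in keep:
                sub.add_edge(replace(edge), merge=False)
        return sub

    def copy(self) -> "ContigGraph":
        return self.subgraph(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContigGraph):
            return NotImplemented
        if set(self.nodes) != set(other.nodes):
            return False
        for cid, node in self.nodes.items():
            o = other.nodes[cid]
            if (node.length, node.sequence, node.num_reads) != (
                o.length,
                o.sequence,
                o.num_reads,
            ) or not math.isclose(node.read_depth, o.read_depth, rel_tol=1e-9):
                return False
        if set(self._edges) != set(other._edges):
            return False
        for key, edge in self._edges.items():
            o = other._edges[key]
            if (edge.support, edge.gap, edge.gap_base) != (o.support, o.gap, o.gap_base):
                return False
        return True

    def validate(self) -> None:
        for edge in self.edges:
            for ref in (edge.a, edge.b):
                if ref.contig_id not in self.nodes:
                    raise ValueError(f"edge endpoint {ref} has no node")


# ---------------------------------------------------------------------------
# GFA 1
# ---------------------------------------------------------------------------

_ORIENT_TO_END_SOURCE = {"+": End.THREE_PRIME, "-": End.FIVE_PRIME}
_ORIENT_TO_END_TARGET = {"+": End.FIVE_PRIME, "-": End.THREE_PRIME}


def _parse_tags(fields: Sequence[str], lineno: int) -> dict[str, str]:
    tags: dict[str, str] = {}
    for raw in fields:
        parts = raw.split(":", 2)
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: malformed GFA tag {raw!r}")
        tags[parts[0]] = parts[2]
    return tags


def read_gfa(path: str | Path) -> ContigGraph:
    """Read a GFA 1 file into a :class:`ContigGraph`.

    Depth must be present as a ``DP:f:`` tag on every ``S`` record; contig
    length comes from the sequence or from an ``LN:i:`` tag when the sequence
    is ``*``. ``L``-record orientations are mapped onto contig ends: the
    ``+`` orientation of the source contributes its 3' end, the ``+``
    orientation of the target its 5' end (both flipped for ``-``).
    """
    path = Path(path)
    graph = ContigGraph()
    pending_links: list[tuple[int, list[str]]] = []
    n_lines = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            n_lines += 1
            fields = line.split("\t")
            rec = fields[0]
            if rec == "S":
                if len(fields) < 3:
                    raise ValueError(f"line {lineno}: truncated S record")
                name, seq = fields[1], fields[2]
                tags = _parse_tags(fields[3:], lineno)
                if "DP" not in tags:
                    raise ValueError(
                        f"line {lineno}: segment {name!r} has no DP depth tag"
                    )
                depth = float(tags["DP"])
                sequence = None if seq == "*" else seq
                if sequence is not None:
                    length = len(sequence)
                elif "LN" in tags:
                    length = int(tags["LN"])
                else:
                    raise ValueError(
                        f"line {lineno}: segment {name!r} has neither sequence nor LN tag"
                    )
                num_reads = int(tags["RC"]) if "RC" in tags else None
                graph.add_node(
                    ContigNode(
                        contig_id=name,
                        length=length,
                        read_depth=depth,
                        sequence=sequence,
                        num_reads=num_reads,
                    )
                )
            elif rec == "L":
                pending_links.append((lineno, fields))
    if n_lines == 0:
        raise ValueError(f"{path}: empty GFA file")
    for lineno, fields in pending_links:
        if len(fields) < 6:
            raise ValueError(f"line {lineno}: truncated L record")
        src, src_o, dst, dst_o = fields[1], fields[2], fields[3], fields[4]
        for name in (src, dst):
            if name not in graph.nodes:
                raise ValueError(
                    f"line {lineno}: L record references unknown segment {name!r}"
                )
        tags = _parse_tags(fields[6:], lineno)
        support = int(tags.get("RC", "0"))
        gap = int(tags.get("gp", "0"))
        gap_base = tags.get("gb")
        graph.add_edge(
            ContigEdge(
                a=EndRef(src, _ORIENT_TO_END_SOURCE[src_o]),
                b=EndRef(dst, _ORIENT_TO_END_TARGET[dst_o]),
                support=support,
                gap=gap,
                gap_base=gap_base,
            )
        )
    return graph


def write_gfa(graph: ContigGraph, path: str | Path) -> None:
    """Write GFA 1 with deterministic record order (sorted ids, then edges)."""
    graph.validate()
    path = Path(path)
    lines = ["H\tVN:Z:1.0"]
    for cid in sorted(graph.nodes):
        node = graph.nodes[cid]
        seq = node.sequence if node.sequence is not None else "*"
        tags = [f"LN:i:{node.length}", f"DP:f:{node.read_depth:g}"]
        if node.num_reads is not None:
            tags.append(f"RC:i:{node.num_reads}")
        lines.append("\t".join(["S", cid, seq, *tags]))
    for edge in graph.edges:
        (a_id, a_end), (b_id, b_end) = edge.key
        src_o = "+" if a_end is End.THREE_PRIME else "-"
        dst_o = "+" if b_end is End.FIVE_PRIME else "-"
        tags = [f"RC:i:{edge.support}"]
        if edge.gap:
            tags.append(f"gp:i:{edge.gap}")
            tags.append(f"gb:Z:{edge.gap_base}")
        lines.append("\t".join(["L", a_id, src_o, b_id, dst_o, "0M", *tags]))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# 454/Newbler "AllContigGraph" dialect
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dialect454:
    """Column layout of the tab-separated contig-graph dialect.

    The vendor format is not publicly specified, so the layout is
    table-driven: remap the column indices here if your file differs.
    Contig rows (``contig_code``): index, contig id, length, mean depth.
    Link rows (``link_codes``): contig id, end letter (5/3), contig id,
    end letter, spanning-read count.
    """

    contig_code: str = "C"
    link_codes: tuple[str, ...] = ("L", "I")
    contig_id_col: int = 2
    contig_len_col: int = 3
    contig_depth_col: int = 4
    link_a_col: int = 1
    link_a_end_col: int = 2
    link_b_col: int = 3
    link_b_end_col: int = 4
    link_support_col: int = 5


_END_LETTER = {"5": End.FIVE_PRIME, "3": End.THREE_PRIME}


def read_454_graph(
    path: str | Path, dialect: Dialect454 | None = None
) -> ContigGraph:
    """Read the tab-separated AllContigGraph dialect.

    Unknown record types are skipped with a logged warning and counted in
    the log; malformed contig or link rows raise with their line number.
    """
    dialect = dialect or Dialect454()
    path = Path(path)
    graph = ContigGraph()
    links: list[tuple[int, list[str]]] = []
    skipped = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            code = fields[0]
            if code == dialect.contig_code:
                try:
                    cid = fields[dialect.contig_id_col]
                    length = int(fields[dialect.contig_len_col])
                    depth = float(fields[dialect.contig_depth_col])
                except (IndexError, ValueError) as exc:
                    raise ValueError(
                        f"{path} line {lineno}: malformed contig row ({exc})"
                    ) from exc
                graph.add_node(ContigNode(contig_id=cid, length=length, read_depth=depth))
            elif code in dialect.link_codes:
                links.append((lineno, fields))
            else:
                skipped += 1
                logger.warning("%s line %d: skipping unrecognized record type %r", path, lineno, code)
    for lineno, fields in links:
        try:
            a_id = fields[dialect.link_a_col]
            a_end = _END_LETTER[fields[dialect.link_a_end_col]]
            b_id = fields[dialect.link_b_col]
            b_end = _END_LETTER[fields[dialect.link_b_end_col]]
            support = int(fields[dialect.link_support_col])
        except (IndexError, KeyError, ValueError) as exc:
            raise ValueError(f"{path} line {lineno}: malformed link row ({exc})") from exc
        for name in (a_id, b_id):
            if name not in graph.nodes:
                raise ValueError(
                    f"{path} line {lineno}: link references absent contig {name!r}"
                )
        graph.add_edge(
            ContigEdge(a=EndRef(a_id, a_end), b=EndRef(b_id, b_end), support=support)
        )
    if skipped:
        logger.warning("%s: skipped %d unrecognized line(s)", path, skipped)
    if not graph.nodes:
        raise ValueError(f"{path}: no contig rows found")
    return graph


# ---------------------------------------------------------------------------
# Mate-pair candidate link table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinkRecord:
    """One candidate mate-pair pairing of the two flanks of a repeat."""

    repeat_id: str
    five_prime_contig: str
    three_prime_contig: str
    link_count: int

    def __post_init__(self) -> None:
        if self.link_count < 0:
            raise ValueError("link_count must be >= 0")

    @property
    def flanks(self) -> frozenset[str]:
        return frozenset((self.five_prime_contig, self.three_prime_contig))


class LinkTable(list):
    """Ordered collection of :class:`LinkRecord` with grouping helpers."""

    def by_repeat(self) -> dict[str, list[LinkRecord]]:
        groups: dict[str, list[LinkRecord]] = {}
        for rec in self:
            groups.setdefault(rec.repeat_id, []).append(rec)
        return groups


def read_link_table(path: str | Path) -> LinkTable:
    """Read a TSV of candidate mate-pair links.

    Columns: repeat id, link count, 5'-flank contig, 3'-flank contig. A
    header row is detected and skipped if the second column is not an
    integer. A blank repeat-id field inherits the last non-blank value,
    matching the layout of published link tables where the repeat name is
    printed only on its first row.
    """
    path = Path(path)
    table = LinkTable()
    seen: set[tuple[str, str, str]] = set()
    current_repeat: str | None = None
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) < 4:
                raise ValueError(f"{path} line {lineno}: expected 4 columns, got {len(row)}")
            rid, count_s, five, three = (f.strip() for f in row[:4])
            if lineno == 1:
                try:
                    int(count_s)
                except ValueError:
                    continue  # header row
            try:
                count = int(count_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path} line {lineno}: non-integer link count {count_s!r}"
                ) from exc
            if count < 0:
                raise ValueError(f"{path} line {lineno}: negative link count {count}")
            if rid:
                current_repeat = rid
            elif current_repeat is None:
                raise ValueError(f"{path} line {lineno}: first row has blank repeat id")
            triple = (current_repeat, five, three)
            if triple in seen:
                raise ValueError(f"{path} line {lineno}: duplicate link row {triple}")
            seen.add(triple)
            table.append(
                LinkRecord(
                    repeat_id=current_repeat,
                    five_prime_contig=five,
                    three_prime_contig=three,
                    link_count=count,
                )
            )
    return table


# ---------------------------------------------------------------------------
# Sequences and statistics
# ---------------------------------------------------------------------------


def attach_sequences(graph: ContigGraph, fasta_path: str | Path) -> ContigGraph:
    """Attach FASTA sequences onto graph nodes (matched by record id).

    FASTA records without a matching contig are skipped with a warning;
    graph contigs without a record keep an absent sequence. A sequence
    whose length conflicts with the node's stated length raises.
    """
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        node = graph.nodes.get(record.id)
        if node is None:
            logger.warning("FASTA record %r has no matching contig; skipped", record.id)
            continue
        seq = normalize(str(record.seq), context=f"contig {record.id}")
        if len(seq) != node.length:
            raise ValueError(
                f"contig {record.id}: FASTA sequence length {len(seq)} "
                f"conflicts with stated length {node.length}"
            )
        node.sequence = seq
    return graph


@dataclass(frozen=True)
class StatsRecord:
    n_contigs: int
    total_bp: int
    n50: int


def graph_stats(
    contigs: Iterable[ContigNode],
    *,
    count_repeats_once: bool = True,
    multiplicity: Mapping[str, int] | None = None,
) -> StatsRecord:
    """Contig count, total bases, and N50.

    With ``count_repeats_once`` (the convention used when a collapsed repeat
    contig stands for several copies) each contig's length is counted once;
    otherwise, when ``multiplicity`` is given, each length is counted that
    many times. N50 is the smallest length L such that contigs of length
    >= L together hold at least half of the total bases.
    """
    contigs = list(contigs)
    if not contigs:
        raise ValueError("cannot compute stats of an empty contig collection")
    lengths: list[int] = []
    for node in contigs:
        copies = 1
        if not count_repeats_once and multiplicity is not None:
            copies = int(multiplicity.get(node.contig_id, 1))
        lengths.extend([node.length] * copies)
    arr = np.sort(np.asarray(lengths))[::-1]
    total = int(arr.sum())
    cum = np.cumsum(arr)
    idx = int(np.searchsorted(cum, total / 2.0))
    return StatsRecord(n_contigs=len(lengths), total_bp=total, n50=int(arr[idx]))
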