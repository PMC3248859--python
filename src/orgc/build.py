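"""Sequence reconstruction and assembly reporting.

Once the circular walk is fixed, the genome sequence is the concatenation
of the oriented contig sequences (reverse-complemented for REVERSE steps)
with an optional single gap/insert base at a join; almost all joins in a
Newbler-style contig graph are zero-gap. Circular sequences are compared
in canonical form: the lexicographically smallest string over all
rotations of the sequence and of its reverse complement, which is
invariant to the arbitrary origin and strand of a circular assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .circle import CirclePath, Orientation, StructureAnnotation, _entry_end, _exit_end
from .graphio import ContigGraph, EndRef, StatsRecord, graph_stats
from .seqs import normalize, revcomp, rotate

__all__ = [
    "AssemblyReport",
    "reconstruct_sequence",
    "canonical_form",
    "gc_content",
    "assembly_report",
]

GapPolicy = Mapping[frozenset, str]


def _join_edges(graph: ContigGraph, circle: CirclePath):
    """Yield (edge, previous step, next step) around the closed walk."""
    steps = circle.steps
    n = len(steps)
    for i in range(n):
        cid, orient = steps[i]
        nid, norient = steps[(i + 1) % n]
        a = EndRef(cid, _exit_end(orient))
        b = EndRef(nid, _entry_end(norient))
        edge = graph.find_edge(a, b)
        if edge is None:
            raise ValueError(
                f"circle step {i}: no edge joins {cid}({orient.value}) to "
                f"{nid}({norient.value})"
            )
        yield edge, steps[i], steps[(i + 1) % n]


def reconstruct_sequence(
    graph: ContigGraph,
    circle: CirclePath,
    gap_policy: GapPolicy | None = None,
) -> str:
    """Concatenate oriented contig sequences around the circle.

    ``gap_policy`` maps an unordered contig pair ``frozenset({a, b})`` to a
    single base inserted at that join; joins without a policy entry use the
    edge's own recorded gap base, or no gap at all. Keys that do not
    correspond to a join of the circle raise.
    """
    if not circle.closed:
        raise ValueError("cannot reconstruct a sequence from an open walk")
    gap_policy = dict(gap_policy or {})
    joins = {frozenset({a[0], b[0]}) for _, a, b in _join_edges(graph, circle)}
    stray = set(gap_policy) - joins
    if stray:
        raise ValueError(f"gap policy references non-circle joins: {sorted(map(sorted, stray))}")
    parts: list[str] = []
    for edge, (cid, orient), (nid, _) in _join_edges(graph, circle):
        node = graph.nodes[cid]
        if node.sequence is None:
            raise ValueError(f"contig {cid} carries no sequence")
        seq = node.sequence if orient is Orientation.FORWARD else revcomp(node.sequence)
        parts.append(seq)
        pair = frozenset({cid, nid})
        if pair in gap_policy:
            parts.append(normalize(gap_policy[pair], context="gap base"))
        elif edge.gap_base is not None:
            parts.append(edge.gap_base)
    return "".join(parts)


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation."""
    n = len(s)
    s2 = s + s
    f = [-1] * len(s2)
    k = 0
    for j in range(1, len(s2)):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_form(sequence: str) -> str:
    """Canonical representative of a circular sequence.

    The lexicographically smallest string among all rotations of the
    sequence and all rotations of its reverse complement; idempotent and
    invariant under rotation and reverse complement.
    """
    if not sequence:
        raise ValueError("empty sequence has no canonical form")
    s = normalize(sequence)
    r = revcomp(s)
    return min(rotate(s, _least_rotation(s)), rotate(r, _least_rotation(r)))


def gc_content(sequence: str) -> float:
    """GC percentage over A/C/G/T (N excluded from the denominator)."""
    if not sequence:
        raise ValueError("empty sequence")
    s = normalize(sequence)
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence contains only N; GC content undefined")
    return 100.0 * (s.count("G") + s.count("C")) / acgt


@dataclass
class AssemblyReport:
    genome_length: int
    gc_percent: float  # rounded to 2 decimals for reporting
    n_contigs: int  # distinct contigs (repeats counted once)
    n_traversals: int  # circle steps (repeats counted per traversal)
    n50: int
    total_contig_bp: int  # repeats counted once
    structure: StructureAnnotation | None
    gaps_filled: list[tuple[str, str, str]]  # (contig a, contig b, base)


def assembly_report(
    sequence: str,
    circle: CirclePath,
    graph: ContigGraph,
    annotation: StructureAnnotation | None = None,
    gap_policy: GapPolicy | None = None,
) -> AssemblyReport:
    """Assembly summary: length, GC%, contig stats and filled gaps.

    Contig statistics follow the convention of counting a collapsed repeat
    contig once; the per-traversal step count is reported separately.
    """
    missing = [cid for cid, _ in circle.steps if cid not in graph.nodes]
    if missing:
        raise ValueError(f"circle steps not in graph: {sorted(set(missing))}")
    gap_policy = dict(gap_policy or {})
    gaps: list[tuple[str, str, str]] = []
    oriented_bp = 0
    for edge, (cid, _), (nid, _) in _join_edges(graph, circle):
        oriented_bp += graph.nodes[cid].length
        pair = frozenset({cid, nid})
        if pair in gap_policy:
            gaps.append((cid, nid, gap_policy[pair]))
        elif edge.gap_base is not None:
            gaps.append((cid, nid, edge.gap_base))
    if len(sequence) != oriented_bp + len(gaps):
        raise ValueError(
            f"sequence length {len(sequence)} does not equal traversed contig "
            f"bases {oriented_bp} plus {len(gaps)} gap base(s)"
        )
    distinct = sorted(circle.multiplicity)
    stats: StatsRecord = graph_stats(
        (graph.nodes[c] for c in distinct), count_repeats_once=True
    )
    return AssemblyReport(
        genome_length=len(sequence),
        gc_percent=round(gc_content(sequence), 2),
        n_contigs=stats.n_contigs,
        n_traversals=len(circle.steps),
        n50=stats.n50,
        total_contig_bp=stats.total_bp,
        structure=annotation,
        gaps_filled=gaps,
    )
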