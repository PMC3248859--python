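"""Circularization: closed walks, quadripartite structure, repeat resolution.

A finished organellar genome is a single closed walk over the pruned
contig graph in which each contig is traversed as many times as its copy
number (collapsed repeats are traversed multiply). The walk search is
exhaustive backtracking — pruned organellar graphs are small (tens of
nodes) — and reports all solutions up to rotation and full reversal.

For plastids, the multiplicity-2 contigs of the walk form the inverted
repeat, and the two single-copy arcs between its two traversals are the
large and small single-copy regions (LSC/SSC).

When dispersed mitochondrial repeats make the walk ambiguous, candidate
mate-pair links between the repeat's flanking contigs decide the traversal:
per repeat, the set of flank pairings with the largest total mate-pair
support, covering each flank exactly once (a maximum-weight perfect
matching), are the *major links*; the rest are minor links and are
reported but never assembled. Wiring each repeat copy between its major
flank pair yields the master circle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .classify import DepthPartition, Label, flag_repeats
from .graphio import (
    ContigEdge,
    ContigGraph,
    End,
    EndRef,
    LinkRecord,
    LinkTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Orientation",
    "CirclePath",
    "Region",
    "StructureAnnotation",
    "RepeatLinkChoice",
    "MajorLinkSelection",
    "infer_multiplicity",
    "find_circular_path",
    "annotate_quadripartite",
    "select_major_links",
    "apply_major_links",
]

DEFAULT_MAX_SOLUTIONS = 16


class Orientation(str, Enum):
    FORWARD = "+"
    REVERSE = "-"

    @property
    def other(self) -> "Orientation":
        return Orientation.REVERSE if self is Orientation.FORWARD else Orientation.FORWARD


Step = tuple[str, Orientation]


def _entry_end(orient: Orientation) -> End:
    return End.FIVE_PRIME if orient is Orientation.FORWARD else End.THREE_PRIME


def _exit_end(orient: Orientation) -> End:
    return _entry_end(orient).other


@dataclass
class CirclePath:
    """An ordered, oriented closed walk over contigs."""

    steps: list[Step]
    closed: bool = True
    multiplicity: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.multiplicity:
            counts: dict[str, int] = {}
            for cid, _ in self.steps:
                counts[cid] = counts.get(cid, 0) + 1
            self.multiplicity = counts

    def canonical_steps(self) -> tuple[Step, ...]:
        """Lexicographically minimal representative over rotations/reversal."""
        return canonical_walk(self.steps)

    def __len__(self) -> int:
        return len(self.steps)


def _reverse_walk(steps: Sequence[Step]) -> list[Step]:
    return [(cid, o.other) for cid, o in reversed(steps)]


def canonical_walk(steps: Sequence[Step]) -> tuple[Step, ...]:
    n = len(steps)
    candidates: list[tuple[tuple[str, str], ...]] = []
    for variant in (list(steps), _reverse_walk(steps)):
        for k in range(n):
            rot = variant[k:] + variant[:k]
            candidates.append(tuple((c, o.value) for c, o in rot))
    best = min(candidates)
    return tuple((c, Orientation(o)) for c, o in best)


# ---------------------------------------------------------------------------
# Multiplicity on the pruned graph
# ---------------------------------------------------------------------------


def infer_multiplicity(graph: ContigGraph, tolerance: float = 0.35) -> dict[str, int]:
    """Copy number per contig of a pruned single-class graph.

    Re-runs depth-multiple repeat flagging with every contig treated as one
    class; unflagged contigs get multiplicity 1.
    """
    labels = {cid: Label.MT for cid in graph.nodes}
    partition = DepthPartition(t_low=0.0, t_high=float("inf"), labels=labels)
    flagged = flag_repeats(graph, partition, Label.MT, tolerance=tolerance)
    return {cid: flagged.get(cid, 1) for cid in graph.nodes}


# ---------------------------------------------------------------------------
# Closed-walk search
# ---------------------------------------------------------------------------


def find_circular_path(
    graph: ContigGraph,
    multiplicity: Mapping[str, int],
    max_solutions: int = DEFAULT_MAX_SOLUTIONS,
) -> list[CirclePath]:
    """All closed walks traversing each contig ``multiplicity`` times.

    Walks must use every edge of the graph at least once; solutions are
    deduplicated up to rotation and full reversal and returned sorted by
    canonical step sequence. When more than ``max_solutions`` distinct
    walks exist the search stops at that many with a warning — such
    ambiguity is resolved with mate-pair links, not by guessing.
    """
    if not graph.nodes:
        raise ValueError("empty graph has no circular path")
    mult = {cid: int(multiplicity.get(cid, 1)) for cid in graph.nodes}
    violations = []
    for cid in sorted(graph.nodes):
        for end in (End.FIVE_PRIME, End.THREE_PRIME):
            deg = graph.degree(EndRef(cid, end))
            if deg == 0:
                violations.append(f"{cid} {end.name}: no edges (degree 0)")
            elif deg > mult[cid]:
                violations.append(
                    f"{cid} {end.name}: degree {deg} exceeds multiplicity {mult[cid]}"
                )
    if violations:
        raise ValueError(
            "no closed walk exists; end-degree violations:\n  " + "\n  ".join(violations)
        )

    edge_keys = [e.key for e in graph.edges]
    edge_index = {k: i for i, k in enumerate(edge_keys)}
    n_steps_total = sum(mult.values())
    start = min(graph.nodes)
    start_entry = EndRef(start, End.FIVE_PRIME)

    solutions: dict[tuple[Step, ...], list[Step]] = {}
    capped = False

    remaining = dict(mult)
    edge_used = [0] * len(edge_keys)

    def backtrack(current_exit: EndRef, steps: list[Step]) -> None:
        nonlocal capped
        if capped:
            return
        if len(steps) == n_steps_total:
            closing = graph.find_edge(current_exit, start_entry)
            if closing is None:
                return
            i = edge_index[closing.key]
            edge_used[i] += 1
            if all(u > 0 for u in edge_used):
                key = canonical_walk(steps)
                if key not in solutions:
                    solutions[key] = list(steps)
                    if len(solutions) >= max_solutions:
                        capped = True
            edge_used[i] -= 1
            return
        for edge in graph.edges_at(current_exit):
            arrival = edge.other(current_exit)
            cid = arrival.contig_id
            if remaining[cid] <= 0:
                continue
            orient = (
                Orientation.FORWARD
                if arrival.end is End.FIVE_PRIME
                else Orientation.REVERSE
            )
            i = edge_index[edge.key]
            remaining[cid] -= 1
            edge_used[i] += 1
            steps.append((cid, orient))
            backtrack(EndRef(cid, arrival.end.other), steps)
            steps.pop()
            edge_used[i] -= 1
            remaining[cid] += 1

    remaining[start] -= 1
    backtrack(EndRef(start, End.THREE_PRIME), [(start, Orientation.FORWARD)])
    remaining[start] += 1

    if capped:
        warnings.warn(
            f"walk search stopped at {max_solutions} distinct circles; "
            "resolve the ambiguity with mate-pair links",
            stacklevel=2,
        )
    if not solutions:
        raise ValueError(
            "no closed walk exists that traverses every contig to its multiplicity "
            "and uses every edge"
        )
    return [
        CirclePath(steps=list(solutions[k]), multiplicity=dict(mult))
        for k in sorted(solutions)
    ]


# ---------------------------------------------------------------------------
# Quadripartite annotation
# ---------------------------------------------------------------------------


class Region(str, Enum):
    LSC = "LSC"
    SSC = "SSC"
    IRA = "IRa"
    IRB = "IRb"


@dataclass
class StructureAnnotation:
    """LSC / IRa / SSC / IRb segmentation of a plastid circle."""

    segments: list[tuple[Region, list[int]]]  # region -> step indices
    lsc_len: int
    ssc_len: int
    ir_len: int


def _circular_runs(indices: set[int], n: int) -> list[list[int]]:
    """Maximal runs of consecutive indices on a circle of size ``n``."""
    if not indices:
        return []
    if len(indices) == n:
        return [list(range(n))]
    runs: list[list[int]] = []
    # find a position not in the set to anchor the scan
    anchor = next(i for i in range(n) if i not in indices)
    run: list[int] = []
    for off in range(1, n + 1):
        i = (anchor + off) % n
        if i in indices:
            run.append(i)
        elif run:
            runs.append(run)
            run = []
    if run:
        runs.append(run)
    return runs


def annotate_quadripartite(
    circle: CirclePath, multiplicity: Mapping[str, int], graph: ContigGraph
) -> StructureAnnotation:
    """Annotate a plastid circle with its quadripartite structure.

    The contigs of multiplicity 2 are traversed twice and form the
    inverted repeat (the two traversals are IRa and IRb, in opposite
    relative orientation); of the two single-copy arcs between them the
    longer is the LSC and the shorter the SSC. Without any multiplicity-2
    contig the annotation degenerates to one LSC segment with a warning.
    """
    if not circle.closed:
        raise ValueError("circle must be closed")
    steps = circle.steps
    n = len(steps)
    rep_idx = {i for i, (c, _) in enumerate(steps) if multiplicity.get(c, 1) >= 2}
    if not rep_idx:
        warnings.warn("no multiplicity-2 contig: annotating a single LSC segment", stacklevel=2)
        lsc_len = sum(graph.nodes[c].length for c, _ in steps)
        return StructureAnnotation(
            segments=[(Region.LSC, list(range(n)))],
            lsc_len=lsc_len,
            ssc_len=0,
            ir_len=0,
        )
    runs = _circular_runs(rep_idx, n)
    if len(runs) != 2:
        raise ValueError(
            f"{len(runs)} separate repeat runs in the circle; this is not a "
            "simple quadripartite plastid - resolve the repeats with mate-pair "
            "links instead"
        )
    run_a, run_b = runs
    set_a = {steps[i][0] for i in run_a}
    set_b = {steps[i][0] for i in run_b}
    if set_a != set_b:
        raise ValueError("the two repeat runs traverse different contig sets")
    ir_len = sum(graph.nodes[steps[i][0]].length for i in run_a)

    def arc_between(end_run: list[int], start_run: list[int]) -> list[int]:
        arc = []
        i = (end_run[-1] + 1) % n
        while i != start_run[0]:
            arc.append(i)
            i = (i + 1) % n
        return arc

    arc1 = arc_between(run_a, run_b)  # traversed after run_a
    arc2 = arc_between(run_b, run_a)
    len1 = sum(graph.nodes[steps[i][0]].length for i in arc1)
    len2 = sum(graph.nodes[steps[i][0]].length for i in arc2)
    if len1 > len2:
        lsc, ssc, lsc_len, ssc_len = arc1, arc2, len1, len2
        ira, irb = run_b, run_a
    elif len2 > len1:
        lsc, ssc, lsc_len, ssc_len = arc2, arc1, len2, len1
        ira, irb = run_a, run_b
    else:
        # equal arcs: the first-traversed arc is called LSC
        logger.info("LSC and SSC arcs have equal length; labelling the first-traversed arc LSC")
        first = arc1 if (arc1 and (not arc2 or min(arc1) < min(arc2))) else arc2
        lsc, ssc = (arc1, arc2) if first is arc1 else (arc2, arc1)
        lsc_len = ssc_len = len1
        ira, irb = (run_b, run_a) if first is arc1 else (run_a, run_b)
    # order segments in traversal order starting at the LSC
    segments = [
        (Region.LSC, lsc),
        (Region.IRA, ira),
        (Region.SSC, ssc),
        (Region.IRB, irb),
    ]
    return StructureAnnotation(
        segments=segments, lsc_len=lsc_len, ssc_len=ssc_len, ir_len=ir_len
    )


# ---------------------------------------------------------------------------
# Major / minor mate-pair links
# ---------------------------------------------------------------------------


@dataclass
class RepeatLinkChoice:
    selected: list[LinkRecord]
    rejected: list[LinkRecord]
    total_support: int


@dataclass
class MajorLinkSelection:
    per_repeat: dict[str, RepeatLinkChoice]

    def __getitem__(self, repeat_id: str) -> RepeatLinkChoice:
        return self.per_repeat[repeat_id]

    def __iter__(self):
        return iter(self.per_repeat)


def _perfect_matchings(
    rows: Sequence[LinkRecord], flanks: frozenset[str]
) -> Iterable[tuple[LinkRecord, ...]]:
    """Every set of rows covering each flanking contig exactly once."""
    if not flanks:
        yield ()
        return
    pivot = min(flanks)
    for i, row in enumerate(rows):
        if pivot not in row.flanks:
            continue
        others = row.flanks - {pivot}
        if not others:  # self-pairing row cannot cover two flanks
            continue
        (partner,) = others
        if partner not in flanks:
            continue
        rest_rows = tuple(rows[:i]) + tuple(rows[i + 1 :])
        for sub in _perfect_matchings(rest_rows, flanks - {pivot, partner}):
            yield (row,) + sub


def select_major_links(table: LinkTable) -> MajorLinkSelection:
    """Pick, per repeat, the major links among the candidate flank pairings.

    The major links are the set of candidate rows of maximum total
    mate-pair count such that every flanking contig occurs in exactly one
    selected row (a maximum-weight perfect matching over the rows); the
    remaining rows are the minor links. No perfect matching, or two
    matchings tied at the maximum weight, raise an error demanding a
    manual decision.
    """
    per_repeat: dict[str, RepeatLinkChoice] = {}
    for repeat_id, rows in table.by_repeat().items():
        flanks = frozenset().union(*(r.flanks for r in rows))
        if len(flanks) > 16:
            raise ValueError(
                f"repeat {repeat_id!r} has {len(flanks)} flanking contigs; "
                "exhaustive matching is capped at 16"
            )
        matchings = list(_perfect_matchings(tuple(rows), flanks))
        if not matchings:
            raise ValueError(
                f"repeat {repeat_id!r}: no set of candidate links covers every "
                "flanking contig exactly once"
            )
        weights = [sum(r.link_count for r in m) for m in matchings]
        best = max(weights)
        winners = {frozenset(m) for m, w in zip(matchings, weights) if w == best}
        if len(winners) > 1:
            raise ValueError(
                f"repeat {repeat_id!r}: {len(winners)} matchings tie at total "
                f"link count {best}; choose manually"
            )
        selected_set = winners.pop()
        selected = [r for r in rows if r in selected_set]
        rejected = [r for r in rows if r not in selected_set]
        per_repeat[repeat_id] = RepeatLinkChoice(
            selected=selected, rejected=rejected, total_support=best
        )
        logger.info(
            "repeat %s: major links %s (total %d), minor links %s",
            repeat_id,
            [(r.five_prime_contig, r.three_prime_contig, r.link_count) for r in selected],
            best,
            [(r.five_prime_contig, r.three_prime_contig, r.link_count) for r in rejected],
        )
    return MajorLinkSelection(per_repeat=per_repeat)


def apply_major_links(
    graph: ContigGraph,
    repeats: Mapping[str, str],
    selection: MajorLinkSelection,
) -> ContigGraph:
    """Expand repeat contigs into per-copy nodes wired by their major links.

    Each repeat contig is replaced by one copy per selected flank pair;
    every copy keeps the repeat's sequence and receives an equal share of
    its read depth, so total sequence content (length x multiplicity) is
    conserved. After expansion the graph of a master circle admits a
    unique closed walk.
    """
    out = graph.copy()
    for repeat_id in sorted(selection.per_repeat):
        if repeat_id not in repeats:
            raise KeyError(f"no contig mapping for repeat {repeat_id!r}")
        rid = repeats[repeat_id]
        if rid not in out.nodes:
            raise KeyError(f"repeat contig {rid!r} not in graph")
        choice = selection.per_repeat[repeat_id]
        node = out.nodes[rid]
        # map each flank to its original edge with the repeat contig
        flank_edges: dict[str, ContigEdge] = {}
        for end in (End.FIVE_PRIME, End.THREE_PRIME):
            for edge in out.edges_at(EndRef(rid, end)):
                other = edge.other(EndRef(rid, end))
                flank_edges.setdefault(other.contig_id, edge)
        copies = len(choice.selected)
        new_depth = node.read_depth / copies
        out.remove_node(rid)
        for i, row in enumerate(choice.selected, start=1):
            copy_id = f"{rid}.copy{i}"
            out.add_node(replace(node, contig_id=copy_id, read_depth=new_depth))
            for flank in (row.five_prime_contig, row.three_prime_contig):
                edge = flank_edges.get(flank)
                if edge is None:
                    raise ValueError(
                        f"major link of repeat {repeat_id!r} references contig "
                        f"{flank!r}, which is not a graph neighbour of {rid!r}"
                    )
                rep_ref = edge.a if edge.a.contig_id == rid else edge.b
                flank_ref = edge.other(rep_ref)
                out.add_edge(
                    ContigEdge(
                        a=EndRef(copy_id, rep_ref.end),
                        b=flank_ref,
                        support=edge.support,
                        gap=edge.gap,
                        gap_base=edge.gap_base,
                    ),
                    merge=False,
                )
    return out
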