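"""Pruning the class-restricted contig graph down to a clean circle.

Two cleaning steps are applied after depth classification:

* ``remove_false_links`` drops contigs of the wrong class and weakly
  supported joins (false links typically connect contigs of different
  genomes, e.g. organellar fragments transferred to the nucleus);
* ``resolve_forks`` settles forks — alternative internal paths sharing the
  same start and end contigs — by keeping the branch whose depth matches
  the unique (non-fork) contigs of the class.

Every removal is logged with a reason; replaying the log against the input
graph reproduces the output exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .classify import DepthPartition, Label
from .graphio import ContigGraph, EdgeKey, End, EndRef

logger = logging.getLogger(__name__)

__all__ = [
    "Fork",
    "Removal",
    "remove_false_links",
    "detect_forks",
    "resolve_forks",
    "apply_removal_log",
]

DEFAULT_MIN_SUPPORT = 2
DEFAULT_MAX_BRANCH_LEN = 5


@dataclass(frozen=True)
class Removal:
    """One logged deletion: a node (contig id) or an edge (edge key)."""

    kind: str  # "node" | "edge"
    target: str | EdgeKey
    reason: str


@dataclass
class Fork:
    """Alternative internal paths sharing the same start and end contig ends."""

    start: EndRef
    end: EndRef
    branches: list[tuple[str, ...]]  # internal contig ids, in traversal order


def apply_removal_log(graph: ContigGraph, log: Sequence[Removal]) -> ContigGraph:
    """Replay a removal log on a fresh copy of ``graph``."""
    out = graph.copy()
    for rem in log:
        if rem.kind == "node":
            if rem.target in out.nodes:
                out.remove_node(rem.target)  # also drops incident edges
        elif rem.kind == "edge":
            if rem.target in {e.key for e in out.edges}:
                out.remove_edge(rem.target)
        else:
            raise ValueError(f"unknown removal kind {rem.kind!r}")
    return out


def remove_false_links(
    graph: ContigGraph,
    partition: DepthPartition,
    class_label: Label,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> tuple[ContigGraph, list[Removal]]:
    """Drop out-of-class contigs and weakly supported edges.

    Nodes not labelled ``class_label`` or UNRESOLVED_REPEAT are deleted
    with their incident edges; remaining edges with spanning-read support
    below ``min_support`` are deleted (single chimeric reads create joins
    of support 1). Returns the pruned graph and the removal log.
    """
    log: list[Removal] = []
    out = graph.copy()
    for cid in sorted(graph.nodes):
        label = partition.labels.get(cid)
        if label not in (class_label, Label.UNRESOLVED_REPEAT):
            out.remove_node(cid)
            log.append(
                Removal(
                    "node",
                    cid,
                    f"labelled {label.value if label else 'UNKNOWN'}, "
                    f"not {class_label.value}",
                )
            )
    for edge in list(out.edges):
        if edge.support < min_support:
            out.remove_edge(edge.key)
            log.append(
                Removal(
                    "edge", edge.key, f"support {edge.support} < {min_support}"
                )
            )
    # an unresolved repeat kept only on the strength of links to another
    # class has none left now; it cannot belong to this circle
    for cid in sorted(out.nodes):
        if partition.labels.get(cid) is Label.UNRESOLVED_REPEAT and not any(
            out.degree(EndRef(cid, end)) for end in (End.FIVE_PRIME, End.THREE_PRIME)
        ):
            out.remove_node(cid)
            log.append(Removal("node", cid, "unresolved repeat with no in-class links"))
    if not out.nodes:
        raise ValueError(
            f"pruning removed every contig; no {class_label.value} contigs remain"
        )
    for rem in log:
        logger.info("removed %s %s: %s", rem.kind, rem.target, rem.reason)
    return out, log


# ---------------------------------------------------------------------------
# Forks
# ---------------------------------------------------------------------------


def _branch_paths(
    graph: ContigGraph, start: EndRef, max_branch_len: int
) -> list[tuple[EndRef, tuple[str, ...]]]:
    """All simple internal paths leaving ``start``.

    Each result is (arrival end of the terminal contig, internal contig
    ids). The empty internal path corresponds to a direct edge.
    """
    results: list[tuple[EndRef, tuple[str, ...]]] = []

    def walk(exit_ref: EndRef, internal: tuple[str, ...]) -> None:
        for edge in graph.edges_at(exit_ref):
            arrival = edge.other(exit_ref)
            if arrival.contig_id == start.contig_id or arrival.contig_id in internal:
                continue
            results.append((arrival, internal))
            if len(internal) < max_branch_len:
                walk(
                    EndRef(arrival.contig_id, arrival.end.other),
                    internal + (arrival.contig_id,),
                )

    # the path continues *through* each internal contig: enter one end,
    # exit the other
    def walk_from_start() -> None:
        for edge in graph.edges_at(start):
            first = edge.other(start)
            if first.contig_id == start.contig_id:
                continue
            results.append((first, ()))
            if max_branch_len >= 1:
                walk(EndRef(first.contig_id, first.end.other), (first.contig_id,))

    walk_from_start()
    return results


def detect_forks(
    graph: ContigGraph, max_branch_len: int = DEFAULT_MAX_BRANCH_LEN
) -> list[Fork]:
    """Enumerate forks with branches of at most ``max_branch_len`` internal contigs.

    A fork is a pair of contig ends joined by two or more internally
    disjoint simple paths (the internal contigs differ between branches; a
    direct edge counts as an empty branch).
    """
    grouped: dict[tuple[EndRef, EndRef], set[tuple[str, ...]]] = {}
    for cid in sorted(graph.nodes):
        for end in (End.FIVE_PRIME, End.THREE_PRIME):
            start = EndRef(cid, end)
            for arrival, internal in _branch_paths(graph, start, max_branch_len):
                key_pair = tuple(sorted([start, arrival]))
                branch = internal
                if start != key_pair[0]:
                    branch = tuple(reversed(internal))
                grouped.setdefault((key_pair[0], key_pair[1]), set()).add(branch)
    forks: list[Fork] = []
    for (start, end), branches in sorted(grouped.items()):
        if len(branches) < 2:
            continue
        # keep a maximal pairwise internally-disjoint subset, shortest first
        chosen: list[tuple[str, ...]] = []
        used: set[str] = set()
        for b in sorted(branches, key=lambda x: (len(x), x)):
            if not used.intersection(b):
                chosen.append(b)
                used.update(b)
        if len(chosen) >= 2:
            forks.append(Fork(start=start, end=end, branches=chosen))
    return forks


def _branch_depth(graph: ContigGraph, branch: tuple[str, ...]) -> float | None:
    """Length-weighted mean depth of a branch's internal contigs."""
    if not branch:
        return None
    total_len = sum(graph.nodes[c].length for c in branch)
    return sum(graph.nodes[c].length * graph.nodes[c].read_depth for c in branch) / total_len


def _branch_support(graph: ContigGraph, fork: Fork, branch: tuple[str, ...]) -> int:
    """Total spanning-read support along the branch's joins."""
    refs = [fork.start]
    for cid in branch:
        # entry end is whichever end connects back toward the previous ref
        prev = refs[-1]
        entry = None
        for end in (End.FIVE_PRIME, End.THREE_PRIME):
            if graph.find_edge(prev, EndRef(cid, end)) is not None:
                entry = End(end)
                break
        if entry is None:
            return 0
        refs.append(EndRef(cid, entry))
        refs.append(EndRef(cid, entry.other))
    refs.append(fork.end)
    total = 0
    for a, b in zip(refs[::2], refs[1::2]):
        edge = graph.find_edge(a, b)
        if edge is not None:
            total += edge.support
    return total


def resolve_forks(
    graph: ContigGraph,
    partition: DepthPartition | None = None,
    max_branch_len: int = DEFAULT_MAX_BRANCH_LEN,
) -> tuple[ContigGraph, list[Removal]]:
    """Keep, per fork, the branch whose depth matches the unique contigs.

    The reference depth is the length-weighted mean depth of contigs that
    are not internal to any fork (the "unique paths" of the class). Each
    fork keeps the branch minimizing |branch depth - reference|; an empty
    branch (direct edge) has deviation 0. Ties break by higher total edge
    support, then by lexicographic internal contig ids; every discarded
    contig is logged.
    """
    forks = detect_forks(graph, max_branch_len=max_branch_len)
    out = graph.copy()
    log: list[Removal] = []
    if not forks:
        return out, log
    fork_internal = {c for f in forks for b in f.branches for c in b}
    unique_nodes = [n for c, n in graph.nodes.items() if c not in fork_internal]
    if unique_nodes:
        total_len = sum(n.length for n in unique_nodes)
        ref_depth = sum(n.length * n.read_depth for n in unique_nodes) / total_len
    else:
        ref_depth = sum(n.read_depth for n in graph.nodes.values()) / len(graph.nodes)
    for fork in forks:
        live = [b for b in fork.branches if all(c in out.nodes for c in b)]
        if len(live) < 2:
            continue

        def score(branch: tuple[str, ...]) -> tuple[float, int, tuple[str, ...]]:
            depth = _branch_depth(graph, branch)
            dev = 0.0 if depth is None else abs(depth - ref_depth)
            return (dev, -_branch_support(graph, fork, branch), branch)

        ordered = sorted(live, key=score)
        keep = ordered[0]
        logger.info(
            "fork %s..%s: keeping branch %s (reference depth %.1f)",
            fork.start,
            fork.end,
            keep or "(direct edge)",
            ref_depth,
        )
        for branch in ordered[1:]:
            for cid in branch:
                if cid in out.nodes:
                    out.remove_node(cid)
                    log.append(
                        Removal(
                            "node",
                            cid,
                            f"fork branch losing to {keep or ('direct edge',)} "
                            f"(reference depth {ref_depth:.1f})",
                        )
                    )
    return out, log
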