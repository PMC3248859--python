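from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from orgc.graphio import ContigEdge, ContigGraph, ContigNode, End, EndRef

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_graph(nodes, edges):
    """Compact graph builder.

    ``nodes``: (contig_id, length, depth[, sequence]) tuples.
    ``edges``: ((id_a, end_a), (id_b, end_b)[, support[, gap_base]]) tuples,
    with ends given as the characters "5"/"3"; support defaults to 5.
    """
    g = ContigGraph()
    for spec in nodes:
        cid, length, depth = spec[:3]
        seq = spec[3] if len(spec) > 3 else None
        g.add_node(ContigNode(contig_id=cid, length=length, read_depth=depth, sequence=seq))
    for spec in edges:
        (ca, ea), (cb, eb) = spec[:2]
        support = spec[2] if len(spec) > 2 else 5
        gap_base = spec[3] if len(spec) > 3 else None
        g.add_edge(
            ContigEdge(
                a=EndRef(ca, End(ea)),
                b=EndRef(cb, End(eb)),
                support=support,
                gap=1 if gap_base else 0,
                gap_base=gap_base,
            )
        )
    return g


@pytest.fixture
def quadripartite_graph():
    """Toy plastid graph: LSC contig L, collapsed IR contig I, SSC contig S.

    Planted circular sequence: L + I + S + revcomp(I).
    """
    g = build_graph(
        nodes=[
            ("L", 10, 87.0, "AAAACCTTGG"),
            ("I", 4, 174.0, "GGTC"),
            ("S", 6, 86.0, "TTTACA"),
        ],
        edges=[
            (("L", "3"), ("I", "5")),
            (("I", "3"), ("S", "5")),
            (("S", "3"), ("I", "3")),
            (("I", "5"), ("L", "5")),
        ],
    )
    return g


def random_graph(seed: int, with_sequences: bool = True) -> ContigGraph:
    """Seeded random valid graph for round-trip style tests."""
    rng = np.random.default_rng(seed)
    g = ContigGraph()
    n = int(rng.integers(1, 9))
    for i in range(n):
        length = int(rng.integers(1, 60))
        seq = None
        if with_sequences and rng.random() < 0.6:
            seq = "".join(rng.choice(list("ACGTN"), size=length))
        num_reads = int(rng.integers(0, 500)) if rng.random() < 0.5 else None
        g.add_node(
            ContigNode(
                contig_id=f"c{i}",
                length=length,
                read_depth=float(np.round(rng.uniform(0.5, 200.0), 3)),
                sequence=seq,
                num_reads=num_reads,
            )
        )
    ids = sorted(g.nodes)
    seen = set()
    for _ in range(int(rng.integers(0, 2 * n))):
        ca, cb = rng.choice(ids, size=2)
        ea = End("5") if rng.random() < 0.5 else End("3")
        eb = End("5") if rng.random() < 0.5 else End("3")
        gap_base = str(rng.choice(list("ACGT"))) if rng.random() < 0.2 else None
        edge = ContigEdge(
            a=EndRef(ca, ea),
            b=EndRef(cb, eb),
            support=int(rng.integers(0, 50)),
            gap=1 if gap_base else 0,
            gap_base=gap_base,
        )
        if edge.key in seen:
            continue
        seen.add(edge.key)
        g.add_edge(edge, merge=False)
    return g
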