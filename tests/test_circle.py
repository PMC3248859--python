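"""Closed-walk search, quadripartite annotation, and major-link selection."""

from __future__ import annotations

from importlib.resources import files

import networkx as nx
import numpy as np
import pytest

from orgc.circle import (
    Orientation,
    Region,
    annotate_quadripartite,
    apply_major_links,
    find_circular_path,
    infer_multiplicity,
    select_major_links,
)
from orgc.graphio import End, EndRef, LinkRecord, LinkTable, read_link_table

from .conftest import build_graph

F, R = Orientation.FORWARD, Orientation.REVERSE
PUBLISHED_LINKS = files("orgc") / "data" / "boea_mt_repeat_links.tsv"


def _entry(o):
    return End.FIVE_PRIME if o is F else End.THREE_PRIME


def _exit(o):
    return End.THREE_PRIME if o is F else End.FIVE_PRIME


def _canon(steps):
    """Test-local canonicalization over rotations and reversal."""
    variants = []
    rev = [(c, "-" if o is F or o == "+" else "+") for c, o in reversed(steps)]
    fwd = [(c, o.value if isinstance(o, Orientation) else o) for c, o in steps]
    for var in (fwd, rev):
        for k in range(len(var)):
            variants.append(tuple(var[k:] + var[:k]))
    return min(variants)


def _oracle_walks(graph, mult):
    """Independent exhaustive enumeration of closed walks."""
    total = sum(mult.values())
    all_keys = [e.key for e in graph.edges]
    sols = set()

    def rec(seq, remaining, used):
        if len(seq) == total:
            lc, lo = seq[-1]
            fc, fo = seq[0]
            e = graph.find_edge(EndRef(lc, _exit(lo)), EndRef(fc, _entry(fo)))
            if e is None:
                return
            u = dict(used)
            u[e.key] = u.get(e.key, 0) + 1
            if all(u.get(k, 0) > 0 for k in all_keys):
                sols.add(_canon(seq))
            return
        lc, lo = seq[-1]
        ex = EndRef(lc, _exit(lo))
        for cid in graph.nodes:
            if remaining[cid] <= 0:
                continue
            for o in (F, R):
                e = graph.find_edge(ex, EndRef(cid, _entry(o)))
                if e is None:
                    continue
                remaining[cid] -= 1
                u2 = dict(used)
                u2[e.key] = u2.get(e.key, 0) + 1
                rec(seq + [(cid, o)], remaining, u2)
                remaining[cid] += 1

    for start in graph.nodes:
        for o in (F, R):
            rem = dict(mult)
            rem[start] -= 1
            rec([(start, o)], rem, {})
    return sols


class TestFindCircularPath:
    def test_three_node_cycle_single_walk(self):
        g = build_graph(
            [("a", 10, 40.0), ("b", 10, 40.0), ("c", 10, 40.0)],
            [
                (("a", "3"), ("b", "5")),
                (("b", "3"), ("c", "5")),
                (("c", "3"), ("a", "5")),
            ],
        )
        walks = find_circular_path(g, {"a": 1, "b": 1, "c": 1})
        assert len(walks) == 1
        assert len(walks[0].steps) == 3

    def test_quadripartite_graph_yields_expected_walk(self, quadripartite_graph):
        """The L-I-S-I walk is found; the only other solution is the
        small-single-copy flip isomer."""
        mult = {"L": 1, "I": 2, "S": 1}
        walks = find_circular_path(quadripartite_graph, mult)
        canons = {w.canonical_steps() for w in walks}
        expected = _canon([("L", F), ("I", F), ("S", F), ("I", R)])
        flipped = _canon([("L", F), ("I", F), ("S", R), ("I", R)])
        assert {tuple((c, o.value) for c, o in k) for k in canons} == {
            expected,
            flipped,
        }

    def test_broken_cycle_raises_with_violations(self):
        g = build_graph(
            [("a", 10, 40.0), ("b", 10, 40.0)],
            [(("a", "3"), ("b", "5"))],
        )
        with pytest.raises(ValueError, match="degree 0"):
            find_circular_path(g, {"a": 1, "b": 1})

    def test_single_contig_circle(self):
        g = build_graph(
            [("c", 10, 40.0)],
            [(("c", "3"), ("c", "5"))],
        )
        walks = find_circular_path(g, {"c": 1})
        assert len(walks) == 1 and len(walks[0].steps) == 1

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_oracle_on_small_graphs(self, seed):
        """Planted walks over <= 6 steps: the search finds exactly the
        closed walks the brute-force enumerator finds."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        steps = [(f"c{i}", F) for i in range(n)]
        if rng.random() < 0.6:  # duplicate one contig as a 2-copy repeat
            dup = f"c{int(rng.integers(n))}"
            o = R if rng.random() < 0.5 else F
            pos = int(rng.integers(1, n + 1))
            steps = steps[:pos] + [(dup, o)] + steps[pos:]
        mult = {}
        for c, _ in steps:
            mult[c] = mult.get(c, 0) + 1
        nodes = [(c, 10, 40.0 * m) for c, m in mult.items()]
        edges = []
        for i in range(len(steps)):
            c1, o1 = steps[i]
            c2, o2 = steps[(i + 1) % len(steps)]
            edges.append(((c1, _exit(o1).value), (c2, _entry(o2).value)))
        g = build_graph(nodes, [])
        from orgc.graphio import ContigEdge

        for (ca, ea), (cb, eb) in edges:
            g.add_edge(
                ContigEdge(a=EndRef(ca, End(ea)), b=EndRef(cb, End(eb)), support=5)
            )
        oracle = _oracle_walks(g, mult)
        walks = find_circular_path(g, mult, max_solutions=64)
        got = {
            _canon([(c, o) for c, o in w.steps]) for w in walks
        }
        assert got == oracle
        assert _canon(steps) in got  # the planted walk itself is found

    def test_canonical_invariance_under_start_relabelling(self):
        g1 = build_graph(
            [("a", 10, 40.0), ("b", 12, 40.0), ("c", 14, 40.0)],
            [
                (("a", "3"), ("b", "5")),
                (("b", "3"), ("c", "5")),
                (("c", "3"), ("a", "5")),
            ],
        )
        w1 = find_circular_path(g1, {c: 1 for c in g1.nodes})[0]
        # same cycle, different ordering of node insertion / edge listing
        g2 = build_graph(
            [("c", 14, 40.0), ("a", 10, 40.0), ("b", 12, 40.0)],
            [
                (("c", "3"), ("a", "5")),
                (("b", "3"), ("c", "5")),
                (("a", "3"), ("b", "5")),
            ],
        )
        w2 = find_circular_path(g2, {c: 1 for c in g2.nodes})[0]
        assert w1.canonical_steps() == w2.canonical_steps()


class TestInferMultiplicity:
    def test_ir_contig_at_double_depth(self, quadripartite_graph):
        assert infer_multiplicity(quadripartite_graph) == {"L": 1, "I": 2, "S": 1}

    def test_uniform_depths_all_single(self):
        g = build_graph([(f"c{i}", 10, 43.0) for i in range(4)], [])
        assert infer_multiplicity(g) == {f"c{i}": 1 for i in range(4)}


class TestAnnotateQuadripartite:
    def test_planted_lsc_ssc_ir_lengths(self):
        g = build_graph(
            [("L", 8000, 87.0), ("I", 3000, 174.0), ("S", 2000, 86.0)],
            [
                (("L", "3"), ("I", "5")),
                (("I", "3"), ("S", "5")),
                (("S", "3"), ("I", "3")),
                (("I", "5"), ("L", "5")),
            ],
        )
        mult = {"L": 1, "I": 2, "S": 1}
        circle = find_circular_path(g, mult)[0]
        ann = annotate_quadripartite(circle, mult, g)
        assert (ann.lsc_len, ann.ssc_len, ann.ir_len) == (8000, 2000, 3000)
        assert ann.lsc_len >= ann.ssc_len
        regions = [r for r, _ in ann.segments]
        assert regions == [Region.LSC, Region.IRA, Region.SSC, Region.IRB]
        ira = next(idx for r, idx in ann.segments if r is Region.IRA)
        irb = next(idx for r, idx in ann.segments if r is Region.IRB)
        assert {circle.steps[i][0] for i in ira} == {circle.steps[i][0] for i in irb}

    def test_no_repeat_degenerates_to_single_lsc(self):
        g = build_graph(
            [("a", 10, 40.0), ("b", 10, 40.0)],
            [(("a", "3"), ("b", "5")), (("b", "3"), ("a", "5"))],
        )
        circle = find_circular_path(g, {"a": 1, "b": 1})[0]
        with pytest.warns(UserWarning, match="single LSC"):
            ann = annotate_quadripartite(circle, {"a": 1, "b": 1}, g)
        assert [r for r, _ in ann.segments] == [Region.LSC]
        assert ann.lsc_len == 20 and ann.ir_len == 0

    def test_equal_arcs_tie_is_stable(self):
        g = build_graph(
            [("A", 500, 87.0), ("I", 300, 174.0), ("B", 500, 86.0)],
            [
                (("A", "3"), ("I", "5")),
                (("I", "3"), ("B", "5")),
                (("B", "3"), ("I", "3")),
                (("I", "5"), ("A", "5")),
            ],
        )
        mult = {"A": 1, "I": 2, "B": 1}
        circle = find_circular_path(g, mult)[0]
        ann = annotate_quadripartite(circle, mult, g)
        assert ann.lsc_len == ann.ssc_len == 500


class TestSelectMajorLinks:
    def test_published_table_reproduces_all_three_decisions(self):
        table = read_link_table(PUBLISHED_LINKS)
        sel = select_major_links(table)
        picks = {
            rid: {
                (r.five_prime_contig, r.three_prime_contig, r.link_count)
                for r in sel[rid].selected
            }
            for rid in sel.per_repeat
        }
        assert picks["Repeat 1"] == {
            ("Contig00011", "Contig00012", 3990),
            ("Contig00059", "Contig00050", 3226),
        }
        assert picks["Repeat 2"] == {
            ("Contig00001", "Contig00026", 810),
            ("Contig00004", "Contig00032", 615),
        }
        assert picks["Repeat 3"] == {
            ("Contig00026", "Contig00281", 53),
            ("Contig00395", "Contig200056", 51),
        }
        # minor links are reported, never dropped silently
        assert all(len(sel[rid].rejected) == 2 for rid in picks)

    def test_single_candidate_row(self):
        table = LinkTable([LinkRecord("r1", "a", "b", 10)])
        sel = select_major_links(table)
        assert len(sel["r1"].selected) == 1 and sel["r1"].rejected == []

    def test_tie_raises(self):
        table = LinkTable(
            [
                LinkRecord("r1", "a", "b", 5),
                LinkRecord("r1", "c", "d", 5),
                LinkRecord("r1", "a", "c", 5),
                LinkRecord("r1", "b", "d", 5),
            ]
        )
        with pytest.raises(ValueError, match="tie"):
            select_major_links(table)

    def test_no_perfect_matching_raises(self):
        table = LinkTable(
            [LinkRecord("r1", "a", "b", 5), LinkRecord("r1", "a", "c", 3)]
        )
        with pytest.raises(ValueError, match="covers every"):
            select_major_links(table)

    @pytest.mark.parametrize("seed", range(200))
    def test_matches_networkx_max_weight_matching(self, seed):
        """Selection weight equals the max-weight perfect matching found
        independently by networkx on random candidate tables."""
        rng = np.random.default_rng(seed)
        flanks = ["a", "b", "c", "d"]
        pairs = [(x, y) for i, x in enumerate(flanks) for y in flanks[i + 1 :]]
        k = int(rng.integers(2, 7))
        chosen = [pairs[i] for i in rng.choice(len(pairs), size=k, replace=False)]
        # powers of two make every matching weight sum unique (no ties)
        weights = [int(w) for w in rng.permutation([1, 2, 4, 8, 16, 32])[:k]]
        table = LinkTable(
            LinkRecord("r", a, b, w) for (a, b), w in zip(chosen, weights)
        )
        G = nx.Graph()
        G.add_nodes_from({f for p in chosen for f in p})
        for (a, b), w in zip(chosen, weights):
            G.add_edge(a, b, weight=w)
        nx_match = nx.max_weight_matching(G, maxcardinality=True)
        perfect_exists = 2 * len(nx_match) == G.number_of_nodes()
        if not perfect_exists:
            with pytest.raises(ValueError):
                select_major_links(table)
            return
        sel = select_major_links(table)
        nx_weight = sum(G.edges[u, v]["weight"] for u, v in nx_match)
        assert sel["r"].total_support == nx_weight


class TestApplyMajorLinks:
    def _mt_like(self):
        """Two-copy repeat (second copy inverted) with flanks l1/r1 and
        l2/r2, embedded in a circle l1-rep-r1-l2-rev(rep)-r2. The inverted
        copy makes the collapsed walk genuinely ambiguous (a middle-segment
        flip is also a closed walk), as for a plastid IR."""
        g = build_graph(
            [
                ("l1", 10, 43.0, "A" * 10),
                ("r1", 10, 43.0, "C" * 10),
                ("l2", 10, 44.0, "G" * 10),
                ("r2", 10, 42.0, "T" * 10),
                ("rep", 6, 86.0, "ACACAC"),
            ],
            [
                (("l1", "3"), ("rep", "5")),
                (("rep", "3"), ("r1", "5")),
                (("r1", "3"), ("l2", "5")),
                (("l2", "3"), ("rep", "3")),
                (("rep", "5"), ("r2", "5")),
                (("r2", "3"), ("l1", "5")),
            ],
        )
        table = LinkTable(
            [
                LinkRecord("rep", "l1", "r1", 50),
                LinkRecord("rep", "l2", "r2", 45),
                LinkRecord("rep", "l1", "l2", 4),
                LinkRecord("rep", "r1", "r2", 3),
            ]
        )
        return g, table

    def test_expansion_makes_walk_unique(self):
        g, table = self._mt_like()
        mult = {c: (2 if c == "rep" else 1) for c in g.nodes}
        ambiguous = find_circular_path(g, mult)
        assert len(ambiguous) > 1  # collapsed repeat leaves alternatives
        sel = select_major_links(table)
        expanded = apply_major_links(g, {"rep": "rep"}, sel)
        walks = find_circular_path(expanded, {c: 1 for c in expanded.nodes})
        assert len(walks) == 1
        steps = walks[0].canonical_steps()
        order = [c for c, _ in steps]
        # copies sit between their selected flank pairs
        i1 = order.index("rep.copy1")
        assert {order[i1 - 1], order[(i1 + 1) % len(order)]} == {"l1", "r1"}
        i2 = order.index("rep.copy2")
        assert {order[i2 - 1], order[(i2 + 1) % len(order)]} == {"l2", "r2"}

    def test_sequence_content_conserved(self):
        g, table = self._mt_like()
        sel = select_major_links(table)
        expanded = apply_major_links(g, {"rep": "rep"}, sel)
        before = sum(
            n.length * (2 if c == "rep" else 1) for c, n in g.nodes.items()
        )
        after = sum(n.length for n in expanded.nodes.values())
        assert before == after
        assert expanded.nodes["rep.copy1"].sequence == "ACACAC"

    def test_non_neighbour_link_raises(self):
        g, _ = self._mt_like()
        table = LinkTable([LinkRecord("rep", "l1", "zz", 50)])
        g.add_node(
            __import__("orgc.graphio", fromlist=["ContigNode"]).ContigNode(
                "zz", 5, 43.0
            )
        )
        sel = select_major_links(table)
        with pytest.raises(ValueError, match="not a graph neighbour"):
            apply_major_links(g, {"rep": "rep"}, sel)

    def test_single_pair_keeps_graph_equivalent(self):
        g = build_graph(
            [("a", 10, 43.0), ("b", 10, 43.0), ("r", 5, 43.0)],
            [
                (("a", "3"), ("r", "5")),
                (("r", "3"), ("b", "5")),
                (("b", "3"), ("a", "5")),
            ],
        )
        sel = select_major_links(LinkTable([LinkRecord("r", "a", "b", 9)]))
        out = apply_major_links(g, {"r": "r"}, sel)
        assert set(out.nodes) == {"a", "b", "r.copy1"}
        assert len(out.edges) == 3
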