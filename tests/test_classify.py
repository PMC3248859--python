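"""Depth classification, repeat flagging, seeding and component extraction."""

from __future__ import annotations

import numpy as np
import pytest

from orgc.classify import (
    DepthPartition,
    Label,
    classify_by_depth,
    depth_histogram,
    extract_component,
    find_seed_contigs,
    flag_repeats,
    repeat_candidates_by_degree,
)
from orgc.seqs import revcomp

from .conftest import build_graph


class TestDepthHistogram:
    def test_three_class_depths_fall_in_separate_bins(self):
        g = build_graph(
            [("a", 100, 9.0), ("b", 100, 43.0), ("c", 100, 87.0)], []
        )
        h = depth_histogram(g, bin_width=10.0)
        assert h.counts == {0: 1, 4: 1, 8: 1}
        assert h.weighted_counts == {0: 100, 4: 100, 8: 100}

    def test_single_contig(self):
        g = build_graph([("a", 50, 12.0)], [])
        assert depth_histogram(g, bin_width=5.0).counts == {2: 1}

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_sum_to_node_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        g = build_graph(
            [(f"c{i}", int(rng.integers(1, 500)), float(rng.uniform(0.5, 200))) for i in range(n)],
            [],
        )
        h = depth_histogram(g, bin_width=float(rng.uniform(1, 25)))
        assert sum(h.counts.values()) == n

    def test_empty_graph_raises(self):
        from orgc.graphio import ContigGraph

        with pytest.raises(ValueError):
            depth_histogram(ContigGraph(), 10.0)


class TestClassifyByDepth:
    def test_class_means_get_expected_labels(self):
        g = build_graph(
            [("cp", 100, 87.0), ("mt", 100, 43.0), ("nuc", 100, 9.0)], []
        )
        p = classify_by_depth(g)
        assert p.labels == {
            "cp": Label.CP,
            "mt": Label.MT,
            "nuc": Label.NUCLEAR,
        }

    def test_boundaries_are_closed_outward(self):
        """The MT window is the open interval (t_low, t_high)."""
        g = build_graph([("hi", 10, 60.0), ("lo", 10, 20.0)], [])
        p = classify_by_depth(g)
        assert p.labels["hi"] is Label.CP
        assert p.labels["lo"] is Label.NUCLEAR

    def test_repeat_flags_defer_labelling(self):
        g = build_graph([("r", 10, 86.0), ("m", 10, 43.0)], [])
        p = classify_by_depth(g, repeat_flags={"r"})
        assert p.labels["r"] is Label.UNRESOLVED_REPEAT

    def test_total_and_uniform(self):
        g = build_graph([(f"c{i}", 10, 43.0) for i in range(5)], [])
        p = classify_by_depth(g)
        assert len(p.labels) == 5
        assert set(p.labels.values()) == {Label.MT}

    def test_bad_thresholds_raise(self):
        g = build_graph([("a", 10, 1.0)], [])
        with pytest.raises(ValueError):
            classify_by_depth(g, t_low=60, t_high=20)


class TestRepeatCandidatesByDegree:
    def test_collapsed_repeat_has_two_joins_per_end(self):
        g = build_graph(
            [("r", 10, 86.0)]
            + [(f"f{i}", 10, 43.0) for i in range(4)],
            [
                (("f0", "3"), ("r", "5")),
                (("f1", "3"), ("r", "5")),
                (("r", "3"), ("f2", "5")),
                (("r", "3"), ("f3", "5")),
            ],
        )
        assert repeat_candidates_by_degree(g) == {"r"}

    def test_weak_links_do_not_create_candidates(self):
        g = build_graph(
            [("a", 10, 43.0), ("b", 10, 43.0), ("c", 10, 9.0), ("d", 10, 9.0)],
            [
                (("a", "5"), ("b", "3"), 5),
                (("a", "5"), ("c", "5"), 1),  # spurious, support 1
                (("a", "3"), ("b", "5"), 5),
                (("a", "3"), ("d", "5"), 1),
            ],
        )
        assert repeat_candidates_by_degree(g, min_support=2) == set()


class TestFindSeedContigs:
    def test_exact_gene_containment_is_a_seed(self):
        rng = np.random.default_rng(0)
        gene = "".join(rng.choice(list("ACGT"), size=300))
        flank = "".join(rng.choice(list("ACGT"), size=200))
        g = build_graph([("c1", 500, 40.0, flank + gene)], [])
        assert find_seed_contigs(g, {"gene": gene}, k=31, min_hits=10) == {"c1"}

    def test_no_shared_kmers_is_not_a_seed(self):
        g = build_graph([("c1", 40, 40.0, "A" * 40)], [])
        assert find_seed_contigs(g, {"gene": "C" * 40}, k=31, min_hits=1) == set()

    def test_reverse_complement_match_counts(self):
        rng = np.random.default_rng(1)
        gene = "".join(rng.choice(list("ACGT"), size=120))
        g = build_graph([("c1", 120, 40.0, revcomp(gene))], [])
        assert find_seed_contigs(g, {"gene": gene}, k=21, min_hits=5) == {"c1"}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_kmer_intersection(self, seed):
        rng = np.random.default_rng(seed)
        k = 15
        ref = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 200))))
        contig = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 200))))
        if rng.random() < 0.5:  # sometimes embed a shared chunk
            i = int(rng.integers(0, len(ref) - 30))
            contig = contig[:20] + ref[i : i + 30] + contig[20:]
        g = build_graph([("c1", len(contig), 40.0, contig)], [])

        def canon(s):
            return {
                min(s[i : i + k], revcomp(s[i : i + k]))
                for i in range(len(s) - k + 1)
            }

        for min_hits in (1, 3, 10):
            expected = {"c1"} if len(canon(contig) & canon(ref)) >= min_hits else set()
            assert find_seed_contigs(g, {"r": ref}, k=k, min_hits=min_hits) == expected

    def test_monotone_in_min_hits(self):
        rng = np.random.default_rng(2)
        ref = "".join(rng.choice(list("ACGT"), size=150))
        contig = ref[:80] + "".join(rng.choice(list("ACGT"), size=80))
        g = build_graph([("c1", len(contig), 40.0, contig)], [])
        sizes = [
            len(find_seed_contigs(g, {"r": ref}, k=21, min_hits=h))
            for h in (1, 20, 200)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_errors(self):
        g = build_graph([("c1", 10, 40.0)], [])
        with pytest.raises(ValueError, match="no contig"):
            find_seed_contigs(g, {"r": "ACGT" * 20})
        g2 = build_graph([("c1", 40, 40.0, "ACGT" * 10)], [])
        with pytest.raises(ValueError, match="no sequences"):
            find_seed_contigs(g2, {})


class TestFlagRepeats:
    def _partition(self, g, label=Label.MT):
        return DepthPartition(
            t_low=20, t_high=60, labels={c: label for c in g.nodes}
        )

    def test_double_depth_contig_flagged_two(self):
        g = build_graph(
            [("a", 10, 43.0), ("b", 10, 44.0), ("c", 10, 42.0), ("r", 10, 88.0)], []
        )
        flags = flag_repeats(g, self._partition(g), Label.MT)
        assert flags == {"r": 2}

    def test_flag_matches_exhaustive_multiple_search(self):
        """The assigned multiplicity minimizes relative deviation over m."""
        g = build_graph(
            [("a", 10, 43.0), ("b", 10, 44.0), ("c", 10, 42.0), ("r", 10, 88.0)], []
        )
        flags = flag_repeats(g, self._partition(g), Label.MT)
        base = 43.0
        best_m = min(range(1, 7), key=lambda m: abs(88.0 - m * base) / base)
        assert flags["r"] == best_m == 2

    def test_uniform_depths_unflagged(self):
        g = build_graph([(f"c{i}", 10, 43.0) for i in range(5)], [])
        assert flag_repeats(g, self._partition(g), Label.MT) == {}

    def test_exact_double_flagged(self):
        g = build_graph(
            [("a", 10, 40.0), ("b", 10, 40.0), ("c", 10, 40.0), ("r", 10, 80.0)], []
        )
        assert flag_repeats(g, self._partition(g), Label.MT) == {"r": 2}

    def test_too_few_class_contigs_raise(self):
        g = build_graph([("a", 10, 43.0), ("b", 10, 43.0)], [])
        with pytest.raises(ValueError, match="manual"):
            flag_repeats(g, self._partition(g), Label.MT)


class TestExtractComponent:
    def _chain(self, labels):
        nodes = [(f"c{i}", 10, 43.0) for i in range(len(labels))]
        edges = [((f"c{i}", "3"), (f"c{i+1}", "5")) for i in range(len(labels) - 1)]
        g = build_graph(nodes, edges)
        part = DepthPartition(
            t_low=20,
            t_high=60,
            labels={f"c{i}": lab for i, lab in enumerate(labels)},
        )
        return g, part

    def test_same_class_chain_fully_extracted(self):
        g, part = self._chain([Label.MT] * 5)
        sub = extract_component(g, {"c0"}, part, Label.MT)
        assert set(sub.nodes) == {f"c{i}" for i in range(5)}

    def test_traversal_stops_at_nuclear_contig(self):
        g, part = self._chain([Label.MT, Label.MT, Label.NUCLEAR, Label.MT])
        sub = extract_component(g, {"c0"}, part, Label.MT)
        assert set(sub.nodes) == {"c0", "c1"}

    def test_internal_cp_contig_retained_in_mt_extraction(self):
        """Plastid DNA transferred into the mt genome stays on the mt path."""
        g, part = self._chain([Label.MT, Label.CP, Label.MT])
        sub = extract_component(g, {"c0"}, part, Label.MT)
        assert set(sub.nodes) == {"c0", "c1", "c2"}

    def test_dangling_cp_contig_excluded_from_mt_extraction(self):
        g, part = self._chain([Label.MT, Label.MT, Label.CP, Label.CP])
        sub = extract_component(g, {"c0"}, part, Label.MT)
        assert set(sub.nodes) == {"c0", "c1"}

    def test_unresolved_repeat_adopted(self):
        g, part = self._chain(
            [Label.MT, Label.UNRESOLVED_REPEAT, Label.MT]
        )
        sub = extract_component(g, {"c0"}, part, Label.MT)
        assert set(sub.nodes) == {"c0", "c1", "c2"}

    def test_missing_seed_raises(self):
        g, part = self._chain([Label.MT])
        with pytest.raises(KeyError):
            extract_component(g, {"zz"}, part, Label.MT)
        with pytest.raises(ValueError):
            extract_component(g, set(), part, Label.MT)
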