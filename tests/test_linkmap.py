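"""Two-point statistics, grouping, binning, ordering, placement, distortion."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gbsmap import genome, linkmap, simpop
from gbsmap.linkmap import (bin_haplotypes, double_co_scan, group_markers,
                            kosambi, kosambi_inverse, order_markers,
                            order_objective, pairwise_tables, place_markers,
                            ril_correct, segregation_chisq, two_point)

A, B, H, M = 0, 1, 2, -1


def col(pattern):
    return np.array([{"A": A, "B": B, "H": H, "-": M}[c] for c in pattern], dtype=np.int8)


class TestTwoPoint:
    def test_identical_segregation(self):
        g = col("AAAAABBBBB")
        res = two_point(g, g)
        assert res.R == 0 and res.distance_cm == 0 and res.n_informative == 10

    def test_single_recombinant(self):
        gi = col("AAAAABBBBB")
        gj = col("AAAAABBBBA")
        assert two_point(gi, gj).R == pytest.approx(0.1)

    def test_pairwise_complete_counting_excludes_missing(self):
        gi = col("AAAAABBBB-")
        gj = col("AABB-BBBBA")
        res = two_point(gi, gj)
        assert res.n_informative == 8
        assert res.R == pytest.approx(2 / 8)

    def test_no_informative_lines_flagged(self):
        res = two_point(col("HH--"), col("AB--"))
        assert not res.defined

    def test_pairwise_tables_match_two_point(self, rng):
        g = rng.choice([A, B, H, M], size=(40, 6), p=[0.4, 0.4, 0.05, 0.15]).astype(np.int8)
        N, D = pairwise_tables(g)
        for i, j in itertools.combinations(range(6), 2):
            res = two_point(g[:, i], g[:, j])
            assert N[i, j] == res.n_informative
            assert D[i, j] == res.n_recombinant


class TestMapFunctions:
    def test_ril_correction_values(self):
        assert ril_correct(0.0) == 0.0
        assert ril_correct(1 / 3) == pytest.approx(0.25)
        assert ril_correct(0.5) == pytest.approx(0.5)   # fixed point

    def test_ril_correction_domain(self):
        with pytest.raises(ValueError):
            ril_correct(1.0)

    def test_correction_roundtrip_on_rational_grid(self):
        for num in range(0, 50):
            r = Fraction(num, 100)
            R = 2 * r / (1 + 2 * r)
            assert ril_correct(float(R)) == pytest.approx(float(r), abs=1e-12)

    def test_kosambi_values(self):
        assert kosambi(0.0) == 0.0
        assert kosambi(0.1) == pytest.approx(25 * np.log(1.2 / 0.8))
        assert kosambi(0.1) == pytest.approx(10.14, abs=0.005)
        assert kosambi(0.25) == pytest.approx(27.47, abs=0.005)

    def test_kosambi_unlinked_is_infinite(self):
        assert kosambi(0.5) == np.inf

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.0, 0.49))
    def test_kosambi_roundtrip(self, r):
        assert kosambi_inverse(kosambi(r)) == pytest.approx(r, abs=1e-12)


class TestGrouping:
    def test_two_separated_clusters(self, rng):
        n = 100
        a = col("A" * 50 + "B" * 50)
        b = a.copy(); b[:5] = B
        c = rng.permutation(a)
        d = c.copy(); d[:5] = 1 - d[:5]
        g = np.stack([a, b, c, d], axis=1).astype(np.int8)
        groups = group_markers(g)
        assert sorted(sorted(grp) for grp in groups) == [[0, 1], [2, 3]]

    def test_chain_is_transitively_grouped(self):
        a = col("A" * 50 + "B" * 50)
        b = a.copy(); b[:10] = B        # R(a,b)=0.1
        c = b.copy(); c[10:19] = np.where(b[10:19] == A, B, A)
        g = np.stack([a, b, c], axis=1).astype(np.int8)
        assert len(group_markers(g)) == 1

    def test_unlinked_singleton_reported_alone(self, rng):
        a = col("A" * 50 + "B" * 50)
        b = a.copy(); b[:5] = B
        c = rng.permutation(a)
        g = np.stack([a, b, c], axis=1).astype(np.int8)
        groups = group_markers(g)
        assert [2] in groups

    def test_eleven_chromosomes_recovered(self, bean_genome):
        panel = genome.build_marker_panel(bean_genome, 520, seed=11)
        pop = simpop.simulate_rils(bean_genome, panel, n_lines=188,
                                   generations=11, seed=12, missing_rate=0.15)
        groups = [grp for grp in group_markers(pop.genotypes) if len(grp) > 1]
        assert len(groups) == 11


class TestBinning:
    def test_duplicate_columns_merge(self):
        a = col("AAABBB")
        g = np.stack([a, a.copy()], axis=1).astype(np.int8)
        bins = bin_haplotypes([0, 1], g)
        assert len(bins) == 1 and sorted(bins[0]["members"]) == [0, 1]

    def test_representative_has_fewest_missing(self):
        a = col("AAABBB")
        b = a.copy(); b[2] = M
        g = np.stack([a, b], axis=1).astype(np.int8)
        bins = bin_haplotypes([0, 1], g)
        assert bins[0]["representative"] == 0

    def test_single_recombinant_prevents_merge(self):
        a = col("AAABBB")
        b = a.copy(); b[0] = B
        g = np.stack([a, b], axis=1).astype(np.int8)
        assert len(bin_haplotypes([0, 1], g)) == 2

    def test_no_merged_pair_has_observed_recombinant(self, rng):
        g = rng.choice([A, B, M], size=(30, 12), p=[0.45, 0.45, 0.1]).astype(np.int8)
        bins = bin_haplotypes(list(range(12)), g)
        _, D = pairwise_tables(g)
        for b in bins:
            for i, j in itertools.combinations(b["members"], 2):
                assert D[i, j] == 0


class TestOrdering:
    def _simulate_chain(self, n_markers, n_lines, seed, spacing_cm=10.0):
        length = n_markers * spacing_cm
        cfg = {"chromosomes": [{"name": "c", "length_mb": length, "base_rate": 1.0,
                                "pericentromere": None, "peri_rate": 0.0,
                                "hotspots": []}]}
        g = genome.build_genome(cfg)
        pos = tuple(int((i + 0.5) * spacing_cm * 1e6) for i in range(n_markers))
        panel = genome.MarkerPanel(tuple(f"m{i:02d}" for i in range(n_markers)),
                                   ("c",) * n_markers, pos,
                                   ("A",) * n_markers, ("G",) * n_markers)
        pop = simpop.simulate_rils(g, panel, n_lines=n_lines, generations=11, seed=seed)
        return pop.genotypes

    def test_true_order_recovered(self):
        g = self._simulate_chain(5, 200, seed=21)
        _, D = pairwise_tables(g)
        shuffled = [3, 0, 4, 1, 2]
        order = order_markers(shuffled, D)
        assert order in ([0, 1, 2, 3, 4], [4, 3, 2, 1, 0])

    def test_two_markers_trivially_ordered(self):
        g = self._simulate_chain(2, 50, seed=22)
        _, D = pairwise_tables(g)
        assert sorted(order_markers([1, 0], D)) == [0, 1]

    def test_matches_bruteforce_optimum_on_small_instances(self):
        for seed in range(5):
            g = self._simulate_chain(6, 150, seed=30 + seed)
            _, D = pairwise_tables(g)
            order = order_markers(list(range(6)), D)
            best = min(order_objective(list(p), D)
                       for p in itertools.permutations(range(6)))
            assert order_objective(order, D) == best


class TestPlacement:
    def test_cosegregating_marker_attached_to_its_locus(self):
        a = col("A" * 30 + "B" * 30)
        b = a.copy(); b[:6] = B
        c = b.copy(); c[6:12] = np.where(b[6:12] == A, B, A)
        x = b.copy()
        g = np.stack([a, b, c, x], axis=1).astype(np.int8)
        N, D = pairwise_tables(g)
        placements, unplaced = place_markers([3], [0, 1, 2], N, D)
        assert placements[3] == 1 and not unplaced

    def test_symmetrically_ambiguous_marker_unplaced(self):
        half = col("A" * 10 + "B" * 10)
        shared = col("A" * 10 + "B" * 10)
        a = np.concatenate([half, shared])
        c = np.concatenate([1 - half, shared])
        b = a.copy(); b[0] = 1 - b[0]
        d = c.copy(); d[1] = 1 - d[1]
        x = np.concatenate([np.full(20, M, dtype=np.int8), shared])
        x[20] = 1 - x[20]; x[21] = 1 - x[21]
        g = np.stack([a, b, d, c, x], axis=1).astype(np.int8)
        N, D = pairwise_tables(g)
        placements, unplaced = place_markers([4], [0, 1, 2, 3], N, D)
        assert unplaced == [4]

    def test_unique_slot_with_margin_placed(self):
        a = col("A" * 30 + "B" * 30)
        x = a.copy(); x[:3] = B
        b = x.copy(); b[3:6] = np.where(x[3:6] == A, B, A)
        c = col("AB" * 30)
        g = np.stack([a, b, c, x], axis=1).astype(np.int8)
        N, D = pairwise_tables(g)
        placements, unplaced = place_markers([3], [0, 1, 2], N, D)
        assert 3 in placements and placements[3] == 1


class TestDistortion:
    def test_balanced_counts_not_distorted(self):
        g = np.concatenate([np.zeros(94), np.ones(94)]).astype(np.int8)[:, None]
        rep = segregation_chisq(g)[0]
        assert rep["chisq"] == 0.0 and not rep["distorted"]

    def test_strong_distortion_detected(self):
        g = np.concatenate([np.zeros(120), np.ones(68)]).astype(np.int8)[:, None]
        rep = segregation_chisq(g)[0]
        assert rep["chisq"] == pytest.approx(14.38, abs=0.01)
        assert rep["distorted"] and rep["favored"] == "A"

    def test_mild_imbalance_not_significant(self):
        g = np.concatenate([np.zeros(100), np.ones(88)]).astype(np.int8)[:, None]
        rep = segregation_chisq(g)[0]
        assert rep["chisq"] == pytest.approx(0.766, abs=0.01)
        assert not rep["distorted"]

    def test_runs_of_consecutive_distorted_markers(self):
        reports = [
            {"distorted": False, "favored": "-"},
            {"distorted": True, "favored": "A"},
            {"distorted": True, "favored": "A"},
            {"distorted": True, "favored": "B"},
            {"distorted": False, "favored": "-"},
        ]
        runs = linkmap.distortion_runs(reports)
        assert runs == [
            {"start": 1, "end": 2, "length": 2, "favored": "A"},
            {"start": 3, "end": 3, "length": 1, "favored": "B"},
        ]


class TestDoubleCrossovers:
    CM = np.array([0.0, 5.0, 10.0])

    def test_consistent_triple_not_flagged(self):
        g = np.array([[A, A, A]], dtype=np.int8)
        flags, n = double_co_scan([0, 1, 2], self.CM, g)
        assert not flags and n == 0

    def test_sandwiched_opposite_allele_flagged(self):
        g = np.array([[A, B, A]], dtype=np.int8)
        flags, n = double_co_scan([0, 1, 2], self.CM, g)
        assert flags == [(0, 1)] and n == 1

    def test_missing_middle_not_flagged(self):
        g = np.array([[A, M, A]], dtype=np.int8)
        flags, _ = double_co_scan([0, 1, 2], self.CM, g)
        assert not flags

    def test_wide_span_outside_window_not_flagged(self):
        g = np.array([[A, B, A]], dtype=np.int8)
        flags, _ = double_co_scan([0, 1, 2], np.array([0.0, 30.0, 60.0]), g)
        assert not flags
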