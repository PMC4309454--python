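"""Read trimming, demultiplexing, reference building and SNP calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gbsmap import gbsproc, simpop
from gbsmap.gbsproc import (SNPRecord, TagRead, UniqueReference, assign_reads,
                            build_reference, call_base, demultiplex,
                            filter_informative, quality_trim, resolve_deletions,
                            select_one_per_read)


def q(scores):
    return "".join(chr(s + 33) for s in scores)


def read(seq, scores=None, rid="r1"):
    return TagRead(rid, seq, q(scores if scores is not None else [40] * len(seq)))


class TestQualityTrim:
    def test_high_quality_read_unchanged(self):
        r = quality_trim(read("ACGTACGT"))
        assert r.sequence == "ACGTACGT"

    def test_truncates_at_three_prime_most_low_base(self):
        r = quality_trim(read("ACGTA", [30, 30, 30, 10, 30]))
        assert r.sequence == "ACG"

    def test_adapter_removed_before_quality_rule(self):
        adapter = "AGATCGGAAGAGC"
        scores = [30] * 10 + [10] + [35] * (len(adapter) - 1) + [35]
        seq = "ACGTACGTAC" + "T" + adapter
        r = quality_trim(read(seq, scores), adapter=adapter)
        assert r.sequence == "ACGTACGTAC"

    def test_fully_trimmed_read_flagged_discard(self):
        r = quality_trim(read("AC", [5, 30]))
        assert r.discard and r.sequence == ""

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 41), min_size=1, max_size=30))
    def test_cut_lands_on_three_prime_most_low_base(self, scores):
        seq = "A" * len(scores)
        r = quality_trim(read(seq, scores))
        low = [i for i, s in enumerate(scores) if s < 20]
        assert len(r.sequence) == (low[-1] if low else len(scores))


class TestDemultiplex:
    TABLE = {"line1": "ACGT", "line2": "TTAG"}

    def test_exact_barcode_assigned_and_stripped(self):
        per, disc = demultiplex([read("ACGT" + "GGGG")], self.TABLE)
        assert [r.sequence for r in per["line1"]] == ["GGGG"]
        assert disc == 0

    def test_one_mismatch_barcode_discarded(self):
        per, disc = demultiplex([read("ACCT" + "GGGG")], self.TABLE)
        assert disc == 1 and not per["line1"] and not per["line2"]

    def test_empty_table_discards_everything(self):
        per, disc = demultiplex([read("ACGTGGGG"), read("TTTTTTTT")], {})
        assert disc == 2

    def test_conservation_assigned_plus_discarded_equals_input(self, rng):
        reads = [read("".join(rng.choice(list("ACGT"), 12)), rid=f"r{i}")
                 for i in range(200)]
        per, disc = demultiplex(reads, self.TABLE)
        assert sum(len(v) for v in per.values()) + disc == 200

    def test_prefix_barcodes_rejected(self):
        with pytest.raises(ValueError):
            demultiplex([], {"a": "ACG", "b": "ACGT"})


class TestBuildReference:
    def test_redundancy_threshold(self):
        reads = ([read("AAAA", rid=f"a{i}") for i in range(5)]
                 + [read("CCCC", rid=f"c{i}") for i in range(3)]
                 + [read("GGGG", rid=f"g{i}") for i in range(12)])
        ref = build_reference(reads, min_redundancy=4)
        assert set(ref.reads) == {"AAAA", "GGGG"}

    def test_spacer_coordinates(self):
        reads = ([read("A" * 101, rid=f"a{i}") for i in range(4)]
                 + [read("C" * 101, rid=f"c{i}") for i in range(4)])
        ref = build_reference(reads, spacer=200)
        assert ref.total_span == 101 + 200 + 101
        assert ref.offsets[1] - ref.offsets[0] == 301
        assert ref.sequence().count("N") == 200

    def test_all_singletons_error(self):
        with pytest.raises(ValueError):
            build_reference([read("ACGT"), read("CGTA")])

    def test_coordinate_bijection(self):
        ref = UniqueReference(["ACGT", "GGTTCC"], [5, 6], spacer=10)
        seen = set()
        for i, r in enumerate(ref.reads):
            for p in range(len(r)):
                coord = ref.coordinate(i, p)
                assert ref.locate(coord) == (i, p)
                assert coord not in seen
                seen.add(coord)
        with pytest.raises(IndexError):
            ref.locate(ref.offsets[0] + 5)   # spacer coordinate


class TestAssignReads:
    REF = UniqueReference(["AAAAAAAAAA", "CCCCCCCCCC"], [4, 4], spacer=5)

    def test_identical_read_counted_at_its_coordinates(self):
        counts = assign_reads([read("AAAAAAAAAA")], self.REF)
        assert counts[0][:, 0].sum() == 10
        assert counts[1].sum() == 0

    def test_one_mismatch_assigned_with_mismatched_base_counted(self):
        counts = assign_reads([read("AAAAGAAAAA")], self.REF)
        assert counts[0][4, 2] == 1       # G at position 4
        assert counts[0][:, 0].sum() == 9

    def test_equidistant_read_unassigned(self):
        ref = UniqueReference(["AAAA", "AATT"], [4, 4], spacer=5)
        counts = assign_reads([read("AAAT")], ref, max_mismatch=3)
        assert counts[0].sum() == 0 and counts[1].sum() == 0

    def test_distance_above_max_mismatch_unassigned(self):
        counts = assign_reads([read("GGGGGAAAAA")], self.REF, max_mismatch=3)
        assert counts[0].sum() == 0 and counts[1].sum() == 0


class TestCallBase:
    def test_unanimous_call(self):
        assert call_base([20, 0, 0, 0]) == "A"

    def test_frequency_exactly_at_threshold_is_missing(self):
        # 19/20 = 0.95 is not > 0.95
        assert call_base([19, 1, 0, 0]) is None

    def test_even_split_missing(self):
        assert call_base([10, 10, 0, 0]) is None

    def test_below_min_depth_missing(self):
        assert call_base([3, 0, 0, 0], min_depth=4) is None


class TestSNPDetection:
    def test_transition_vs_transversion(self):
        assert SNPRecord.classify("A", "G") == "transition"
        assert SNPRecord.classify("C", "T") == "transition"
        assert SNPRecord.classify("A", "C") == "transversion"

    def test_differing_parent_calls_become_snp(self):
        ref = UniqueReference(["ACGT"], [4], spacer=5)
        ta = {0: ["A", "C", "G", "T"]}
        tb = {0: ["A", "C", "A", "T"]}
        snps, cands = gbsproc.detect_parental_snps(ta, tb, ref)
        assert len(snps) == 1
        assert snps[0].within_read == 2 and snps[0].classification == "transition"
        assert not cands

    def test_one_parent_missing_deferred_to_deletion_resolution(self):
        ref = UniqueReference(["ACGT"], [4], spacer=5)
        ta = {0: ["A", None, "G", "T"]}
        tb = {0: ["A", "C", "G", "T"]}
        snps, cands = gbsproc.detect_parental_snps(ta, tb, ref)
        assert not snps
        assert cands == [(0, 1, "B", "C")]


class TestResolveDeletions:
    CAND = (0, 1, "A", "C")

    def _calls(self, present, bases):
        calls = {f"l{i}": bases[i % len(bases)] for i in range(present)}
        calls.update({f"m{i}": None for i in range(100 - present)})
        return calls

    def test_segregating_majority_presence_is_real_snp(self):
        status, allele = resolve_deletions(self.CAND, self._calls(90, ["C", "T"]))
        assert status == "real_snp" and allele == "T"

    def test_monomorphic_majority_presence_ignored(self):
        status, _ = resolve_deletions(self.CAND, self._calls(90, ["C"]))
        assert status == "ignored"

    def test_low_presence_is_artifact(self):
        status, _ = resolve_deletions(self.CAND, self._calls(40, ["C", "T"]))
        assert status == "artifact"


class TestInformativeFilter:
    def _records(self, called_counts, n_lines):
        recs = []
        for k, called in enumerate(called_counts):
            calls = {f"l{i}": (0 if i % 2 else 1) for i in range(called)}
            calls.update({f"l{i}": -1 for i in range(called, n_lines)})
            recs.append(SNPRecord(k, k, 0, "A", "G", "transition",
                                  quality=10.0, calls=calls))
        return recs

    def test_threshold_at_188_lines(self):
        # ceil(0.85 * 188) = 160: 160 kept, 159 dropped, 188 kept
        recs = self._records([160, 159, 188], 188)
        passing = filter_informative(recs, 188)
        assert [r.coordinate for r in passing] == [0, 2]
        assert recs[1].filter_status == "LOW_PRESENCE"

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        recs = self._records(rng.integers(100, 189, size=40), 188)
        survivors = [len(filter_informative(recs, 188, t))
                     for t in (0.5, 0.7, 0.85, 0.95, 1.0)]
        assert survivors == sorted(survivors, reverse=True)


class TestSelectOnePerRead:
    def _rec(self, coord, read_index, quality):
        return SNPRecord(coord, read_index, coord % 100, "A", "G",
                         "transition", quality=quality)

    def test_highest_quality_survives(self):
        out = select_one_per_read([self._rec(5, 0, 30.0), self._rec(9, 0, 45.0)])
        assert [r.coordinate for r in out] == [9]

    def test_single_snp_unchanged(self):
        out = select_one_per_read([self._rec(5, 0, 30.0)])
        assert len(out) == 1

    def test_quality_tie_broken_by_lowest_coordinate(self):
        out = select_one_per_read([self._rec(9, 0, 40.0), self._rec(5, 0, 40.0)])
        assert [r.coordinate for r in out] == [5]


class TestPipelineIdentity:
    def test_zero_error_pipeline_reproduces_truth(self, small_genome, small_panel,
                                                  small_population):
        """With no sequencing error and depth above the calling floor, the
        called genotype matrix equals the simulated truth exactly at every
        homozygous truth site (the caller reports only homozygous calls, so
        residual F11 heterozygotes are legitimately missing)."""
        sim = simpop.simulate_reads(small_population, small_panel,
                                    depth=simpop.DepthModel(mean=6, fixed=True),
                                    error_rate=0.0, include_parents=True, seed=4)
        result = gbsproc.run_pipeline(sim.reads,
                                      {e: sim.barcodes[e] for e in sim.entities})
        assert result.n_demultiplexed + result.n_discarded == result.n_input_reads
        tag_index = {t: j for j, t in enumerate(sim.tags)}
        cols = [tag_index[result.reference.reads[r.read_index]]
                for r in result.passing]
        truth = small_population.genotypes[:, cols]
        called = result.genotype_matrix()
        hom = (truth == 0) | (truth == 1)
        assert np.array_equal(called[hom], truth[hom])
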