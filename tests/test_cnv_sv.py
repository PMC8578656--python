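"""Copy states, arm/focal rule, SV merging/filters, enrichment, chromothripsis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from intervaltree import IntervalTree

from leukdriver.cnv_sv import (
    ArmModel,
    assign_copy_state,
    classify_arm_focal,
    detect_chromothripsis,
    filter_candidate_regions,
    filter_svs,
    merge_sv_calls,
    sv_enrichment_test,
)


class TestCopyState:
    @pytest.mark.parametrize(
        "log2,state",
        [(-1.5, 0), (-1.1, 1), (-0.7, 1), (-0.3, 2), (0.0, 2), (0.3, 2),
         (0.5, 3), (0.7, 3), (0.9, 4)],
    )
    def test_default_map(self, log2, state):
        assert assign_copy_state(log2) == state

    def test_nan_unassigned(self):
        assert assign_copy_state(float("nan")) is None

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_monotone_in_log2(self, a, b):
        lo, hi = min(a, b), max(a, b)
        assert assign_copy_state(lo) <= assign_copy_state(hi)

    def test_non_monotone_map_rejected(self):
        with pytest.raises(ValueError):
            assign_copy_state(0.0, state_map=[(0.4, True), (0.3, True)])


class TestArmFocal:
    @pytest.fixture
    def arm_model(self):
        return ArmModel(
            arms={"chr1": {"p": [(0, 40_000_000)], "q": [(45_000_000, 95_000_000)]}}
        )

    def test_85_percent_of_arm_is_arm_level(self, arm_model):
        seg = {"contig": "chr1", "start": 45_000_001, "end": 45_000_000 + 42_500_000}
        assert classify_arm_focal(seg, arm_model) == "arm"

    def test_exactly_80_percent_is_focal(self, arm_model):
        seg = {"contig": "chr1", "start": 1, "end": 32_000_000}
        assert classify_arm_focal(seg, arm_model) == "focal"

    def test_small_segment_is_focal(self, arm_model):
        seg = {"contig": "chr1", "start": 1_000_001, "end": 1_001_000}
        assert classify_arm_focal(seg, arm_model) == "focal"

    def test_unmodelled_contig_is_focal(self, arm_model):
        seg = {"contig": "chr9", "start": 1, "end": 90_000_000}
        assert classify_arm_focal(seg, arm_model) == "focal"


def sv_call(pos1, pos2, svtype="DEL", chrom="chr1", strand1="+", strand2="-",
            vaf=0.5):
    return {
        "chrom1": chrom, "pos1": pos1, "strand1": strand1,
        "chrom2": chrom, "pos2": pos2, "strand2": strand2,
        "svtype": svtype, "vaf": vaf,
    }


class TestMergeSvCalls:
    def test_identical_call_from_two_callers_merges(self):
        callsets = {
            "manta": pd.DataFrame([sv_call(1000, 5000)]),
            "delly": pd.DataFrame([sv_call(1000, 5000)]),
        }
        out = merge_sv_calls(callsets)
        assert len(out) == 1
        assert out.loc[0, "n_callers"] == 2

    def test_single_caller_call_dropped(self):
        callsets = {
            "manta": pd.DataFrame([sv_call(1000, 5000)]),
            "delly": pd.DataFrame([sv_call(100_000, 200_000)]),
        }
        assert len(merge_sv_calls(callsets)) == 0

    def test_six_call_fixture_matches_bruteforce_clusters(self):
        """3 callers near one event (one offset beyond tolerance) plus a
        3-caller concordant event; expected support sizes worked out by
        exhaustive pairwise clustering by hand."""
        callsets = {
            "a": pd.DataFrame([sv_call(1000, 5000), sv_call(900_000, 950_000)]),
            "b": pd.DataFrame([sv_call(1100, 5100), sv_call(900_050, 950_050)]),
            "c": pd.DataFrame([sv_call(1500, 5400), sv_call(900_100, 950_100)]),
        }
        out = merge_sv_calls(callsets, tolerance=200)
        # event 1: a+b within 200 bp, c offset 400/300 -> support 2
        # event 2: all three within 100 bp -> support 3
        assert sorted(out["n_callers"]) == [2, 3]
        ev2 = out[out["n_callers"] == 3].iloc[0]
        assert ev2["pos1"] == 900_050  # median of merged positions

    def test_type_mismatch_does_not_merge(self):
        callsets = {
            "a": pd.DataFrame([sv_call(1000, 5000, svtype="DEL")]),
            "b": pd.DataFrame([sv_call(1000, 5000, svtype="DUP", strand2="+")]),
        }
        assert len(merge_sv_calls(callsets)) == 0

    def test_invariant_to_caller_order(self):
        sets = {
            "a": pd.DataFrame([sv_call(1000, 5000), sv_call(7000, 9000)]),
            "b": pd.DataFrame([sv_call(1050, 5050)]),
            "c": pd.DataFrame([sv_call(960, 4980), sv_call(7100, 9100)]),
        }
        out1 = merge_sv_calls(sets)
        out2 = merge_sv_calls(dict(reversed(list(sets.items()))))
        pd.testing.assert_frame_equal(out1, out2)


class TestFilterSvs:
    def test_low_vaf_dropped(self):
        svs = pd.DataFrame([sv_call(1000, 5000, vaf=0.05)])
        retained, counts = filter_svs(svs)
        assert len(retained) == 0 and counts["low_vaf"] == 1

    def test_vaf_at_threshold_retained(self):
        svs = pd.DataFrame([sv_call(1000, 5000, vaf=0.1)])
        retained, _ = filter_svs(svs)
        assert len(retained) == 1

    def test_breakend_in_excluded_region_dropped(self):
        tree = IntervalTree()
        tree.addi(900, 1100)
        svs = pd.DataFrame([sv_call(1000, 5000)])
        retained, counts = filter_svs(svs, {"chr1": tree})
        assert len(retained) == 0 and counts["excluded_region"] == 1

    def test_five_sv_fixture_two_fail(self):
        tree = IntervalTree()
        tree.addi(0, 100)
        svs = pd.DataFrame(
            [
                sv_call(50, 5000),          # breakend in excluded region
                sv_call(1000, 5000, vaf=0.02),  # low VAF
                sv_call(2000, 6000),
                sv_call(3000, 7000),
                sv_call(4000, 8000),
            ]
        )
        retained, counts = filter_svs(svs, {"chr1": tree})
        assert len(retained) == 3
        assert counts.sum() == 2


class TestFilterCandidateRegions:
    @pytest.fixture
    def annotation(self):
        return pd.DataFrame(
            {
                "gene": ["G1", "G2"],
                "contig": ["chr1", "chr1"],
                "start": [1000, 50_000],
                "end": [2000, 60_000],
                "protein_coding": [True, True],
            }
        )

    def _region(self, **kw):
        base = {
            "region_id": "r1", "contig": "chr1", "start": 500, "end": 2500,
            "amplified": False, "deleted": True, "q": 0.001,
        }
        base.update(kw)
        return pd.DataFrame([base])

    def test_q_above_threshold_dropped(self, annotation):
        out = filter_candidate_regions(self._region(q=0.02), annotation)
        assert not out.loc[0, "retained"]
        assert out.loc[0, "drop_reason"] == "q_above_threshold"

    def test_ig_overlap_dropped(self, annotation):
        tree = IntervalTree()
        tree.addi(0, 10_000)
        out = filter_candidate_regions(
            self._region(), annotation, ig_regions={"chr1": tree}
        )
        assert out.loc[0, "drop_reason"] == "immunoglobulin_overlap"

    def test_both_amplified_and_deleted_dropped(self, annotation):
        out = filter_candidate_regions(
            self._region(amplified=True, deleted=True), annotation
        )
        assert out.loc[0, "drop_reason"] == "amplified_and_deleted"

    def test_no_protein_coding_gene_dropped(self, annotation):
        out = filter_candidate_regions(
            self._region(start=10_000, end=20_000), annotation
        )
        assert out.loc[0, "drop_reason"] == "no_protein_coding_gene"

    def test_unexpressed_region_dropped(self, annotation):
        expr = pd.DataFrame(0.0, index=["G1", "G2"], columns=["S1", "S2"])
        out = filter_candidate_regions(self._region(), annotation, expression=expr)
        assert out.loc[0, "drop_reason"] == "no_expressed_gene"

    def test_missing_q_rejected(self, annotation):
        with pytest.raises(ValueError):
            filter_candidate_regions(self._region(q=np.nan), annotation)

    def test_clean_region_retained(self, annotation):
        expr = pd.DataFrame(5.0, index=["G1", "G2"], columns=["S1", "S2"])
        out = filter_candidate_regions(self._region(), annotation, expression=expr)
        assert out.loc[0, "retained"]


class TestSvEnrichment:
    def test_zero_observed_gives_p_one(self, rng):
        p, retained = sv_enrichment_test(
            (0, 100_000),
            [(50_000_000, 50_001_000)] * 5,
            [(0, 100_000_000)],
            rng=rng,
        )
        assert p == 1.0 and not retained

    def test_hotspot_gives_p_zero(self, rng):
        """20 SVs inside a 100 kb region of a 100 Mb arm; per-permutation
        overlap probability ~1e-3 per SV, so 20 simultaneous overlaps are
        effectively impossible (closed-form ~1e-60)."""
        svs = [(10_000, 11_000)] * 20
        p, retained = sv_enrichment_test(
            (0, 100_000), svs, [(0, 100_000_000)], n_perm=1000, rng=rng
        )
        assert p == 0.0 and retained

    def test_pseudocount_variant_strictly_positive(self, rng):
        svs = [(10_000, 11_000)] * 20
        p, _ = sv_enrichment_test(
            (0, 100_000), svs, [(0, 100_000_000)], n_perm=1000, rng=rng,
            pseudocount=True,
        )
        assert p == pytest.approx(1 / 1001)

    def test_region_longer_than_arm_rejected(self, rng):
        with pytest.raises(ValueError):
            sv_enrichment_test((0, 200_000), [], [(0, 100_000)], rng=rng)

    def test_p_on_permutation_lattice(self, rng):
        svs = [(int(x), int(x) + 1000) for x in
               np.random.default_rng(0).integers(0, 9_000_000, 30)]
        p, _ = sv_enrichment_test(
            (0, 1_000_000), svs, [(0, 10_000_000)], n_perm=200, rng=rng
        )
        assert abs(p * 200 - round(p * 200)) < 1e-9


class TestChromothripsis:
    def _segments(self, states):
        rows = []
        pos = 1
        for s in states:
            rows.append({"contig": "chr1", "start": pos, "end": pos + 999_999,
                         "state": s})
            pos += 1_000_000
        return pd.DataFrame(rows)

    def _svs(self, n, lo=100_000, hi=4_500_000):
        rng = np.random.default_rng(1)
        p1 = rng.integers(lo, hi - 1000, n)
        return pd.DataFrame(
            {"chrom1": "chr1", "pos1": p1, "chrom2": "chr1", "pos2": p1 + 1000}
        )

    def test_five_oscillating_segments_six_svs_fires(self):
        events = detect_chromothripsis(self._segments([2, 3, 2, 3, 2]), self._svs(6))
        assert len(events) == 1
        assert events[0]["n_segments"] == 5
        assert events[0]["n_svs"] == 6

    def test_three_segments_do_not_fire(self):
        events = detect_chromothripsis(self._segments([2, 3, 2]), self._svs(6))
        assert events == []

    def test_five_svs_do_not_fire(self):
        events = detect_chromothripsis(self._segments([2, 3, 2, 3, 2]), self._svs(5))
        assert events == []

    def test_three_state_alternation_not_oscillating(self):
        # 2,3,4,3,2 alternates direction but involves three states
        events = detect_chromothripsis(self._segments([2, 3, 4, 3, 2]), self._svs(6))
        assert all(e["n_segments"] < 4 for e in events)

    def test_sv_outside_span_not_counted(self):
        svs = self._svs(5)
        far = pd.DataFrame(
            {"chrom1": ["chr1"], "pos1": [20_000_000], "chrom2": ["chr1"],
             "pos2": [21_000_000]}
        )
        events = detect_chromothripsis(
            self._segments([2, 3, 2, 3, 2]), pd.concat([svs, far])
        )
        assert events == []
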