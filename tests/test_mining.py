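"""Single-dose SNP selection: filters, AAF windows, encoding, segregation filter."""

import numpy as np
import pandas as pd
import pytest

from hexadose import mining
from hexadose.containers import LocusReadCounts
from hexadose.mining import (
    AAF_WINDOWS,
    HOM,
    MISSING,
    NON_HOM,
    CrossType,
    classify_cross_type,
    encode_individuals,
    locus_filters,
    mine_single_dose,
    per_individual_aaf,
    pooled_aaf,
    segregation_filter,
)

from conftest import PARENTS


def make_counts(ref_rows, alt_rows, samples=None):
    """LocusReadCounts from per-locus lists of (ref, alt) per sample."""
    ref = np.asarray(ref_rows, dtype=np.int64)
    alt = np.asarray(alt_rows, dtype=np.int64)
    n_loci, n_samples = ref.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    loci = pd.DataFrame(
        {
            "contig": ["chr01"] * n_loci,
            "pos": np.arange(1, n_loci + 1) * 100,
            "ref": ["A"] * n_loci,
            "alt": ["T"] * n_loci,
        }
    )
    return LocusReadCounts(loci=loci, samples=list(samples), ref_counts=ref, alt_counts=alt)


class TestLocusFilters:
    def test_depth_threshold_is_inclusive(self):
        # depths 10 and 9: exactly-10 counts as covered, 9 as missing
        counts = make_counts([[5, 5, 4, 30]], [[5, 4, 5, 10]])
        kept, missing = locus_filters(counts, min_depth=10, max_missing=0.75)
        np.testing.assert_array_equal(missing[0], [False, True, True, False])

    def test_missing_fraction_boundary(self):
        # locus 0: 1/4 missing (== 0.25, dropped); locus 1: 0/4 missing (kept)
        ref = [[20, 20, 20, 0], [20, 20, 20, 20]]
        alt = [[0, 0, 0, 0], [0, 0, 0, 0]]
        counts = make_counts(ref, alt)
        kept, missing = locus_filters(counts, min_depth=10, max_missing=0.25)
        assert kept.n_loci == 1
        assert kept.loci["pos"].iloc[0] == 200

    def test_parents_excluded_from_missingness(self):
        # both parents uncovered but all progeny covered -> locus survives
        ref = [[0, 0, 20, 20, 20, 20]]
        alt = [[0, 0, 0, 0, 2, 0]]
        counts = make_counts(ref, alt, samples=["P1", "P2", "a", "b", "c", "d"])
        kept, _ = locus_filters(
            counts, min_depth=10, max_missing=0.25, progeny=["a", "b", "c", "d"]
        )
        assert kept.n_loci == 1


class TestPooledAAF:
    def test_hand_computed_fraction(self):
        # 1200 progeny reads, 100 ALT -> pooled AAF 0.0833 (simplex window)
        ref = [[50, 50] + [275, 275, 275, 275]]
        alt = [[0, 50] + [25, 25, 25, 25]]
        counts = make_counts(ref, alt, samples=["P1", "P2", "a", "b", "c", "d"])
        progeny = ["a", "b", "c", "d"]
        kept, missing = locus_filters(counts, progeny=progeny)
        aaf = pooled_aaf(kept, missing, progeny)
        assert aaf[0] == pytest.approx(100 / 1200)
        assert classify_cross_type(aaf[0]) == CrossType.SIMPLEX_ALT_RARE

    def test_missing_points_excluded_from_pool(self):
        ref = [[100, 5, 10]]
        alt = [[0, 0, 10]]  # middle sample depth 5 -> missing
        counts = make_counts(ref, alt)
        kept, missing = locus_filters(counts, max_missing=0.5)
        aaf = pooled_aaf(kept, missing)
        assert aaf[0] == pytest.approx(10 / 120)

    def test_per_individual_aaf(self):
        ref = [[18, 0, 3]]
        alt = [[2, 20, 2]]
        counts = make_counts(ref, alt)
        kept, missing = locus_filters(counts, max_missing=0.75)
        ind = per_individual_aaf(kept, missing, list(counts.samples))
        assert ind[0, 0] == pytest.approx(0.1)
        assert ind[0, 1] == pytest.approx(1.0)
        assert np.isnan(ind[0, 2])  # depth 5 < 10


class TestWindows:
    @pytest.mark.parametrize(
        "aaf,expected",
        [
            (0.0417, CrossType.SIMPLEX_ALT_RARE),  # lower edge inclusive
            (0.0416, CrossType.UNCLASSIFIED),
            (1 / 12, CrossType.SIMPLEX_ALT_RARE),
            (0.1250, CrossType.DOUBLE_SIMPLEX_ALT_RARE),  # half-open handoff
            (2 / 12, CrossType.DOUBLE_SIMPLEX_ALT_RARE),
            (0.2083, CrossType.UNCLASSIFIED),  # upper edge exclusive
            (0.5, CrossType.UNCLASSIFIED),
            (0.7917, CrossType.DOUBLE_SIMPLEX_ALT_COMMON),
            (10 / 12, CrossType.DOUBLE_SIMPLEX_ALT_COMMON),
            (0.8750, CrossType.SIMPLEX_ALT_COMMON),
            (11 / 12, CrossType.SIMPLEX_ALT_COMMON),
            (0.9583, CrossType.UNCLASSIFIED),
            (0.0, CrossType.UNCLASSIFIED),
            (1.0, CrossType.UNCLASSIFIED),
        ],
    )
    def test_half_open_boundaries(self, aaf, expected):
        assert classify_cross_type(aaf) == expected

    def test_windows_are_contiguous_and_centered(self):
        assert AAF_WINDOWS["simplex_alt_rare"][1] == AAF_WINDOWS["double_simplex_alt_rare"][0]
        assert AAF_WINDOWS["double_simplex_alt_common"][1] == AAF_WINDOWS["simplex_alt_common"][0]
        for name, center in [
            ("simplex_alt_rare", 1 / 12),
            ("double_simplex_alt_rare", 2 / 12),
            ("double_simplex_alt_common", 10 / 12),
            ("simplex_alt_common", 11 / 12),
        ]:
            lo, hi = AAF_WINDOWS[name]
            assert lo < center < hi

    def test_nan_and_out_of_range(self):
        assert classify_cross_type(float("nan")) == CrossType.UNCLASSIFIED
        with pytest.raises(ValueError):
            classify_cross_type(1.2)


class TestEncoding:
    def _one_locus(self, pairs, cross_type):
        ref = [[p[0] for p in pairs]]
        alt = [[p[1] for p in pairs]]
        counts = make_counts(ref, alt)
        kept, missing = locus_filters(counts, max_missing=0.99)
        return encode_individuals(
            kept, 0, cross_type, missing[0], 0.08, list(counts.samples)
        )

    def test_any_minority_read_flips_the_call(self):
        m = self._one_locus(
            [(12, 0), (11, 1), (0, 30), (5, 5)], CrossType.SIMPLEX_ALT_RARE
        )
        np.testing.assert_array_equal(m.codes, [HOM, NON_HOM, NON_HOM, NON_HOM])
        assert m.expected_ratio == (1, 1)

    def test_alt_common_mirrors_roles(self):
        m = self._one_locus(
            [(0, 12), (1, 11), (30, 0), (4, 40)], CrossType.SIMPLEX_ALT_COMMON
        )
        np.testing.assert_array_equal(m.codes, [HOM, NON_HOM, NON_HOM, NON_HOM])

    def test_missing_points_stay_missing(self):
        m = self._one_locus([(12, 0), (3, 2), (20, 1)], CrossType.SIMPLEX_ALT_RARE)
        assert m.codes[1] == MISSING
        assert m.class_counts() == (1, 1)

    def test_double_simplex_gets_31_ratio_and_diagnostic(self):
        pairs = [(12, 1)] * 30 + [(12, 0)] * 10
        m = self._one_locus(pairs, CrossType.DOUBLE_SIMPLEX_ALT_RARE)
        assert m.expected_ratio == (3, 1)
        assert np.isfinite(m.loglik_31_vs_41)
        # 30:10 is exactly 3:1 so the 3:1 model must beat 4:1
        assert m.loglik_31_vs_41 > 0

    def test_unclassified_cannot_be_encoded(self):
        with pytest.raises(ValueError):
            self._one_locus([(12, 0)], CrossType.UNCLASSIFIED)


class TestSegregationFilter:
    def _marker(self, non_hom, hom, ratio=(1, 1)):
        codes = np.array([NON_HOM] * non_hom + [HOM] * hom, dtype=np.int8)
        return mining.EncodedMarker(
            contig="chr01",
            pos=1,
            cross_type=CrossType.SIMPLEX_ALT_RARE if ratio == (1, 1) else CrossType.DOUBLE_SIMPLEX_ALT_RARE,
            pooled_aaf=0.08,
            codes=codes,
            expected_ratio=ratio,
        )

    def test_balanced_counts_pass(self):
        kept = segregation_filter([self._marker(51, 51), self._marker(54, 48)])
        assert len(kept) == 2
        assert kept[0].seg_p == pytest.approx(1.0)

    def test_skewed_counts_fail(self):
        assert segregation_filter([self._marker(90, 12)]) == []

    def test_31_ratio_judged_against_31(self):
        kept = segregation_filter([self._marker(77, 25, ratio=(3, 1))])
        assert len(kept) == 1
        assert segregation_filter([self._marker(51, 51, ratio=(3, 1))]) == []

    def test_all_missing_marker_dropped(self):
        m = self._marker(0, 0)
        m.codes = np.array([MISSING, MISSING], dtype=np.int8)
        assert segregation_filter([m]) == []


class TestMineEndToEnd:
    def test_clean_data_recovers_planted_single_dose_loci(self, small_clean_dataset):
        counts, _, scenario, _ = small_clean_dataset
        retained, audit = mine_single_dose(counts, parent_samples=PARENTS)
        truth = scenario.truth.set_index("marker")
        audit = audit.copy()
        audit["marker"] = audit["contig"] + "_" + audit["pos"].astype(str)
        merged = audit.merge(
            truth[["category", "dosage_p1", "dosage_p2"]], left_on="marker", right_index=True
        )
        sums = merged["dosage_p1"] + merged["dosage_p2"]
        is_simplex_truth = sums.isin([1, 11])
        is_ds_truth = sums.isin([2, 10]) & (merged["dosage_p1"] == merged["dosage_p2"])
        called = merged["cross_type"]
        # error-free data classifies every single-dose locus correctly
        assert (
            called[is_simplex_truth].isin(CrossType.SIMPLEX).all()
        ), called[is_simplex_truth].value_counts()
        assert called[is_ds_truth].isin(CrossType.DOUBLE_SIMPLEX).all()
        # no multiplex locus sneaks into the retained set
        retained_ids = {m.marker_id for m in retained}
        bad = merged[merged["marker"].isin(retained_ids) & (merged["category"] == "multiplex")]
        assert bad.empty
        # the segregation filter's nominal false-drop rate is 1%
        n_single = int((is_simplex_truth | is_ds_truth).sum())
        n_kept = int(merged["marker"].isin(retained_ids).sum())
        assert n_kept >= 0.9 * n_single

    def test_audit_covers_all_depth_surviving_loci(self, small_clean_dataset):
        counts, _, _, _ = small_clean_dataset
        retained, audit = mine_single_dose(counts, parent_samples=PARENTS)
        assert {"pooled_aaf", "cross_type", "retained"}.issubset(audit.columns)
        assert audit["retained"].sum() == len(retained)
        assert audit.loc[audit["retained"], "cross_type"].ne(CrossType.UNCLASSIFIED).all()

    def test_markers_to_frame_vcf_codes(self, small_clean_dataset):
        counts, _, _, _ = small_clean_dataset
        progeny = [s for s in counts.samples if s not in PARENTS]
        retained, _ = mine_single_dose(counts, parent_samples=PARENTS)
        frame = mining.markers_to_frame(retained, progeny)
        assert len(frame) == len(retained)
        cell_values = frame[progeny].to_numpy().ravel()
        assert set(cell_values) <= {"0/0", "0/1", "1/1", "./."}
        m0 = retained[0]
        expected_hom = "0/0" if m0.cross_type.endswith("alt_rare") else "1/1"
        hom_idx = int(np.flatnonzero(m0.codes == HOM)[0])
        assert frame.iloc[0][progeny[hom_idx]] == expected_hom
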