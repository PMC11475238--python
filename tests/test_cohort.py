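import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fidmrsi.cohort import (
    classify_roi,
    inter_subject_cv,
    metabolite_qualification,
    ratio_to_tcr,
    resample_map_to_labels,
    roi_mean_concentration,
    roi_pass_fraction,
    summarize_column,
)


class TestPassFraction:
    def test_all_good(self):
        maps = {m: np.full((4, 4, 2), 10.0) for m in ("NAA", "tCr", "tCho", "mIns")}
        assert roi_pass_fraction(maps, np.ones((4, 4, 2), bool)) == 100.0

    def test_half_fail_on_one_metabolite(self):
        maps = {m: np.full((4, 4, 2), 10.0) for m in ("NAA", "tCr", "tCho", "mIns")}
        maps["mIns"][:2] = 50.0
        assert roi_pass_fraction(maps, np.ones((4, 4, 2), bool)) == 50.0

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(2)
        maps = {m: rng.uniform(5, 70, (5, 5, 4)) for m in ("NAA", "tCr", "tCho", "mIns")}
        roi = rng.random((5, 5, 4)) > 0.4
        n_ok = sum(
            all(maps[m][idx] < 40 for m in maps)
            for idx in np.ndindex((5, 5, 4)) if roi[idx]
        )
        assert roi_pass_fraction(maps, roi) == pytest.approx(100 * n_ok / roi.sum())

    def test_empty_roi(self):
        maps = {m: np.ones((2, 2)) for m in ("NAA", "tCr", "tCho", "mIns")}
        with pytest.raises(ValueError):
            roi_pass_fraction(maps, np.zeros((2, 2), bool))


class TestClassification:
    @pytest.mark.parametrize("pct,label", [(85, "good"), (80, "good"), (70, "acceptable"),
                                           (66, "acceptable"), (65.9, "rejected"), (50, "rejected")])
    def test_thresholds(self, pct, label):
        assert classify_roi(pct) == label

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=st.floats(0, 100), b=st.floats(0, 100))
    def test_monotone_in_pass_fraction(self, a, b):
        order = {"rejected": 0, "acceptable": 1, "good": 2}
        lo, hi = sorted((a, b))
        assert order[classify_roi(lo)] <= order[classify_roi(hi)]


class TestQualification:
    def test_rules(self):
        table = pd.DataFrame({
            "NAA": [90.0, 80.0],     # mean 85 -> qualified
            "Gln": [50.0, 40.0],     # mean 45 -> not qualified
            "Asp": [90.0, 90.0],     # discarded: fit in < 10% of brain
            "tCho": [66.0, 66.0],    # boundary: strictly-greater rule
        })
        out = metabolite_qualification(table, brain_fit_fraction_pct={"Asp": 5.0})
        assert out == ["NAA"]

    def test_empty_table(self):
        with pytest.raises(ValueError):
            metabolite_qualification(pd.DataFrame())


class TestRoiMean:
    def test_uniform(self):
        conc = np.full((4, 4), 10.0)
        mean, sd, n = roi_mean_concentration(conc, np.ones_like(conc, bool), np.ones_like(conc, bool))
        assert (mean, sd, n) == (10.0, 0.0, 16)

    def test_half_and_half(self):
        conc = np.array([8.0] * 5 + [12.0] * 5)
        mean, _, _ = roi_mean_concentration(conc, np.ones(10, bool), np.ones(10, bool))
        assert mean == 10.0

    def test_brute_force_equality(self):
        rng = np.random.default_rng(4)
        conc = rng.uniform(2, 12, (6, 6))
        quality = rng.random((6, 6)) > 0.3
        roi = rng.random((6, 6)) > 0.5
        mean, _, n = roi_mean_concentration(conc, quality, roi)
        vals = [conc[i] for i in np.ndindex((6, 6)) if quality[i] and roi[i]]
        assert n == len(vals)
        assert mean == pytest.approx(np.mean(vals), abs=1e-12)

    def test_no_passing_voxels_flagged_not_raised(self):
        mean, sd, n = roi_mean_concentration(np.ones((3, 3)), np.zeros((3, 3), bool),
                                             np.ones((3, 3), bool))
        assert np.isnan(mean) and n == 0


class TestRatios:
    def test_identical_maps_ratio_one(self):
        r, mean, sd = ratio_to_tcr(np.array([7.0, 8.0, 6.5]), np.array([7.0, 8.0, 6.5]))
        np.testing.assert_array_equal(r, 1.0)
        assert mean == 1.0 and sd == 0.0

    def test_cohort_mean_of_subject_ratios(self):
        _, mean, _ = ratio_to_tcr(np.array([3.0, 4.0]), np.array([10.0, 10.0]))
        assert mean == pytest.approx(0.35)

    def test_zero_tcr_flagged(self):
        with pytest.raises(ValueError):
            ratio_to_tcr(np.array([1.0, 2.0]), np.array([0.0, 5.0]))

    def test_invariant_to_water_reference_scaling(self):
        met = np.array([3.0, 4.0, 3.5])
        tcr = np.array([9.0, 10.0, 9.5])
        _, m1, _ = ratio_to_tcr(met, tcr)
        _, m2, _ = ratio_to_tcr(met * 3.7, tcr * 3.7)
        assert m1 == pytest.approx(m2, rel=1e-14)


class TestCV:
    def test_constant_is_zero(self):
        assert inter_subject_cv(np.array([10.0, 10.0, 10.0])) == 0.0

    def test_hand_computed_example(self):
        # sample SD of {8, 10, 12} is 2, mean 10 -> 20%
        assert inter_subject_cv(np.array([8.0, 10.0, 12.0])) == pytest.approx(20.0)

    def test_scale_invariance(self):
        vals = np.array([8.0, 10.0, 12.0, 9.0])
        assert inter_subject_cv(vals) == pytest.approx(inter_subject_cv(vals * 123.4), rel=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            inter_subject_cv(np.array([5.0]))
        with pytest.raises(ValueError):
            inter_subject_cv(np.array([-1.0, 1.0]))


class TestSummaries:
    def test_single_value(self):
        assert summarize_column([4.2]) == (4.2, 4.2, 4.2)

    def test_rounding_modes(self):
        assert summarize_column([9.4, 5.2, 18.6], rounding=0) == (11, 5, 19)
        assert summarize_column([1.234, 2.345], rounding=2) == (1.79, 1.23, 2.35)


class TestResample:
    def test_identity_on_identical_grids(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 5, (4, 5, 3)).astype(float)
        eye = np.eye(4)
        np.testing.assert_array_equal(resample_map_to_labels(m, eye, m.shape, eye), m)

    def test_upsampling_constant_stays_constant(self):
        m = np.full((4, 4, 4), 7.0)
        src = np.diag([2.0, 2.0, 2.0, 1.0])
        dst = np.eye(4)
        out = resample_map_to_labels(m, src, (8, 8, 8), dst)
        inside = ~np.isnan(out)
        assert inside.any()
        assert np.all(out[inside] == 7.0)

    def test_value_support_preserved(self):
        rng = np.random.default_rng(9)
        m = rng.integers(0, 4, (6, 6, 6)).astype(float)
        src = np.diag([2.0, 2.0, 2.0, 1.0])
        out = resample_map_to_labels(m, src, (9, 9, 9), np.eye(4))
        vals = set(np.unique(out[~np.isnan(out)]))
        assert vals <= set(np.unique(m))

    def test_disjoint_grids_error(self):
        shifted = np.eye(4)
        shifted[:3, 3] = 1000.0
        with pytest.raises(ValueError):
            resample_map_to_labels(np.ones((4, 4, 4)), np.eye(4), (4, 4, 4), shifted)
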