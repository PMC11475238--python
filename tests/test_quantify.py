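import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fidmrsi.basis import METABOLITE_SCAN, WATER_SCAN
from fidmrsi.quantify import (
    QualityThresholds,
    RelaxationTable,
    build_quality_mask,
    ernst_angle,
    ernst_factor,
    estimate_concentration,
    mad_outlier_filter,
    voxel_water_concentration,
)


class TestErnst:
    def test_fully_relaxed_limit(self):
        assert ernst_factor(39.0, 1e6, 1500.0) == pytest.approx(math.sin(math.radians(39.0)), rel=1e-9)

    def test_e1_closed_form_tcr_gm(self):
        # TR 450 ms, tCr GM T1 1780 ms -> E1 = exp(-450/1780) = 0.7766
        assert math.exp(-450.0 / 1780.0) == pytest.approx(0.7766, abs=5e-5)

    def test_water_scan_flip_maximizes_signal(self):
        # mean GM/WM water T1 (2000, 1550) = 1775 ms at TR 200 ms; the
        # optimum angle from a brute-force grid search rounds to 27 deg
        t1 = (2000.0 + 1550.0) / 2.0
        grid = np.linspace(0.1, 90.0, 9000)
        best = grid[np.argmax([ernst_factor(th, 200.0, t1) for th in grid])]
        analytic = ernst_angle(200.0, t1)
        assert analytic == pytest.approx(best, abs=0.01)
        assert round(analytic) == 27

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(theta=st.floats(1.0, 179.0), tr=st.floats(10.0, 5000.0), t1=st.floats(100.0, 5000.0))
    def test_factor_bounded_by_fully_relaxed_signal(self, theta, tr, t1):
        f = ernst_factor(theta, tr, t1)
        assert 0.0 < f <= 1.0 + 1e-12

    def test_validation(self):
        with pytest.raises(ValueError):
            ernst_factor(0.0, 450.0, 1500.0)
        with pytest.raises(ValueError):
            ernst_factor(39.0, 450.0, -1.0)


class TestWaterConcentration:
    table = RelaxationTable()

    @pytest.mark.parametrize(
        "fractions,expected",
        [((1.0, 0.0, 0.0), 36.1), ((0.0, 0.0, 1.0), 53.8), ((0.5, 0.5, 0.0), 39.7)],
    )
    def test_compartment_mixture(self, fractions, expected):
        water, _ = voxel_water_concentration(fractions, self.table)
        assert water == pytest.approx(expected, abs=1e-9)

    def test_all_zero_fractions_flagged(self):
        with pytest.raises(ValueError):
            voxel_water_concentration((0.0, 0.0, 0.0), self.table)


class TestConcentration:
    table = RelaxationTable()

    def test_zero_amplitude_gives_zero(self):
        c = estimate_concentration(0.0, 5.0, (1, 0, 0), self.table, METABOLITE_SCAN, WATER_SCAN, "NAA")
        assert c == 0.0

    def test_corrections_cancel_for_matched_scans_and_t1(self):
        # same TR/flip for both scans and equal T1 everywhere: the Ernst
        # factors cancel and C = (A_m/A_w) * 36.1 mol/L in a pure-GM voxel
        table = RelaxationTable(
            metabolite_t1_ms={"NAA": (1500.0, 1500.0)},
            water_t1_gm=1500.0, water_t1_wm=1500.0, water_t1_csf=1500.0,
        )
        c = estimate_concentration(0.25, 5.0, (1, 0, 0), table, METABOLITE_SCAN, METABOLITE_SCAN, "NAA")
        assert c == pytest.approx(0.25 / 5.0 * 36.1e3, rel=1e-12)

    def test_forward_model_inversion_pure_gm(self):
        # generate amplitudes with the forward model at 10 mM NAA and invert
        truth = 10.0
        e_m = ernst_factor(METABOLITE_SCAN.flip_deg, METABOLITE_SCAN.tr_ms,
                           self.table.metabolite_t1("NAA")[0])
        e_w = ernst_factor(WATER_SCAN.flip_deg, WATER_SCAN.tr_ms, self.table.water_t1_gm)
        a_m = truth * e_m
        a_w = 36.1e3 * e_w
        est = estimate_concentration(a_m, a_w, (1, 0, 0), self.table,
                                     METABOLITE_SCAN, WATER_SCAN, "NAA")
        assert est == pytest.approx(truth, rel=0.01)

    def test_gain_invariance_and_monotonicity(self):
        base = estimate_concentration(0.3, 6.0, (0.6, 0.3, 0.1), self.table,
                                      METABOLITE_SCAN, WATER_SCAN, "Glu")
        scaled = estimate_concentration(0.3 * 7.7, 6.0 * 7.7, (0.6, 0.3, 0.1), self.table,
                                        METABOLITE_SCAN, WATER_SCAN, "Glu")
        assert scaled == pytest.approx(base, rel=1e-12)
        more_met = estimate_concentration(0.4, 6.0, (0.6, 0.3, 0.1), self.table,
                                          METABOLITE_SCAN, WATER_SCAN, "Glu")
        more_water = estimate_concentration(0.3, 8.0, (0.6, 0.3, 0.1), self.table,
                                            METABOLITE_SCAN, WATER_SCAN, "Glu")
        assert more_met > base > more_water

    def test_degenerate_voxels_flagged(self):
        with pytest.raises(ValueError):
            estimate_concentration(1.0, 5.0, (0, 0, 1), self.table, METABOLITE_SCAN, WATER_SCAN, "NAA")
        with pytest.raises(KeyError, match="Unknown"):
            estimate_concentration(1.0, 5.0, (1, 0, 0), self.table, METABOLITE_SCAN, WATER_SCAN,
                                   "Unknown")


class TestMadFilter:
    def test_constant_vector_excludes_nothing(self):
        assert not mad_outlier_filter(np.full(10, 3.3)).any()

    def test_single_gross_outlier(self):
        # values 1..10 plus 1000: median 6, MAD 3, threshold 13*3 = 39
        vals = np.array(list(range(1, 11)) + [1000], dtype=float)
        excl = mad_outlier_filter(vals, k=13.0)
        assert excl.sum() == 1 and excl[-1]

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(10, 2, 500)
        vals[::50] += rng.uniform(100, 200, 10)
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        expected = np.abs(vals - med) > 13.0 * mad
        np.testing.assert_array_equal(mad_outlier_filter(vals), expected)

    def test_zero_mad_fallback(self):
        vals = np.array([5.0] * 9 + [100.0])
        excl = mad_outlier_filter(vals)
        assert excl[-1] and excl.sum() == 1

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            mad_outlier_filter(np.array([1.0, 2.0, np.nan, np.nan, np.nan]))


class TestQualityMask:
    def _maps(self, shape=(6, 6, 3)):
        rng = np.random.default_rng(7)
        return {
            "snr": rng.uniform(3, 20, shape),
            "fwhm": rng.uniform(0.03, 0.2, shape),
            "crlb": rng.uniform(5, 60, shape),
            "fit": rng.normal(10, 2, shape),
        }

    def test_snr_just_below_threshold_excluded(self):
        m = {k: np.full((2, 3, 1), v) for k, v in
             [("snr", 10.0), ("fwhm", 0.06), ("crlb", 10.0), ("fit", 5.0)]}
        m["snr"][0, 0, 0] = 4.9
        mask, counts = build_quality_mask(m["snr"], m["fwhm"], m["crlb"], m["fit"])
        assert not mask[0, 0, 0]
        assert counts["snr"] == 1 and counts["passed"] == 5

    def test_all_rules_pass(self):
        mask, counts = build_quality_mask(
            np.full((2, 2, 2), 11.0), np.full((2, 2, 2), 0.06),
            np.full((2, 2, 2), 12.0), np.full((2, 2, 2), 8.0),
        )
        assert mask.all() and counts["passed"] == 8

    def test_counts_match_brute_force(self):
        m = self._maps()
        thresholds = QualityThresholds()
        mask, counts = build_quality_mask(m["snr"], m["fwhm"], m["crlb"], m["fit"],
                                          thresholds=thresholds)
        med = np.median(m["fit"])
        mad = np.median(np.abs(m["fit"] - med))
        n_snr = n_fwhm = n_crlb = n_mad = n_pass = 0
        for idx in np.ndindex(m["snr"].shape):
            f_snr = m["snr"][idx] < thresholds.snr_min
            f_fwhm = m["fwhm"][idx] > thresholds.fwhm_max_ppm
            f_crlb = m["crlb"][idx] > thresholds.crlb_max_percent
            f_mad = abs(m["fit"][idx] - med) > thresholds.mad_k * mad
            n_snr += f_snr
            n_fwhm += f_fwhm
            n_crlb += f_crlb
            n_mad += f_mad
            ok = not (f_snr or f_fwhm or f_crlb or f_mad)
            n_pass += ok
            assert mask[idx] == ok
        assert counts == {"snr": n_snr, "fwhm": n_fwhm, "crlb": n_crlb, "mad": n_mad,
                          "passed": n_pass, "domain": m["snr"].size}

    def test_missing_map_named(self):
        with pytest.raises(ValueError, match="fwhm"):
            build_quality_mask(np.ones((2, 2)), None, np.ones((2, 2)), np.ones((2, 2)))
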