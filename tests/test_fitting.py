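import numpy as np
import pytest

from fidmrsi.basis import (
    METABOLITE_SCAN,
    Resonance,
    build_basis_set,
    build_water_basis,
    fid_to_spectrum,
)
from fidmrsi.fitting import (
    EvaluationRange,
    crlb_percent,
    estimate_fwhm,
    estimate_snr,
    fit_spectrum,
    fit_water,
    pseudo_replica_noise_sd,
)


@pytest.fixture(scope="module")
def three_compound_basis(met_basis):
    return met_basis.subset(["NAA", "tCr", "tCho"])


@pytest.fixture(scope="module")
def mixture(three_compound_basis):
    truth = np.array([1.0, 2.0, 0.5])
    fid = truth @ three_compound_basis.signals
    spec, _ = fid_to_spectrum(fid, three_compound_basis.sampling_bandwidth)
    return truth, fid, spec


def _masked_model(basis, sel, params):
    """Independent forward model used for the finite-difference oracle."""
    m = len(basis.compound_names)
    amps, (shift, damp, phase) = params[:m], params[m:]
    t = np.arange(basis.n_points) / basis.sampling_bandwidth
    fid = (amps @ basis.signals) * np.exp((2j * np.pi * shift - damp) * t)
    spec = np.fft.fftshift(np.fft.fft(fid)) / np.sqrt(basis.n_points)
    return spec[sel] * np.exp(1j * phase)


def test_noiseless_mixture_recovered(three_compound_basis, mixture):
    truth, _, spec = mixture
    res = fit_spectrum(spec, three_compound_basis, noise_sd=0.01)
    np.testing.assert_allclose(res.amplitudes, truth, rtol=1e-4)
    assert abs(res.global_shift_hz) < 0.01
    assert res.extra_damping < 0.1
    assert abs(res.zero_order_phase) < 1e-3


def test_signal_in_excluded_lipid_band_does_not_bias_amplitudes(three_compound_basis, mixture):
    truth, _, spec = mixture
    ppm = three_compound_basis.ppm_axis
    contaminated = spec.copy()
    bump = (ppm >= 1.4) & (ppm <= 1.6)
    contaminated[bump] += 50.0 * np.exp(1j * 0.7)
    a = fit_spectrum(spec, three_compound_basis, noise_sd=0.01).amplitudes
    b = fit_spectrum(contaminated, three_compound_basis, noise_sd=0.01).amplitudes
    np.testing.assert_allclose(a, b, rtol=1e-6)


def test_residual_at_optimum_not_worse_than_truth(three_compound_basis, mixture):
    truth, _, spec = mixture
    res = fit_spectrum(spec, three_compound_basis, noise_sd=0.01)
    sel = EvaluationRange().mask(three_compound_basis.ppm_axis)
    truth_resid = np.linalg.norm(
        _masked_model(three_compound_basis, sel, np.concatenate([truth, [0, 0, 0]])) - spec[sel]
    )
    assert res.residual_norm <= truth_resid + 1e-9


def test_amplitudes_always_nonnegative(three_compound_basis, mixture):
    _, fid, _ = mixture
    rng = np.random.default_rng(3)
    for _ in range(5):
        noisy = fid + 2.0 * (rng.standard_normal(fid.size) + 1j * rng.standard_normal(fid.size))
        spec, _ = fid_to_spectrum(noisy, three_compound_basis.sampling_bandwidth)
        res = fit_spectrum(spec, three_compound_basis, noise_sd=2.0)
        assert np.all(res.amplitudes >= 0)


def test_crlb_scales_linearly_with_noise(three_compound_basis, mixture):
    _, _, spec = mixture
    c1 = fit_spectrum(spec, three_compound_basis, noise_sd=0.05).crlb_percent
    c2 = fit_spectrum(spec, three_compound_basis, noise_sd=0.10).crlb_percent
    np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-6)


def test_crlb_block_diagonal_for_separated_singlets():
    # spectrally separated compounds: the amplitude Fisher matrix is
    # block-diagonal, so co-fitting the second compound leaves the first
    # compound's absolute CRLB unchanged; overlapping compounds inflate it
    def abs_crlb_a(table):
        basis = build_basis_set(table, METABOLITE_SCAN, include_mm=False)
        specs = np.fft.fftshift(np.fft.fft(basis.signals, axis=1), axes=1) / np.sqrt(basis.n_points)
        jac = specs.T
        amps = np.ones(len(table))
        return crlb_percent(jac, 0.05, amps)[0] * amps[0]

    alone = abs_crlb_a({"A": [Resonance(2.0, 1.0, 0.09)]})
    separated = abs_crlb_a({"A": [Resonance(2.0, 1.0, 0.09)],
                            "B": [Resonance(3.5, 1.0, 0.09)]})
    overlapping = abs_crlb_a({"A": [Resonance(2.0, 1.0, 0.09)],
                              "B": [Resonance(2.005, 1.0, 0.09)]})
    assert separated == pytest.approx(alone, rel=0.01)
    assert overlapping > 1.5 * alone


def test_crlb_against_finite_difference_jacobian(three_compound_basis, mixture):
    truth, _, spec = mixture
    sd = 0.05
    res = fit_spectrum(spec, three_compound_basis, noise_sd=sd)
    sel = EvaluationRange().mask(three_compound_basis.ppm_axis)
    params = np.concatenate(
        [res.amplitudes, [res.global_shift_hz, res.extra_damping, res.zero_order_phase]]
    )
    steps = [1e-6, 1e-6, 1e-6, 1e-5, 1e-5, 1e-7]
    cols = []
    for i, h in enumerate(steps):
        up, dn = params.copy(), params.copy()
        up[i] += h
        dn[i] -= h
        cols.append(
            (_masked_model(three_compound_basis, sel, up)
             - _masked_model(three_compound_basis, sel, dn)) / (2 * h)
        )
    jac = np.stack(cols, axis=1)
    oracle = crlb_percent(jac, sd, res.amplitudes)
    np.testing.assert_allclose(res.crlb_percent, oracle, rtol=0.01)


def test_snr_halves_when_noise_doubles(three_compound_basis, mixture):
    _, _, spec = mixture
    res = fit_spectrum(spec, three_compound_basis, noise_sd=0.05)
    s1 = estimate_snr(res, three_compound_basis, noise_sd=0.05)
    s2 = estimate_snr(res, three_compound_basis, noise_sd=0.10)
    assert s1 == pytest.approx(2 * s2, rel=1e-12)
    with pytest.raises(ValueError):
        estimate_snr(res, three_compound_basis, noise_sd=0.0)


def test_pseudo_replica_agrees_with_known_noise_level(three_compound_basis, mixture):
    _, fid, _ = mixture
    sd = 0.5
    rng = np.random.default_rng(11)
    noisy = fid + sd * (rng.standard_normal(fid.size) + 1j * rng.standard_normal(fid.size))
    est = pseudo_replica_noise_sd(noisy, three_compound_basis.sampling_bandwidth,
                                  n_replicas=100, seed=1)
    assert est == pytest.approx(sd, rel=0.10)


def test_fwhm_closed_form():
    # effective T2* of 100 ms -> 3.183 Hz -> 0.0107 ppm at 297.2 MHz
    basis = build_basis_set({"tCr": [Resonance(3.02, 1.0, 0.1)]}, METABOLITE_SCAN,
                            include_mm=False)
    fid = basis.signals[0]
    spec, _ = fid_to_spectrum(fid, basis.sampling_bandwidth)
    res = fit_spectrum(spec, basis, noise_sd=0.01)
    fwhm = estimate_fwhm(res, basis)
    assert fwhm == pytest.approx(1 / (np.pi * 0.1) / 297.2, rel=1e-3)
    assert fwhm == pytest.approx(0.0107, abs=2e-4)


def test_fitted_damping_adds_to_basis_linewidth(met_basis):
    t = np.arange(met_basis.n_points) / met_basis.sampling_bandwidth
    gamma = 20.0
    fid = (2.0 * met_basis.signal("tCr")) * np.exp(-gamma * t)
    spec, _ = fid_to_spectrum(fid, met_basis.sampling_bandwidth)
    basis = met_basis.subset(["tCr"])
    res = fit_spectrum(spec, basis, noise_sd=0.01)
    assert res.extra_damping == pytest.approx(gamma, rel=0.01)
    expected = (1 / 0.09 + gamma) / np.pi / 297.2
    assert estimate_fwhm(res, basis) == pytest.approx(expected, rel=0.01)


def test_water_fit_noiseless_recovery():
    wb = build_water_basis()
    spec, _ = fid_to_spectrum(1234.5 * wb.signal("water"), wb.sampling_bandwidth)
    res = fit_water(spec, wb)
    assert res.amplitude("water") == pytest.approx(1234.5, rel=1e-6)


def test_water_fit_flags_empty_voxel():
    wb = build_water_basis()
    rng = np.random.default_rng(0)
    noise = 0.3 * (rng.standard_normal(wb.n_points) + 1j * rng.standard_normal(wb.n_points))
    res = fit_water(noise, wb, noise_sd=0.3)
    assert "no-signal" in res.flags
    assert res.amplitude("water") == 0.0


def test_nonfinite_spectrum_rejected(three_compound_basis):
    bad = np.full(three_compound_basis.n_points, np.nan, dtype=complex)
    with pytest.raises(ValueError):
        fit_spectrum(bad, three_compound_basis)


def test_overlapping_evaluation_ranges_rejected():
    with pytest.raises(ValueError):
        EvaluationRange(((0.2, 1.5), (1.2, 3.88)))
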