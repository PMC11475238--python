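"""Self-validation studies: parameter recovery, calibration and invariances.

Each function runs a small, fully seeded synthetic study through the actual
pipeline components and returns the measured quantity, so that calibration
claims (CRLB consistency, CV recovery, lipid-removal efficacy, gain
invariance, mask-rule bookkeeping) are always recomputed rather than quoted.
Problem sizes are desk-scale; see docs/methods.md for the rationale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .basis import build_basis_set, build_water_basis, default_resonance_table, fid_to_spectrum
from .fitting import fit_spectrum
from .lipid import auto_beta, extract_lipid_basis, l2_lipid_removal
from .phantom import ROISpec, assign_truth_concentrations, build_phantom, synthesize_subject
from .pipeline import PipelineConfig, process_subject, run_pipeline, substream_seed
from .quantify import QualityThresholds, build_quality_mask

STUDY_METABOLITES = ("NAA", "tCr", "tCho", "Glu", "mIns")
TWO_ROI_SPEC = [
    ROISpec("deep-WM", 0.30, 0.60, tissue="WM"),
    ROISpec("cortical-GM", 0.72, 0.90, tissue="GM"),
]


def noiseless_recovery_errors(seed: int, grid=(16, 16, 8), max_csf: float = 0.3) -> pd.DataFrame:
    """Noiseless end-to-end recovery: per-voxel relative error [%] vs truth.

    Fits every labeled brain voxel of one noiseless subject, quantifies it,
    and compares with the generator's tissue-volume truth
    (voxel truth / (1 - f_CSF)) wherever f_CSF < ``max_csf``.
    """
    cfg = PipelineConfig(grid_shape=grid, n_subjects=2, noise_sd=0.0, lipid_removal=False,
                         seed=seed)
    phantom = build_phantom(grid, seed=seed)
    assign_truth_concentrations(phantom, n_subjects=2, inter_subject_cv=10.0,
                                seed=substream_seed(seed, -1, "truth"))
    basis = build_basis_set(default_resonance_table(), phantom.metabolite_acq)
    water_basis = build_water_basis(phantom.water_acq)
    ds = synthesize_subject(phantom, 0, basis, noise_sd=0.0, seed=seed)
    res = process_subject(phantom, ds, basis, water_basis, cfg)

    sel = res.fitted_mask & (phantom.f_csf < max_csf)
    rows = []
    for c in STUDY_METABOLITES:
        truth = phantom.truth_concentrations[c][0] / np.clip(1.0 - phantom.f_csf, 1e-9, None)
        est = res.concentration[c]
        ok = sel & np.isfinite(est) & (truth > 0)
        err = 100.0 * np.abs(est[ok] - truth[ok]) / truth[ok]
        rows.append({"metabolite": c, "n_voxels": int(ok.sum()),
                     "max_err_pct": float(err.max()), "mean_err_pct": float(err.mean())})
    return pd.DataFrame(rows).set_index("metabolite")


def crlb_calibration(seed: int, n_reps: int = 200, noise_sd: float = 0.9) -> pd.DataFrame:
    """Monte-Carlo amplitude SD vs mean reported CRLB on one voxel spectrum."""
    basis = build_basis_set(default_resonance_table())
    truth = {"NAA": 3.8, "NAAG": 0.5, "tCr": 2.2, "tCho": 0.6, "Glu": 3.0,
             "Gln": 0.8, "mIns": 2.2, "MM": 1.6}
    amps = np.array([truth[c] for c in basis.compound_names])
    fid0 = amps @ basis.signals
    rng = np.random.default_rng(seed)
    n = basis.n_points
    ests, crlbs = [], []
    for _ in range(n_reps):
        fid = fid0 + noise_sd * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
        spec, _ = fid_to_spectrum(fid, basis.sampling_bandwidth)
        fit = fit_spectrum(spec, basis, noise_sd=noise_sd)
        ests.append(fit.amplitudes)
        crlbs.append(fit.crlb_percent)
    ests = np.array(ests)
    crlbs = np.array(crlbs)
    rows = []
    for i, c in enumerate(basis.compound_names):
        if c not in STUDY_METABOLITES:
            continue
        mc_sd = float(ests[:, i].std(ddof=1))
        crlb_abs = float(np.mean(crlbs[:, i] * ests[:, i] / 100.0))
        rows.append({"metabolite": c, "mc_sd": mc_sd, "mean_crlb_abs": crlb_abs,
                     "ratio": mc_sd / crlb_abs})
    return pd.DataFrame(rows).set_index("metabolite")


def cv_recovery(seed: int, n_subjects: int = 20, true_cv: float = 10.0,
                grid=(16, 16, 8)) -> pd.DataFrame:
    """Estimated inter-subject CVs for a cohort generated at ``true_cv``."""
    cfg = PipelineConfig(grid_shape=grid, n_subjects=n_subjects, inter_subject_cv=true_cv,
                         seed=seed, roi_spec=TWO_ROI_SPEC, lipid_removal=False)
    report = run_pipeline(cfg)
    cv = report.cv_table.drop(index=["Mean", "Min", "Max"])
    return cv[list(STUDY_METABOLITES)]


def lipid_removal_error(seed: int, grid=(16, 16, 8), lipid_amplitude: float = 5.0) -> float:
    """Relative NAA error [%] after L2 removal vs the lipid-free fit.

    Fits the most contaminated peripheral brain voxel of a noiseless subject
    generated twice (with and without scalp lipid) and compares the fitted
    NAA amplitudes after removal at the automatically chosen beta.
    """
    phantom = build_phantom(grid, seed=seed)
    assign_truth_concentrations(phantom, n_subjects=2, seed=seed + 1)
    basis = build_basis_set(default_resonance_table(), phantom.metabolite_acq)
    clean = synthesize_subject(phantom, 0, basis, noise_sd=0.0, seed=seed)
    dirty = synthesize_subject(phantom, 0, basis, noise_sd=0.0,
                               lipid_amplitude=lipid_amplitude, seed=seed)
    spec_c, ppm = fid_to_spectrum(clean.metabolite_fids, basis.sampling_bandwidth)
    spec_d, _ = fid_to_spectrum(dirty.metabolite_fids, basis.sampling_bandwidth)
    lb = extract_lipid_basis(spec_d, phantom.scalp_mask, n_components=8)
    beta = auto_beta(spec_d[phantom.brain_mask], lb, ppm)

    periph = np.argwhere(phantom.brain_mask & (phantom.rho > 0.9))
    contamination = [np.sum(np.abs(spec_d[tuple(i)] - spec_c[tuple(i)]) ** 2) for i in periph]
    vox = tuple(periph[int(np.argmax(contamination))])
    ref = fit_spectrum(spec_c[vox], basis, noise_sd=0.05).amplitude("NAA")
    removed = fit_spectrum(l2_lipid_removal(spec_d[vox], lb, beta), basis,
                           noise_sd=0.05).amplitude("NAA")
    return float(100.0 * abs(removed - ref) / ref)


def gain_invariance(seed: int, gain: float = 37.5, grid=(16, 16, 8),
                    n_voxels: int = 8, noise_sd: float = 0.9) -> float:
    """Max relative concentration change under a global receiver-gain change."""
    cfg = PipelineConfig(grid_shape=grid, n_subjects=2, noise_sd=noise_sd, seed=seed,
                         roi_spec=TWO_ROI_SPEC, lipid_removal=False)
    phantom = build_phantom(grid, roi_spec=TWO_ROI_SPEC, seed=seed)
    assign_truth_concentrations(phantom, n_subjects=2, inter_subject_cv=10.0,
                                seed=substream_seed(seed, -1, "truth"))
    basis = build_basis_set(default_resonance_table(), phantom.metabolite_acq)
    water_basis = build_water_basis(phantom.water_acq)
    ds = synthesize_subject(phantom, 0, basis, noise_sd=noise_sd, seed=seed)

    spectra, _ = fid_to_spectrum(ds.metabolite_fids, basis.sampling_bandwidth)
    water_spectra, _ = fid_to_spectrum(ds.water_fids, water_basis.sampling_bandwidth)
    voxels = [tuple(v) for v in np.argwhere(phantom.roi_labels > 0)[::max(1, (phantom.roi_labels > 0).sum() // n_voxels)][:n_voxels]]

    from .fitting import fit_water
    from .quantify import estimate_concentration

    worst = 0.0
    for vox in voxels:
        concs = []
        frac = tuple(phantom.fraction_maps[:, vox[0], vox[1], vox[2]])
        for g in (1.0, gain):
            fit = fit_spectrum(g * spectra[vox], basis, noise_sd=g * noise_sd)
            wfit = fit_water(g * water_spectra[vox], water_basis, noise_sd=g * noise_sd)
            concs.append({
                c: estimate_concentration(fit.amplitude(c), wfit.amplitude("water"), frac,
                                          cfg.relaxation, phantom.metabolite_acq,
                                          phantom.water_acq, c)
                for c in STUDY_METABOLITES
            })
        for c in STUDY_METABOLITES:
            if concs[0][c] > 0:
                worst = max(worst, abs(concs[1][c] - concs[0][c]) / concs[0][c])
    return worst


def mask_oracle_mismatch(seed: int, grid=(32, 32, 16)) -> tuple[int, dict, dict]:
    """Mask exclusion counts vs an independent per-voxel brute-force recount."""
    rng = np.random.default_rng(seed)
    snr = rng.uniform(3, 20, grid)
    fwhm = rng.uniform(0.03, 0.2, grid)
    crlb = rng.uniform(5, 60, grid)
    fit_vals = rng.normal(10, 2, grid)
    fit_vals[rng.random(grid) < 0.002] += 500.0
    thresholds = QualityThresholds()
    mask, counts = build_quality_mask(snr, fwhm, crlb, fit_vals, thresholds=thresholds)

    med = np.median(fit_vals)
    mad = np.median(np.abs(fit_vals - med))
    brute = {"snr": 0, "fwhm": 0, "crlb": 0, "mad": 0, "passed": 0, "domain": int(np.prod(grid))}
    mismatch = 0
    for idx in np.ndindex(grid):
        f = {
            "snr": snr[idx] < thresholds.snr_min,
            "fwhm": fwhm[idx] > thresholds.fwhm_max_ppm,
            "crlb": crlb[idx] > thresholds.crlb_max_percent,
            "mad": abs(fit_vals[idx] - med) > thresholds.mad_k * mad,
        }
        for k, v in f.items():
            brute[k] += v
        ok = not any(f.values())
        brute["passed"] += ok
        mismatch += int(mask[idx] != ok)
    mismatch += sum(counts[k] != brute[k] for k in brute)
    return mismatch, counts, brute
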