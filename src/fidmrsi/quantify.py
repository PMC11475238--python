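"""Water-referenced absolute quantification and quality masking.

Converts fitted metabolite amplitudes to molar concentration estimates via
the unsuppressed water reference, correcting for tissue composition
(GM/WM/CSF partial volume) and T1 saturation at short TR through
per-compartment Ernst factors.  Also implements the spectral quality mask:
tCr SNR, tCr linewidth, per-metabolite CRLB, and a median-absolute-deviation
outlier filter on the fit values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

# literature T1 relaxation times [ms] at 7 T for (GM, WM)
DEFAULT_METABOLITE_T1_MS: dict[str, tuple[float, float]] = {
    "Asp": (1000.0, 1000.0),
    "tCho": (1510.0, 1320.0),
    "tCr": (1780.0, 1740.0),
    "GABA": (1100.0, 1200.0),
    "Glu": (1610.0, 1750.0),
    "Gln": (1540.0, 1740.0),
    "Gly": (1400.0, 1400.0),
    "GSH": (1140.0, 1060.0),
    "mIns": (1280.0, 1190.0),
    "NAA": (1535.0, 1545.0),
    "NAAG": (1210.0, 940.0),
    "Ser": (1400.0, 1400.0),
    "Tau": (2150.0, 2090.0),
}


@dataclass
class RelaxationTable:
    """T1 times [ms] and compartment water concentrations [mol/L]."""

    metabolite_t1_ms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_METABOLITE_T1_MS)
    )
    water_t1_gm: float = 2000.0
    water_t1_wm: float = 1550.0
    water_t1_csf: float = 4300.0  # no published table value; long-T1 default
    water_gm_mol_l: float = 36.1
    water_wm_mol_l: float = 43.3
    water_csf_mol_l: float = 53.8

    def __post_init__(self) -> None:
        for comp, (a, b) in self.metabolite_t1_ms.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"non-positive T1 for {comp}")
        for v in (self.water_t1_gm, self.water_t1_wm, self.water_t1_csf,
                  self.water_gm_mol_l, self.water_wm_mol_l, self.water_csf_mol_l):
            if v <= 0:
                raise ValueError("relaxation table entries must be positive")

    def metabolite_t1(self, compound: str) -> tuple[float, float]:
        try:
            return self.metabolite_t1_ms[compound]
        except KeyError:
            raise KeyError(f"no T1 entry for compound {compound!r}") from None


@dataclass(frozen=True)
class QualityThresholds:
    """Voxel exclusion rules of the spectral quality mask."""

    snr_min: float = 5.0
    fwhm_max_ppm: float = 0.15
    crlb_max_percent: float = 40.0
    mad_k: float = 13.0

    def __post_init__(self) -> None:
        if min(self.snr_min, self.fwhm_max_ppm, self.crlb_max_percent, self.mad_k) <= 0:
            raise ValueError("thresholds must be positive")


def ernst_factor(theta_deg: float, tr_ms: float, t1_ms: float) -> float:
    """Steady-state signal factor sin(theta)*(1-E1)/(1-cos(theta)*E1).

    E1 = exp(-TR/T1).  This is the saturation weighting of a short-TR
    gradient-echo readout; dividing it out corrects T1 saturation.
    """
    if t1_ms <= 0 or tr_ms <= 0:
        raise ValueError("TR and T1 must be positive")
    if not (0.0 < theta_deg < 180.0):
        raise ValueError("flip angle must be in (0, 180) degrees")
    e1 = math.exp(-tr_ms / t1_ms)
    th = math.radians(theta_deg)
    return math.sin(th) * (1.0 - e1) / (1.0 - math.cos(th) * e1)


def ernst_angle(tr_ms: float, t1_ms: float) -> float:
    """Flip angle [deg] maximizing the steady-state signal: acos(exp(-TR/T1))."""
    if t1_ms <= 0 or tr_ms <= 0:
        raise ValueError("TR and T1 must be positive")
    return math.degrees(math.acos(math.exp(-tr_ms / t1_ms)))


def voxel_water_concentration(
    fractions: tuple[float, float, float],
    table: RelaxationTable,
    water_acq=None,
) -> tuple[float, float]:
    """Total water content and its effective Ernst factor for one voxel.

    Returns ``(water_mol_l, e_water_eff)`` where
    water_mol_l = f_GM*36.1 + f_WM*43.3 + f_CSF*53.8 and e_water_eff is the
    water-content-weighted mean of the per-compartment Ernst factors of the
    reference scan.  With ``water_acq=None`` the relaxation weighting is
    skipped (e_water_eff = 1).
    """
    f_gm, f_wm, f_csf = fractions
    for f in fractions:
        if not (0.0 <= f <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
    if f_gm + f_wm + f_csf > 1.0 + 1e-5:  # tolerance for float32 map storage
        raise ValueError("fractions sum above 1")
    if f_gm + f_wm + f_csf <= 0.0:
        raise ValueError("all-zero tissue fractions: voxel has no water compartment")
    concs = (table.water_gm_mol_l, table.water_wm_mol_l, table.water_csf_mol_l)
    water = f_gm * concs[0] + f_wm * concs[1] + f_csf * concs[2]
    if water_acq is None:
        return water, 1.0
    t1s = (table.water_t1_gm, table.water_t1_wm, table.water_t1_csf)
    weighted = sum(
        f * c * ernst_factor(water_acq.flip_deg, water_acq.tr_ms, t1)
        for f, c, t1 in zip(fractions, concs, t1s)
    )
    return water, weighted / water


def metabolite_ernst_eff(
    compound: str,
    fractions: tuple[float, float, float],
    table: RelaxationTable,
    met_acq,
) -> float:
    """Tissue-fraction-weighted metabolite Ernst factor (GM/WM only)."""
    f_gm, f_wm, _ = fractions
    tissue = f_gm + f_wm
    if tissue <= 0:
        raise ValueError("no GM/WM tissue in voxel")
    t1_gm, t1_wm = table.metabolite_t1(compound)
    e_gm = ernst_factor(met_acq.flip_deg, met_acq.tr_ms, t1_gm)
    e_wm = ernst_factor(met_acq.flip_deg, met_acq.tr_ms, t1_wm)
    return (f_gm * e_gm + f_wm * e_wm) / tissue


def estimate_concentration(
    met_amp: float,
    water_amp: float,
    fractions: tuple[float, float, float],
    table: RelaxationTable,
    met_acq,
    water_acq,
    compound: str,
) -> float:
    """Molar concentration estimate [mM] for one voxel and compound.

    C = (A_met / A_water) * W(voxel) * (E_water_eff / E_met_eff) / (1 - f_CSF)

    where W is the voxel water content in mM, E_* are effective Ernst
    factors, and the 1/(1 - f_CSF) term normalizes the (CSF-free) metabolite
    signal to the tissue volume.  Scale-invariant to receiver gain because
    only the amplitude ratio enters.
    """
    if water_amp <= 0:
        raise ValueError("water amplitude must be positive")
    f_csf = fractions[2]
    if f_csf >= 1.0 - 1e-9:
        raise ValueError("pure-CSF voxel: no tissue to quantify")
    if met_amp == 0.0:
        return 0.0
    water_mol_l, e_w = voxel_water_concentration(fractions, table, water_acq)
    e_m = metabolite_ernst_eff(compound, fractions, table, met_acq)
    water_mm = water_mol_l * 1000.0
    return (met_amp / water_amp) * water_mm * (e_w / e_m) / (1.0 - f_csf)


def mad_outlier_filter(values: np.ndarray, k: float = 13.0) -> np.ndarray:
    """Boolean exclusion mask: |v - median| > k * MAD (raw, unscaled MAD).

    With MAD = 0 but unequal values present, falls back to excluding values
    that deviate from the median by more than a relative tolerance.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 5:
        raise ValueError("need at least 5 finite values for MAD filtering")
    med = np.median(values[finite])
    dev = np.abs(values - med)
    mad = np.median(dev[finite])
    excluded = np.zeros(values.shape, dtype=bool)
    if mad == 0.0:
        if np.any(dev[finite] > 0):
            log.warning("MAD is zero with outliers present; falling back to relative tolerance")
            excluded[finite] = dev[finite] > 1e-9 * max(abs(med), 1.0)
    else:
        excluded[finite] = dev[finite] > k * mad
    excluded[~finite] = True
    return excluded


def build_quality_mask(
    snr_map: np.ndarray,
    fwhm_ppm_map: np.ndarray,
    crlb_percent_map: np.ndarray,
    fit_value_map: np.ndarray,
    thresholds: QualityThresholds = QualityThresholds(),
    domain_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """Per-voxel quality mask for one compound, with per-rule exclusion counts.

    A voxel passes iff SNR >= snr_min AND FWHM <= fwhm_max AND
    CRLB <= crlb_max AND it is not a MAD outlier of the fit values.  The MAD
    statistics are computed over the domain (brain) voxels only.
    """
    maps = {"snr": snr_map, "fwhm": fwhm_ppm_map, "crlb": crlb_percent_map, "fit": fit_value_map}
    for name, m in maps.items():
        if m is None:
            raise ValueError(f"missing required map: {name}")
    shape = snr_map.shape
    domain = np.ones(shape, dtype=bool) if domain_mask is None else domain_mask.astype(bool)

    fail_snr = domain & ~(snr_map >= thresholds.snr_min)
    fail_fwhm = domain & ~(fwhm_ppm_map <= thresholds.fwhm_max_ppm)
    fail_crlb = domain & ~(crlb_percent_map <= thresholds.crlb_max_percent)
    mad_excl = np.zeros(shape, dtype=bool)
    vals = fit_value_map[domain]
    if np.isfinite(vals).sum() >= 5:
        mad_excl[domain] = mad_outlier_filter(vals, thresholds.mad_k)
    fail_mad = domain & mad_excl

    mask = domain & ~(fail_snr | fail_fwhm | fail_crlb | fail_mad)
    counts = {
        "snr": int(fail_snr.sum()),
        "fwhm": int(fail_fwhm.sum()),
        "crlb": int(fail_crlb.sum()),
        "mad": int(fail_mad.sum()),
        "passed": int(mask.sum()),
        "domain": int(domain.sum()),
    }
    return mask, counts
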