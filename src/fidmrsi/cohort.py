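"""ROI-level aggregation, qualification and inter-subject CV statistics.

Implements the regional evaluation machinery: the joint-CRLB pass fraction
per ROI, the good/acceptable/rejected ROI classification, metabolite
qualification rules, per-subject ROI means, ratios to total creatine, and
inter-subject coefficients of variation with mean/min/max summary rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

JOINT_CRITERION_METABOLITES = ("NAA", "tCr", "tCho", "mIns")
GOOD_THRESHOLD_PCT = 80.0
ACCEPTABLE_THRESHOLD_PCT = 66.0
BRAIN_FIT_FRACTION_MIN_PCT = 10.0
QUALIFICATION_MEAN_PASS_PCT = 66.0


def roi_pass_fraction(
    crlb_maps: dict[str, np.ndarray],
    roi_mask: np.ndarray,
    crlb_max_percent: float = 40.0,
    metabolites: tuple[str, ...] = JOINT_CRITERION_METABOLITES,
) -> float:
    """Percentage of ROI voxels where ALL listed metabolites have CRLB below
    the threshold."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    n = int(roi_mask.sum())
    if n == 0:
        raise ValueError("empty ROI")
    ok = np.ones(n, dtype=bool)
    for met in metabolites:
        if met not in crlb_maps:
            raise ValueError(f"missing CRLB map for {met}")
        vals = np.asarray(crlb_maps[met])[roi_mask]
        ok &= np.isfinite(vals) & (vals < crlb_max_percent)
    return 100.0 * ok.sum() / n


def classify_roi(
    pass_fraction: float,
    good_threshold: float = GOOD_THRESHOLD_PCT,
    acceptable_threshold: float = ACCEPTABLE_THRESHOLD_PCT,
) -> str:
    """good (>= 80%), acceptable (>= 66%), else rejected.

    The published rule leaves a gap between "66-79% acceptable" and
    "less than 60% rejected"; the cut is resolved at 66% (an acceptance
    threshold consistent with the reported count of retained regions) and
    both thresholds are configurable.
    """
    if not (0.0 <= pass_fraction <= 100.0):
        raise ValueError("pass fraction must be a percentage")
    if pass_fraction >= good_threshold:
        return "good"
    if pass_fraction >= acceptable_threshold:
        return "acceptable"
    return "rejected"


def metabolite_qualification(
    roi_pass_table: pd.DataFrame,
    brain_fit_fraction_pct: dict[str, float] | None = None,
    min_brain_fraction: float = BRAIN_FIT_FRACTION_MIN_PCT,
    qualification_threshold: float = QUALIFICATION_MEAN_PASS_PCT,
) -> list[str]:
    """Qualified metabolites from a (ROI x metabolite) pass-percentage table.

    A metabolite is discarded outright when it was fit in fewer than
    ``min_brain_fraction`` percent of brain voxels, and qualifies when its
    mean pass percentage over all ROIs is strictly above
    ``qualification_threshold``.
    """
    if roi_pass_table.empty:
        raise ValueError("ROI table is empty")
    qualified = []
    for met in roi_pass_table.columns:
        if brain_fit_fraction_pct is not None:
            if brain_fit_fraction_pct.get(met, 100.0) < min_brain_fraction:
                continue
        if roi_pass_table[met].mean() > qualification_threshold:
            qualified.append(met)
    return qualified


def roi_mean_concentration(
    conc_map: np.ndarray, quality_mask: np.ndarray, roi_mask: np.ndarray
) -> tuple[float, float, int]:
    """Mean and SD of in-mask, in-ROI concentrations; returns (mean, sd, n).

    A (nan, nan, 0) triple flags an ROI with zero passing voxels for this
    subject rather than raising, so cohort aggregation can skip it.
    """
    sel = np.asarray(roi_mask, dtype=bool) & np.asarray(quality_mask, dtype=bool)
    vals = np.asarray(conc_map)[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), float("nan"), 0
    return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0, int(vals.size)


def ratio_to_tcr(met_means: np.ndarray, tcr_means: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Per-subject metabolite/tCr ratio of ROI means, and cohort mean +/- SD.

    Ratios are formed per subject from that subject's ROI means, then
    averaged over the cohort.
    """
    met_means = np.asarray(met_means, dtype=float)
    tcr_means = np.asarray(tcr_means, dtype=float)
    if met_means.shape != tcr_means.shape:
        raise ValueError("per-subject mean arrays differ in length")
    if np.any(~np.isfinite(tcr_means)) or np.any(tcr_means <= 0):
        raise ValueError("non-positive tCr ROI mean: ratio undefined")
    ratios = met_means / tcr_means
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    return ratios, float(np.mean(ratios)), sd


def inter_subject_cv(per_subject_means: np.ndarray) -> float:
    """100 * sample SD / mean of per-subject ROI means."""
    vals = np.asarray(per_subject_means, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 subjects for a CV")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("non-positive mean: CV undefined")
    return 100.0 * vals.std(ddof=1) / mean


def summarize_column(values, rounding: int | None = None) -> tuple[float, float, float]:
    """(mean, min, max) of per-ROI values, optionally rounded for reporting.

    Report formatting: CV percentages round to integers (``rounding=0``),
    concentrations to 2 decimals (``rounding=2``).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty column")
    out = (float(vals.mean()), float(vals.min()), float(vals.max()))
    if rounding is not None:
        out = tuple(round(v, rounding) if rounding > 0 else int(round(v)) for v in out)
    return out


def resample_map_to_labels(
    source_map: np.ndarray,
    source_affine: np.ndarray,
    label_grid_shape: tuple[int, ...],
    label_affine: np.ndarray,
) -> np.ndarray:
    """Nearest-neighbor resampling of a map onto a label grid.

    Each label-grid voxel center is mapped through the affines into source
    voxel coordinates and rounded; the value set of the output is a subset
    of the input's.  Raises when the grids do not overlap at all.
    """
    ii = np.indices(label_grid_shape).reshape(len(label_grid_shape), -1)
    homog = np.vstack([ii, np.ones((1, ii.shape[1]))])
    world = label_affine @ homog
    src = np.linalg.inv(source_affine) @ world
    idx = np.round(src[:3]).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(source_map.shape)[:, None]), axis=0)
    if not inside.any():
        raise ValueError("grids do not overlap")
    out = np.full(ii.shape[1], np.nan)
    out[inside] = source_map[tuple(idx[:, inside])]
    return out.reshape(label_grid_shape)


def cohort_cv_table(
    roi_subject_means: pd.DataFrame,
    rounding: int | None = 0,
) -> pd.DataFrame:
    """Per-ROI, per-metabolite inter-subject CVs with summary rows.

    ``roi_subject_means`` has a (roi, subject) MultiIndex and one column per
    metabolite.  Output rows are ROIs plus Mean/Min/Max summary rows, as in
    the report tables.
    """
    def _cv_or_nan(values: np.ndarray) -> float:
        vals = values[np.isfinite(values)]
        if vals.size < 2 or vals.mean() <= 0:
            return float("nan")  # flagged ROI: too few subjects with data
        return inter_subject_cv(vals)

    rois = roi_subject_means.index.get_level_values(0).unique()
    table = {}
    for roi in rois:
        sub = roi_subject_means.loc[roi]
        table[roi] = {met: _cv_or_nan(sub[met].to_numpy()) for met in sub.columns}
    df = pd.DataFrame(table).T
    summary = pd.DataFrame(
        {
            met: summarize_column(df[met].dropna()) if df[met].notna().any() else (np.nan,) * 3
            for met in df.columns
        },
        index=["Mean", "Min", "Max"],
    )
    out = pd.concat([df, summary])
    if rounding is not None:
        out = out.round(rounding)
        if rounding == 0:
            out = out.astype(int)
    return out
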