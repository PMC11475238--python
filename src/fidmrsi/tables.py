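"""Packaged reference tables and their summary recomputation.

The CSVs under ``fidmrsi/data`` are transcriptions of the published per-ROI
cohort results (clearly labeled as such in their headers): inter-subject CV
percentages, cohort mean concentrations, and the region fitting-quality
table.  They serve two purposes: feeding the summary-statistics machinery
(mean/min/max rows, metabolite qualification, retained-ROI counts) with the
original cohort's numbers, and providing realistic defaults for the
synthetic phantom.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import metabolite_qualification, summarize_column

QUALIFIED_METABOLITES = ("tCho", "tCr", "Glu", "mIns", "NAA")


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.files("fidmrsi.data").joinpath(name).open() as f:
        return pd.read_csv(f, comment="#", **kw)


def load_roi_cv_table() -> pd.DataFrame:
    """Per-ROI inter-subject CVs [%] for the five qualified metabolites."""
    return _read("roi_cv_percent.csv", index_col="roi")


def load_roi_concentration_table() -> pd.DataFrame:
    """Per-ROI cohort mean +/- SD concentrations [mM]."""
    return _read("roi_concentration_mm.csv", index_col="roi")


def load_roi_quality_table() -> pd.DataFrame:
    """Region fitting-quality table for the retained ROIs."""
    return _read("roi_quality.csv", index_col="roi")


def load_rejected_rois() -> list[str]:
    return _read("roi_rejected.csv")["roi"].tolist()


def cv_summary() -> pd.DataFrame:
    """Mean/min/max rows of the per-ROI CV columns, rounded to integers."""
    cv = load_roi_cv_table()
    rows = {met: summarize_column(cv[met], rounding=0) for met in cv.columns}
    return pd.DataFrame(rows, index=["mean", "min", "max"])


def concentration_summary() -> pd.DataFrame:
    """Mean/min/max rows of the per-ROI cohort-mean concentrations [mM]."""
    conc = load_roi_concentration_table()
    rows = {
        met: summarize_column(conc[f"{met}_mean"], rounding=2)
        for met in QUALIFIED_METABOLITES
    }
    return pd.DataFrame(rows, index=["mean", "min", "max"])


def retained_roi_count() -> dict[str, int]:
    """Counts of good/acceptable/rejected regions and the retained total."""
    quality = load_roi_quality_table()
    counts = quality["group"].value_counts().to_dict()
    counts.setdefault("good", 0)
    counts.setdefault("acceptable", 0)
    counts["rejected"] = len(load_rejected_rois())
    counts["retained"] = counts["good"] + counts["acceptable"]
    return counts


def qualified_metabolites_from_quality_table() -> list[str]:
    """Run the qualification rule on the transcribed per-ROI pass table."""
    quality = load_roi_quality_table()
    pass_table = quality.drop(columns=["group", "gm_pct", "wm_pct", "size_cm3"])
    return metabolite_qualification(pass_table)
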