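"""End-to-end study orchestration: eligibility, analysis battery, reporting.

``run_study`` reproduces the complete analysis chain on a cohort table:

1. sector summary (means/SDs of the eight ppCT sectors),
2. Steel-Dwass all-pairs comparison of the sectors,
3. per-sector association grid — Spearman correlation and standardized
   multiple-regression coefficient of each sector's ppCT against axial
   length, PMP angle, and optic disc tilt (the three predictors entered
   simultaneously),
4. the temporal ppCT ratio (temporal / mean of the other seven sectors):
   summary and its correlations with the three predictors (Spearman, with
   Pearson alongside),
5. per-sector Mann-Whitney comparison by parapapillary-atrophy status,
6. the association grid within each sex plus Fisher-z comparison of the
   between-sex Spearman coefficients.

Significance is read at two-sided p < 0.05 throughout, with no extra
multiple-testing correction across the grid — a deliberate fidelity choice
documented in the methods note. The Steel-Dwass comparison treats sector
values as independent groups although they are within-eye repeated
measures; this too is a documented fidelity choice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import stats as st
from .geometry import SECTORS
from .thickness import SectorThickness, temporal_ratio
from scipy.stats import pearsonr

__all__ = ["AnalysisReport", "apply_eligibility", "run_study", "write_report", "PREDICTORS"]

logger = logging.getLogger("ppct")

#: Predictor columns of the association grid, in display order.
PREDICTORS: Dict[str, str] = {
    "axial_length": "axial_length_mm",
    "pmp": "pmp_deg",
    "tilt": "tilt_px",
}

_SECTOR_COLS = {s: f"ppct_{s.lower()}" for s in SECTORS}

_ELIGIBILITY_FLAGS = [
    "has_ocular_disease", "has_staphyloma", "has_disc_anomaly",
    "prior_surgery", "poor_image_quality",
]


@dataclass
class AnalysisReport:
    """Container for every table the study analysis produces."""

    n: int
    demographics: pd.DataFrame
    sector_summary: pd.DataFrame
    sector_comparisons: pd.DataFrame
    association_grid: pd.DataFrame
    ratio_summary: Dict[str, float]
    ratio_correlations: pd.DataFrame
    ppa_comparison: pd.DataFrame
    sex_stratified: Dict[str, Optional[pd.DataFrame]] = field(default_factory=dict)
    sex_correlation_comparison: Optional[pd.DataFrame] = None


def apply_eligibility(records: pd.DataFrame, mirror_left: bool = False) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a cohort table to eligible right eyes.

    Eligibility: age in [20, 40] years, BCVA <= 0.1 logMAR, IOP <= 21 mmHg
    (all bounds inclusive), no exclusion flag set, right eyes only. With
    ``mirror_left=True`` left eyes are relabelled into the right-eye frame
    instead of excluded (sector names are anatomical, so sector columns are
    unchanged). Returns the retained table and an exclusion log listing each
    excluded eye with every rule it triggered.
    """
    required = ["eye_id", "laterality", "age_years", "bcva_logmar", "iop_mmhg", *_ELIGIBILITY_FLAGS]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"records missing eligibility field(s): {', '.join(missing)}")

    df = records.copy()
    if mirror_left:
        mirrored = df["laterality"] == "left"
        if mirrored.any():
            logger.info("mirroring %d left eyes into the right-eye frame", int(mirrored.sum()))
            df.loc[mirrored, "laterality"] = "right"

    reasons: List[Tuple[str, str]] = []

    def check(mask: pd.Series, rule: str) -> None:
        for eid in df.loc[mask, "eye_id"]:
            reasons.append((str(eid), rule))

    check(df["laterality"] != "right", "laterality")
    check((df["age_years"] < 20) | (df["age_years"] > 40), "age")
    check(df["bcva_logmar"] > 0.1, "bcva")
    check(df["iop_mmhg"] > 21, "iop")
    for flag in _ELIGIBILITY_FLAGS:
        check(df[flag].astype(bool), flag)

    log = pd.DataFrame(reasons, columns=["eye_id", "rule"])
    excluded_ids = set(log["eye_id"])
    retained = df[~df["eye_id"].astype(str).isin(excluded_ids)].reset_index(drop=True)
    if len(log):
        logger.info("excluded %d of %d eyes", len(excluded_ids), len(df))
    return retained, log


def _demographics(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for label, col in [
        ("age_years", "age_years"),
        ("refractive_error_d", "refractive_error_d"),
        ("axial_length_mm", "axial_length_mm"),
        ("pmp_deg", "pmp_deg"),
        ("tilt_px", "tilt_px"),
    ]:
        v = df[col].to_numpy(float)
        rows.append({"variable": label, "mean": v.mean(), "sd": v.std(ddof=1),
                     "min": v.min(), "max": v.max()})
    rows.append({
        "variable": "n_male", "mean": float((df["sex"] == "M").sum()),
        "sd": np.nan, "min": np.nan, "max": np.nan,
    })
    return pd.DataFrame(rows)


def _association_grid(df: pd.DataFrame) -> pd.DataFrame:
    """Spearman r/p and standardized beta/p for each sector x predictor cell."""
    x_cols = list(PREDICTORS.values())
    X = df[x_cols].to_numpy(float)
    rows = []
    for s in SECTORS:
        y = df[_SECTOR_COLS[s]].to_numpy(float)
        reg = st.regress_standardized(y, X, predictor_names=list(PREDICTORS), outcome=s)
        for pred, col in PREDICTORS.items():
            corr = st.spearman(df[col].to_numpy(float), y)
            rows.append({
                "sector": s, "predictor": pred,
                "spearman_r": corr.r, "spearman_p": corr.p,
                "beta": reg.coefficients[pred], "beta_p": reg.p_values[pred],
                "n": corr.n,
            })
    return pd.DataFrame(rows)


def _per_eye_ratio(df: pd.DataFrame) -> pd.Series:
    vals = df[[_SECTOR_COLS[s] for s in SECTORS]].to_numpy(float)
    ratios = [
        temporal_ratio(SectorThickness(values={s: float(v) for s, v in zip(SECTORS, row)}))
        for row in vals
    ]
    return pd.Series(ratios, index=df.index, name="temporal_ratio")


def run_study(records: pd.DataFrame, min_n: int = 10) -> AnalysisReport:
    """Run the full statistical battery on an eligible cohort table."""
    df = records.sort_values("eye_id").reset_index(drop=True)
    if len(df) < min_n:
        raise ValueError(f"need at least {min_n} eligible records, got {len(df)}")
    sector_mat = {s: df[_SECTOR_COLS[s]].to_numpy(float) for s in SECTORS}

    sector_summary = pd.DataFrame({
        "sector": list(SECTORS),
        "mean": [sector_mat[s].mean() for s in SECTORS],
        "sd": [sector_mat[s].std(ddof=1) for s in SECTORS],
    })

    sd = st.steel_dwass([sector_mat[s] for s in SECTORS])
    comp_rows = []
    for (i, j), z in sd.statistics.items():
        comp_rows.append({
            "sector_a": SECTORS[i], "sector_b": SECTORS[j],
            "z": z, "p_adjusted": sd.p_values[(i, j)],
        })
    sector_comparisons = pd.DataFrame(comp_rows)

    grid = _association_grid(df)

    ratios = _per_eye_ratio(df)
    ratio_summary = {
        "mean": float(ratios.mean()), "sd": float(ratios.std(ddof=1)),
        "min": float(ratios.min()), "max": float(ratios.max()),
    }
    ratio_rows = []
    for pred, col in PREDICTORS.items():
        x = df[col].to_numpy(float)
        sp = st.spearman(x, ratios.to_numpy())
        pe = pearsonr(x, ratios.to_numpy())
        ratio_rows.append({
            "predictor": pred, "spearman_r": sp.r, "spearman_p": sp.p,
            "pearson_r": float(pe.statistic), "pearson_p": float(pe.pvalue), "n": sp.n,
        })
    ratio_correlations = pd.DataFrame(ratio_rows)

    ppa_rows = []
    with_ppa = df[df["ppa"].astype(bool)]
    without_ppa = df[~df["ppa"].astype(bool)]
    for s in SECTORS:
        if len(with_ppa) and len(without_ppa):
            p = st.mann_whitney(with_ppa[_SECTOR_COLS[s]], without_ppa[_SECTOR_COLS[s]])
        else:
            p = np.nan
        ppa_rows.append({"sector": s, "p": p, "n_ppa": len(with_ppa), "n_no_ppa": len(without_ppa)})
    ppa_comparison = pd.DataFrame(ppa_rows)

    sex_grids: Dict[str, Optional[pd.DataFrame]] = {}
    for sex in ("M", "F"):
        sub = df[df["sex"] == sex]
        if len(sub) >= min_n:
            sex_grids[sex] = _association_grid(sub)
        else:
            sex_grids[sex] = None
            logger.info("sex stratum %s absent or too small (n=%d); skipped", sex, len(sub))

    sex_cmp = None
    if sex_grids["M"] is not None and sex_grids["F"] is not None:
        gm = sex_grids["M"].set_index(["sector", "predictor"])
        gf = sex_grids["F"].set_index(["sector", "predictor"])
        cmp_rows = []
        for key in gm.index:
            r1, n1 = gm.loc[key, "spearman_r"], int(gm.loc[key, "n"])
            r2, n2 = gf.loc[key, "spearman_r"], int(gf.loc[key, "n"])
            cmp_rows.append({
                "sector": key[0], "predictor": key[1],
                "r_male": r1, "r_female": r2,
                "p_difference": st.compare_correlations(r1, n1, r2, n2),
            })
        sex_cmp = pd.DataFrame(cmp_rows)

    return AnalysisReport(
        n=len(df),
        demographics=_demographics(df),
        sector_summary=sector_summary,
        sector_comparisons=sector_comparisons,
        association_grid=grid,
        ratio_summary=ratio_summary,
        ratio_correlations=ratio_correlations,
        ppa_comparison=ppa_comparison,
        sex_stratified=sex_grids,
        sex_correlation_comparison=sex_cmp,
    )


def write_report(report: AnalysisReport, directory: str | Path) -> Path:
    """Serialize an :class:`AnalysisReport` as CSV tables plus a JSON summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    report.demographics.to_csv(directory / "demographics.csv", index=False)
    report.sector_summary.to_csv(directory / "sector_summary.csv", index=False)
    report.sector_comparisons.to_csv(directory / "sector_comparisons.csv", index=False)
    report.association_grid.to_csv(directory / "association_grid.csv", index=False)
    report.ratio_correlations.to_csv(directory / "ratio_correlations.csv", index=False)
    report.ppa_comparison.to_csv(directory / "ppa_comparison.csv", index=False)
    for sex, grid in report.sex_stratified.items():
        if grid is not None:
            grid.to_csv(directory / f"association_grid_{sex}.csv", index=False)
    if report.sex_correlation_comparison is not None:
        report.sex_correlation_comparison.to_csv(directory / "sex_correlation_comparison.csv", index=False)
    summary = {
        "n": report.n,
        "temporal_ratio": report.ratio_summary,
        "sector_means": dict(zip(report.sector_summary["sector"], report.sector_summary["mean"])),
    }
    (directory / "summary.json").write_text(json.dumps(summary, indent=2))
    return directory
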