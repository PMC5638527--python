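"""Cohort-table and trace I/O (CSV with an XLSX variant for cohort tables).

The cohort schema mirrors a per-eye raw-data sheet: demographics, biometry,
PMP angle, disc tilt, the eight sector ppCT columns, a parapapillary-atrophy
flag and the eligibility fields. Headers are matched case-insensitively;
malformed numeric cells are reported with their file line numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .geometry import SECTORS

__all__ = [
    "SchemaError",
    "REQUIRED_COLUMNS",
    "NUMERIC_COLUMNS",
    "read_cohort_csv",
    "read_cohort_xlsx",
    "write_cohort_csv",
    "write_trace_csv",
    "read_trace_csv",
]


class SchemaError(ValueError):
    """Raised when a cohort table does not match the documented schema."""


_SECTOR_COLS = [f"ppct_{s.lower()}" for s in SECTORS]

REQUIRED_COLUMNS: List[str] = [
    "eye_id", "laterality", "age_years", "sex", "refractive_error_d",
    "axial_length_mm", "pmp_deg", "tilt_px", *_SECTOR_COLS, "ppa",
]

NUMERIC_COLUMNS: List[str] = [
    "age_years", "refractive_error_d", "axial_length_mm", "pmp_deg", "tilt_px",
    *_SECTOR_COLS, "bcva_logmar", "iop_mmhg",
]

_BOOL_COLUMNS = [
    "ppa", "has_ocular_disease", "has_staphyloma", "has_disc_anomaly",
    "prior_surgery", "poor_image_quality",
]


def _validate(df: pd.DataFrame, source: str, header_offset: int) -> pd.DataFrame:
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s): {', '.join(missing)}")
    bad_lines: List[str] = []
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        for idx in df.index[newly_bad]:
            # +1 header row, +1 one-based
            bad_lines.append(f"line {int(idx) + header_offset}: non-numeric value {df.at[idx, col]!r} in column '{col}'")
        df[col] = coerced
    if bad_lines:
        raise SchemaError(f"{source}: malformed rows:\n" + "\n".join(bad_lines))
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else str(v).strip().lower() in ("true", "1", "yes")
            )
    df["laterality"] = df["laterality"].astype(str).str.strip().str.lower()
    df["sex"] = df["sex"].astype(str).str.strip().str.upper()
    return df


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort table from CSV, validating the schema."""
    path = Path(path)
    df = pd.read_csv(path)
    return _validate(df, str(path), header_offset=2)


def read_cohort_xlsx(path: str | Path, sheet: int | str = 0) -> pd.DataFrame:
    """Read the XLSX variant of the cohort table (same schema as the CSV)."""
    path = Path(path)
    df = pd.read_excel(path, sheet_name=sheet)
    return _validate(df, str(path), header_offset=2)


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_trace_csv(eye_id: str, trace, marked, directory: str | Path) -> Tuple[Path, Path]:
    """Write one eye's boundary trace and marked RPE points as CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trace_path = directory / f"{eye_id}_trace.csv"
    pd.DataFrame({
        "eye_id": eye_id,
        "ascan_index": np.arange(trace.n_ascans),
        "z_rpe_px": trace.z_rpe,
        "z_csi_px": trace.z_csi,
    }).to_csv(trace_path, index=False)
    marked_path = directory / f"{eye_id}_marked.csv"
    pd.DataFrame({
        "eye_id": eye_id,
        "x_px": marked.x,
        "y_px": marked.y,
        "scan_width_px": marked.scan_width_px,
    }).to_csv(marked_path, index=False)
    return trace_path, marked_path


def read_trace_csv(trace_path: str | Path, axial_scale: float):
    """Read a boundary-trace CSV back into a :class:`CircumpapillaryTrace`."""
    from .thickness import CircumpapillaryTrace

    df = pd.read_csv(trace_path)
    for col in ("ascan_index", "z_rpe_px", "z_csi_px"):
        if col not in df.columns:
            raise SchemaError(f"{trace_path}: missing required column '{col}'")
    df = df.sort_values("ascan_index")
    return CircumpapillaryTrace(
        z_rpe=df["z_rpe_px"].to_numpy(float),
        z_csi=df["z_csi_px"].to_numpy(float),
        axial_scale=axial_scale,
        n_ascans=len(df),
    )
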