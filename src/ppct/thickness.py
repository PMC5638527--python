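"""Per-sector peripapillary choroidal thickness from circumpapillary traces.

Choroidal thickness at each A-scan is the axial distance between the outer
retinal-pigment-epithelium boundary and the sclerochoroidal interface;
sector values sample that profile at the eight fovea-disc-anchored sites.
Measuring along the A-scan approximates the perpendicular distance and
coincides with it where the boundaries run parallel to the scan circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .geometry import SECTORS, SectorMap, angle_to_nearest_index, trace_index_to_angle

__all__ = ["CircumpapillaryTrace", "SectorThickness", "measure_ppct", "temporal_ratio"]


@dataclass(frozen=True)
class CircumpapillaryTrace:
    """Boundary depths along the 3.4 mm scan circle.

    ``z_rpe`` and ``z_csi`` are per-A-scan axial depths (px, increasing with
    depth) of the outer RPE boundary and the sclerochoroidal interface; the
    choroid has non-negative thickness, so ``z_csi >= z_rpe`` everywhere.
    """

    z_rpe: np.ndarray
    z_csi: np.ndarray
    axial_scale: float  # µm per pixel, axial
    n_ascans: int = 1024
    circle_diameter_mm: float = 3.4

    def __post_init__(self) -> None:
        z_rpe = np.asarray(self.z_rpe, dtype=float)
        z_csi = np.asarray(self.z_csi, dtype=float)
        object.__setattr__(self, "z_rpe", z_rpe)
        object.__setattr__(self, "z_csi", z_csi)
        if z_rpe.shape != (self.n_ascans,) or z_csi.shape != (self.n_ascans,):
            raise ValueError("boundary arrays must have length n_ascans")
        if self.axial_scale <= 0:
            raise ValueError("axial_scale must be positive")
        if np.any(z_csi < z_rpe - 1e-9):
            raise ValueError("z_csi must be >= z_rpe at every A-scan (non-negative choroid)")


@dataclass(frozen=True)
class SectorThickness:
    """Named 8-sector ppCT vector (µm)."""

    values: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.values) != SECTORS:
            raise ValueError(f"sector thickness must cover {SECTORS} in order")
        arr = np.array(list(self.values.values()), dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("sector thicknesses must be finite and non-negative")

    def __getitem__(self, sector: str) -> float:
        return self.values[sector]

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def measure_ppct(
    trace: CircumpapillaryTrace, sectors: SectorMap, window_deg: float = 0.0
) -> SectorThickness:
    """Sector ppCT (µm) from a boundary trace.

    For each sector the thickness is the median of ``(z_csi - z_rpe) *
    axial_scale`` over the A-scans within ``±window_deg`` of the sector's
    central angle; ``window_deg = 0`` reads the single nearest A-scan (the
    point measurement used by manual grading). The window half-width must be
    below 22.5 deg so adjacent sectors never share A-scans symmetrically.
    """
    if not 0.0 <= window_deg < 22.5:
        raise ValueError("window_deg must lie in [0, 22.5)")
    n = trace.n_ascans
    thickness_px = trace.z_csi - trace.z_rpe
    angles = trace_index_to_angle(np.arange(n), n)
    out: Dict[str, float] = {}
    for name in SECTORS:
        center = sectors[name]
        if window_deg == 0.0:
            sel = np.array([angle_to_nearest_index(center, n)])
        else:
            dist = np.abs((angles - center + 180.0) % 360.0 - 180.0)
            sel = np.nonzero(dist <= window_deg)[0]
        out[name] = float(np.median(thickness_px[sel]) * trace.axial_scale)
    return SectorThickness(values=out)


def temporal_ratio(sectors: SectorThickness) -> float:
    """Temporal ppCT divided by the mean ppCT of the other seven sectors.

    A per-eye asymmetry statistic: values below 1 indicate a temporally
    thinned choroid relative to the rest of the peripapillary ring.
    """
    others = np.array([sectors[s] for s in SECTORS if s != "T"], dtype=float)
    denom = others.mean()
    if denom <= 0:
        raise ZeroDivisionError("mean of non-temporal sectors must be positive")
    return float(sectors["T"] / denom)
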