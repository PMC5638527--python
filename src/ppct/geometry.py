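"""Fundus-landmark geometry for circumpapillary circle scans.

The circle scan is anchored to the fovea-disc axis: the temporal (T)
measurement site sits where the line from the optic disc center to the fovea
crosses the 3.4 mm scan circle, and the remaining seven sites follow at 45
degree intervals (T, ST, S, SN, N, IN, I, IT — TSNIT-style, superior first).

Coordinate conventions
----------------------
* Fundus-image frame: x to the image right, y increasing **inferiorly**
  (screen convention of fundus photographs), units in micrometres.
* Papillo-macular position (PMP) angle: the angle between the horizontal and
  the disc-center-to-fovea line, **positive when the fovea lies inferior** to
  the horizontal through the disc center. Healthy eyes typically carry a
  small positive PMP (fovea slightly below the disc).
* Scan-circle angular frame: 0 deg at the temporal horizontal axis,
  increasing toward the superior sectors, so an unwrapped trace reads
  T -> S -> N -> I -> T. The frame is laterality-aware: for left eyes the
  temporal axis points the other way on the photograph, but sector names keep
  their anatomical meaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "SECTORS",
    "FundusLandmarks",
    "SectorMap",
    "DegenerateGeometryError",
    "pmp_angle",
    "build_sector_map",
    "trace_index_to_angle",
    "angle_to_nearest_index",
]

#: Anatomical sector names in angular order starting temporally, superior first.
SECTORS: Tuple[str, ...] = ("T", "ST", "S", "SN", "N", "IN", "I", "IT")

SECTOR_STEP_DEG = 45.0


class DegenerateGeometryError(ValueError):
    """Raised when fundus landmarks do not define a usable fovea-disc axis."""


@dataclass(frozen=True)
class FundusLandmarks:
    """Disc center and fovea in the fundus-image frame (µm, y down).

    Parameters
    ----------
    disc_center, fovea
        Planar points ``(x, y)`` in micrometres.
    laterality
        ``"right"`` or ``"left"``. Under the adopted convention the fovea of
        a right eye lies at negative x displacement from the disc (temporal).
    """

    disc_center: Tuple[float, float]
    fovea: Tuple[float, float]
    laterality: str = "right"

    def __post_init__(self) -> None:
        if self.laterality not in ("right", "left"):
            raise ValueError(f"laterality must be 'right' or 'left', got {self.laterality!r}")
        if tuple(self.disc_center) == tuple(self.fovea):
            raise DegenerateGeometryError("disc center and fovea coincide")


@dataclass(frozen=True)
class SectorMap:
    """Ordered mapping of sector name to central angle (deg) on the scan circle.

    Angles live in the laterality-aware scan frame (0 deg = temporal
    horizontal, increasing toward superior) and are 45 deg apart.
    """

    angles: Dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.angles) != SECTORS:
            raise ValueError(f"sector map must cover {SECTORS} in order")
        vals = np.array(list(self.angles.values()))
        steps = np.diff(np.append(vals, vals[0] + 360.0)) % 360.0
        if not np.allclose(steps, SECTOR_STEP_DEG, atol=1e-9):
            raise ValueError("consecutive sector angles must differ by 45 deg")

    def __getitem__(self, sector: str) -> float:
        return self.angles[sector]


def _axis_components(landmarks: FundusLandmarks) -> Tuple[float, float]:
    """Disc->fovea displacement resolved onto (temporal, superior) axes."""
    dx = landmarks.fovea[0] - landmarks.disc_center[0]
    dy = landmarks.fovea[1] - landmarks.disc_center[1]
    temporal = -dx if landmarks.laterality == "right" else dx
    superior = -dy  # image y grows inferiorly
    return temporal, superior


def pmp_angle(landmarks: FundusLandmarks) -> float:
    """Papillo-macular position angle in degrees.

    The signed angle between the horizontal through the disc center and the
    disc-to-fovea line; positive when the fovea is inferior to that
    horizontal. Range is the open interval (-90, 90).

    Raises
    ------
    DegenerateGeometryError
        If the landmarks coincide or the fovea sits vertically above/below
        the disc (no horizontal component, angle would be ±90).
    """
    temporal, superior = _axis_components(landmarks)
    horizontal = abs(temporal)
    if horizontal == 0.0:
        raise DegenerateGeometryError(
            "fovea is vertically aligned with the disc center; PMP undefined"
        )
    inferior = -superior
    return math.degrees(math.atan2(inferior, horizontal))


def build_sector_map(landmarks: FundusLandmarks) -> SectorMap:
    """Anchor the eight 45-deg sectors at the fovea-disc axis.

    The T sector center is the intersection of the disc->fovea direction with
    the scan circle; subsequent sectors proceed superiorly (ST, S, SN, N, IN,
    I, IT). In the scan frame the T anchor sits at ``-pmp`` degrees: a fovea
    displaced inferiorly (positive PMP) drags the temporal anchor inferiorly.
    """
    temporal, superior = _axis_components(landmarks)
    if temporal <= 0.0:
        raise DegenerateGeometryError(
            "fovea must lie on the temporal side of the disc for sector anchoring"
        )
    anchor = math.degrees(math.atan2(superior, temporal))
    angles = {
        name: (anchor + i * SECTOR_STEP_DEG) % 360.0 for i, name in enumerate(SECTORS)
    }
    return SectorMap(angles=angles)


def trace_index_to_angle(index, n_ascans: int):
    """Map A-scan index/indices on the circle scan to angles (deg).

    The scan is assumed recorded in the sector-map frame: index 0 at the
    temporal horizontal (0 deg), increasing toward superior. Accepts scalars
    or arrays.
    """
    idx = np.asarray(index)
    if np.any(idx < 0) or np.any(idx >= n_ascans):
        raise IndexError(f"A-scan index out of range [0, {n_ascans})")
    angle = idx * (360.0 / n_ascans)
    return float(angle) if np.isscalar(index) else angle


def angle_to_nearest_index(angle_deg: float, n_ascans: int) -> int:
    """Inverse of :func:`trace_index_to_angle` (nearest A-scan, wraparound aware)."""
    return int(round((angle_deg % 360.0) / 360.0 * n_ascans)) % n_ascans
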