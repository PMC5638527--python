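"""Optic-disc-tilt quantification by sinusoid fitting of the RPE trajectory.

A circular OCT scan around a tilted optic disc intersects the (locally
planar) retinal pigment epithelium in an ellipse; unwrapped into a linear
B-scan, the RPE trajectory is one period of a sinusoid. The amplitude ``a``
of the least-squares fit ``y = a * sin(b*x - c)`` to manually marked RPE
points is therefore a direct tilt metric: the flatter the disc, the flatter
the wave. Tilt is reported in axial pixels; a micrometre conversion is
available through the axial pixel scale but pixels are the default unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MarkedRpePoints",
    "SineFitResult",
    "recenter",
    "fit_sine",
    "measure_tilt",
    "expected_amplitude",
]


@dataclass(frozen=True)
class MarkedRpePoints:
    """Manually marked RPE positions along the unwrapped circular B-scan.

    ``x`` is the A-scan (lateral) position in pixels, strictly increasing
    within ``[0, scan_width_px]`` before recentering; ``y`` the axial depth
    in pixels. At least 6 points are required for a three-parameter fit.
    """

    x: np.ndarray
    y: np.ndarray
    scan_width_px: float
    recentered: bool = False

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size < 6:
            raise ValueError("at least 6 marked RPE points are required")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x positions must be strictly increasing")
        if not self.recentered and (x[0] < 0 or x[-1] > self.scan_width_px):
            raise ValueError("x positions must lie within [0, scan_width_px]")

    def __len__(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class SineFitResult:
    """Least-squares sine fit ``y = a sin(b x - c)``.

    ``a`` (amplitude, px) is normalized non-negative — the sign is absorbed
    into the phase — and is the optic-disc-tilt metric. ``rms_residual`` is
    the root-mean-square fit residual in pixels.
    """

    a: float
    b: float
    c: float
    rms_residual: float
    converged: bool


def recenter(points: MarkedRpePoints) -> MarkedRpePoints:
    """Shift marked coordinates so the wave center is the origin.

    x is translated so the scan midline (``scan_width/2``) maps to zero; y is
    translated by its mean. Ordering is preserved.
    """
    return replace(
        points,
        x=points.x - points.scan_width_px / 2.0,
        y=points.y - points.y.mean(),
        recentered=True,
    )


def _normalize(a: float, b: float, c: float) -> tuple[float, float, float]:
    """Report a >= 0, folding a sign flip into a pi phase shift; c in [0, 2pi)."""
    if a < 0:
        a, c = -a, c + math.pi
    return a, b, c % (2.0 * math.pi)


def _phase_seed(x: np.ndarray, y: np.ndarray, b0: float) -> float:
    """Initial phase from the first Fourier component at frequency b0.

    Writing y ~ a sin(b0 x - c) = a cos(c) sin(b0 x) - a sin(c) cos(b0 x),
    the projections onto sin/cos give the phase directly.
    """
    s = float(np.dot(y, np.sin(b0 * x)))
    co = float(np.dot(y, np.cos(b0 * x)))
    return math.atan2(-co, s)


def fit_sine(points: MarkedRpePoints) -> SineFitResult:
    """Fit ``y = a sin(b x - c)`` to recentered marked points by least squares.

    The angular frequency is seeded at ``2*pi/scan_width`` (one period per
    circle — a planar tilted RPE admits exactly one) and constrained to
    [0.5, 2] times that value so noise cannot lock onto harmonics. The phase
    is multi-started around the first-Fourier-component seed to avoid local
    minima; amplitude is reported non-negative.

    A flat trace (all y equal after recentering) returns ``a = 0`` with
    ``converged=True``; optimizer failure returns ``converged=False`` with
    the best parameters found.
    """
    pts = points if points.recentered else recenter(points)
    x, y = pts.x, pts.y
    span = x.max() - x.min()
    if span < points.scan_width_px / 2.0:
        raise ValueError("marked points must span at least half the scan width")

    b0 = 2.0 * math.pi / points.scan_width_px
    if np.allclose(y, y[0]):
        return SineFitResult(a=0.0, b=b0, c=0.0, rms_residual=0.0, converged=True)

    a0 = (y.max() - y.min()) / 2.0
    c_seed = _phase_seed(x, y, b0)

    def residual(params: np.ndarray) -> np.ndarray:
        a, b, c = params
        return a * np.sin(b * x - c) - y

    best = None
    ok = False
    for dc in (0.0, math.pi / 2, math.pi, 3 * math.pi / 2):
        try:
            sol = least_squares(
                residual,
                x0=[a0, b0, c_seed + dc],
                bounds=([0.0, 0.5 * b0, -np.inf], [np.inf, 2.0 * b0, np.inf]),
                method="trf",
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
            ok = bool(sol.success)
    if best is None:
        return SineFitResult(a=math.nan, b=math.nan, c=math.nan, rms_residual=math.nan, converged=False)

    a, b, c = _normalize(*best.x)
    rms = float(np.sqrt(np.mean(residual(best.x) ** 2)))
    return SineFitResult(a=float(a), b=float(b), c=float(c), rms_residual=rms, converged=ok)


def measure_tilt(points: MarkedRpePoints) -> SineFitResult:
    """Recenter then fit: the full tilt measurement on raw marked points."""
    return fit_sine(recenter(points))


def expected_amplitude(tilt_deg: float, circle_radius_um: float, axial_scale_um_per_px: float) -> float:
    """Forward model: sine amplitude (px) produced by a planar RPE tilted by ``tilt_deg``.

    A plane tilted by angle t, sectioned along a circle of radius r, yields an
    axial excursion of +/- r*tan(t); dividing by the axial pixel pitch gives
    the amplitude in pixels. Used by the synthetic generator and for
    inverse-fit recovery checks.
    """
    if not 0.0 <= tilt_deg < 90.0:
        raise ValueError("tilt_deg must be in [0, 90)")
    if circle_radius_um <= 0 or axial_scale_um_per_px <= 0:
        raise ValueError("radius and axial scale must be positive")
    return circle_radius_um * math.tan(math.radians(tilt_deg)) / axial_scale_um_per_px
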