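"""Synthetic cohorts and circumpapillary traces with programmed structure.

The generator emulates a young, predominantly myopic study population: per
eye it draws axial length (truncated normal), papillo-macular position (PMP)
angle, and optic disc tilt (linearly coupled to axial length), then builds
the eight sector ppCT values as

    ppCT_s = baseline_s + beta_AL[s] * (AL - mean_AL)
                        + beta_PMP[s] * (PMP - mean_PMP)
                        + beta_tilt[s] * (tilt - mean_tilt)
                        + shared eye-level residual + sector residual

with all effects centered so cohort sector means match the configured
baselines. Default effect directions encode the biology being emulated:
longer eyes have thinner choroids everywhere, an inferiorly displaced fovea
(positive PMP) accompanies thicker choroids everywhere, and disc tilt thins
only the temporal and inferotemporal sectors. The default coefficient
magnitudes are derived analytically (:func:`calibrated_effects`) from target
correlation coefficients so that sample correlations at n ~ 114 land in
realistic ranges.

Boundary traces follow the forward geometric model: a circular section of a
tilted RPE plane is one period of a sinusoid, so ``z_rpe(i) = a sin(2 pi i/n
- c) + noise`` with amplitude equal to the eye's tilt (px); the
sclerochoroidal interface sits below it by the eye's angular thickness
profile (periodic cubic interpolation through the 8 sector anchors) plus
independent boundary-marking noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import truncnorm

from .geometry import SECTORS, FundusLandmarks, build_sector_map
from .thickness import CircumpapillaryTrace
from .tilt_fit import MarkedRpePoints

__all__ = [
    "SECTOR_BASELINE_MEAN",
    "SECTOR_BASELINE_SD",
    "TARGET_R_AL",
    "TARGET_R_PMP",
    "TARGET_R_TILT",
    "CohortConfig",
    "TraceConfig",
    "calibrated_effects",
    "generate_cohort",
    "generate_trace",
    "landmarks_from_pmp",
]

#: Per-sector ppCT baselines (µm): population means and SDs of the emulated cohort.
SECTOR_BASELINE_MEAN: Dict[str, float] = {
    "T": 166.87, "ST": 183.41, "S": 191.59, "SN": 190.50,
    "N": 190.62, "IN": 173.21, "I": 151.49, "IT": 153.09,
}
SECTOR_BASELINE_SD: Dict[str, float] = {
    "T": 62.45, "ST": 57.19, "S": 50.44, "SN": 49.59,
    "N": 47.66, "IN": 45.58, "I": 44.58, "IT": 51.10,
}

#: Target (population) correlations the default effects are calibrated to.
#: Axial-length correlations are negative in every sector, strongest
#: temporally; PMP correlations positive everywhere; tilt effects are
#: programmed only in T and IT.
TARGET_R_AL: Dict[str, float] = {
    "T": -0.42, "ST": -0.36, "S": -0.32, "SN": -0.30,
    "N": -0.28, "IN": -0.30, "I": -0.34, "IT": -0.40,
}
TARGET_R_PMP: Dict[str, float] = {
    "T": 0.36, "ST": 0.32, "S": 0.30, "SN": 0.28,
    "N": 0.26, "IN": 0.28, "I": 0.30, "IT": 0.34,
}
TARGET_R_TILT: Dict[str, float] = {
    "T": -0.32, "ST": 0.0, "S": 0.0, "SN": 0.0,
    "N": 0.0, "IN": 0.0, "I": 0.0, "IT": -0.32,
}

#: Column order of the generated cohort table (S1-style raw data layout).
COHORT_COLUMNS = [
    "eye_id", "laterality", "age_years", "sex", "refractive_error_d",
    "axial_length_mm", "pmp_deg", "tilt_px",
    "ppct_t", "ppct_st", "ppct_s", "ppct_sn", "ppct_n", "ppct_in", "ppct_i", "ppct_it",
    "ppa", "bcva_logmar", "iop_mmhg",
    "has_ocular_disease", "has_staphyloma", "has_disc_anomaly",
    "prior_surgery", "poor_image_quality",
]


def calibrated_effects(
    target_r_al: Dict[str, float],
    target_r_pmp: Dict[str, float],
    target_r_tilt: Dict[str, float],
    sector_sds: Dict[str, float],
    al_sd: float,
    pmp_sd: float,
    tilt_sd: float,
    tilt_al_corr: float,
) -> Tuple[Dict[str, float], Dict[str, float], Dict[str, float], Dict[str, float]]:
    """Derive linear effect coefficients from target marginal correlations.

    With tilt = rho * (sd_tilt/sd_AL) * (AL - mean) + independent noise, the
    marginal correlations of a sector value y with AL and tilt satisfy

        r_AL  = u_A + rho * u_T,    r_tilt = u_T + rho * u_A,

    where ``u_A = beta_AL sd_AL / sd_y`` and ``u_T = beta_tilt sd_tilt /
    sd_y`` are the effects in correlation units. Inverting gives the betas;
    the residual SD absorbs whatever variance the effects do not explain so
    each sector's total SD equals the configured value. Sectors whose tilt
    target is zero get ``beta_tilt = 0`` exactly (their marginal tilt
    correlation is then ``rho * r_AL``, small for weak coupling).
    """
    rho = tilt_al_corr
    beta_al, beta_pmp, beta_tilt, resid_sd = {}, {}, {}, {}
    for s in SECTORS:
        sd_y = sector_sds[s]
        r_a, r_p, r_t = target_r_al[s], target_r_pmp[s], target_r_tilt[s]
        if r_t == 0.0:
            u_a, u_t = r_a, 0.0
        else:
            u_a = (r_a - rho * r_t) / (1.0 - rho * rho)
            u_t = (r_t - rho * r_a) / (1.0 - rho * rho)
        u_p = r_p
        r2 = u_a * u_a + u_t * u_t + u_p * u_p + 2.0 * rho * u_a * u_t
        if r2 >= 1.0:
            raise ValueError(f"targets for sector {s} explain more than total variance")
        beta_al[s] = u_a * sd_y / al_sd
        beta_pmp[s] = u_p * sd_y / pmp_sd
        beta_tilt[s] = u_t * sd_y / tilt_sd
        resid_sd[s] = sd_y * math.sqrt(1.0 - r2)
    return beta_al, beta_pmp, beta_tilt, resid_sd


@dataclass
class CohortConfig:
    """Configuration of the synthetic study population.

    Distribution parameters default to the emulated cohort: axial length
    25.46 ± 1.43 mm truncated to [22.38, 30.42]; PMP 5.43 ± 3.47 deg; disc
    tilt 53.08 ± 23.93 px with a weak positive coupling to axial length
    (longer eyes are more tilted); sector baselines/SDs above. Effect
    coefficients default to the calibrated values; ``residual_shared_frac``
    is the fraction of residual variance shared across sectors within an eye
    (choroidal thickness is strongly spatially correlated within an eye).
    """

    n_eyes: int = 114
    seed: int = 0
    axial_length_mean: float = 25.46
    axial_length_sd: float = 1.43
    axial_length_bounds: Tuple[float, float] = (22.38, 30.42)
    pmp_mean: float = 5.43
    pmp_sd: float = 3.47
    tilt_mean: float = 53.08
    tilt_sd: float = 23.93
    tilt_al_corr: float = 0.05
    age_mean: float = 25.8
    age_sd: float = 3.9
    age_bounds: Tuple[float, float] = (20.0, 40.0)
    refractive_mean: float = -4.79
    refractive_sd: float = 3.31
    refractive_al_slope: float = -2.0  # D per mm, myopic shift with elongation
    sex_ratio_male: float = 79 / 114
    ppa_prevalence: float = 82 / 119
    ppa_al_slope: float = 0.8  # log-odds per mm of axial length
    sector_baselines: Dict[str, float] = field(default_factory=lambda: dict(SECTOR_BASELINE_MEAN))
    sector_sds: Dict[str, float] = field(default_factory=lambda: dict(SECTOR_BASELINE_SD))
    beta_al: Optional[Dict[str, float]] = None
    beta_pmp: Optional[Dict[str, float]] = None
    beta_tilt: Optional[Dict[str, float]] = None
    residual_sd: Optional[Dict[str, float]] = None
    residual_shared_frac: float = 0.85
    ineligible_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be positive")
        for name in ("axial_length_sd", "pmp_sd", "tilt_sd", "age_sd", "refractive_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.axial_length_bounds[0] >= self.axial_length_bounds[1]:
            raise ValueError("axial_length_bounds must be ordered")
        if not 0.0 <= self.residual_shared_frac <= 1.0:
            raise ValueError("residual_shared_frac must be in [0, 1]")
        if not 0.0 <= self.ineligible_fraction < 1.0:
            raise ValueError("ineligible_fraction must be in [0, 1)")
        if not -1.0 < self.tilt_al_corr < 1.0:
            raise ValueError("tilt_al_corr must be in (-1, 1)")
        if self.beta_al is None or self.beta_pmp is None or self.beta_tilt is None or self.residual_sd is None:
            b_al, b_pmp, b_tilt, r_sd = calibrated_effects(
                TARGET_R_AL, TARGET_R_PMP, TARGET_R_TILT,
                self.sector_sds, self.axial_length_sd, self.pmp_sd,
                self.tilt_sd, self.tilt_al_corr,
            )
            if self.beta_al is None:
                self.beta_al = b_al
            if self.beta_pmp is None:
                self.beta_pmp = b_pmp
            if self.beta_tilt is None:
                self.beta_tilt = b_tilt
            if self.residual_sd is None:
                self.residual_sd = r_sd
        for d in (self.sector_baselines, self.sector_sds, self.beta_al, self.beta_pmp, self.beta_tilt, self.residual_sd):
            if set(d) != set(SECTORS):
                raise ValueError("per-sector dictionaries must cover all 8 sectors")


@dataclass
class TraceConfig:
    """Configuration of synthetic boundary traces and RPE markings.

    ``axial_scale`` is the axial pixel pitch (µm/px). ``rpe_noise_sd`` and
    ``csi_noise_sd`` model boundary-localization jitter on the two traced
    interfaces; ``marking_noise_sd`` the extra jitter of manual RPE marking.
    """

    n_ascans: int = 1024
    axial_scale: float = 2.6
    rpe_noise_sd: float = 2.0
    csi_noise_sd: float = 1.5
    marking_noise_sd: float = 2.0
    n_marked_points: int = 64
    rpe_offset_px: float = 250.0

    def __post_init__(self) -> None:
        if self.n_ascans < 64:
            raise ValueError("n_ascans must be >= 64")
        if min(self.rpe_noise_sd, self.csi_noise_sd, self.marking_noise_sd) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.axial_scale <= 0:
            raise ValueError("axial_scale must be positive")
        if self.n_marked_points < 6:
            raise ValueError("need at least 6 marked points")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: Tuple[float, float], size: int) -> np.ndarray:
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a reproducible synthetic cohort table (one row per right eye)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_eyes

    al = _truncated_normal(rng, config.axial_length_mean, config.axial_length_sd,
                           config.axial_length_bounds, n)
    pmp = rng.normal(config.pmp_mean, config.pmp_sd, size=n)
    rho = config.tilt_al_corr
    tilt_slope = rho * config.tilt_sd / config.axial_length_sd
    tilt = np.clip(
        config.tilt_mean
        + tilt_slope * (al - config.axial_length_mean)
        + rng.normal(0.0, config.tilt_sd * math.sqrt(1.0 - rho * rho), size=n),
        0.0, None,
    )
    age = _truncated_normal(rng, config.age_mean, config.age_sd, config.age_bounds, n)
    re_resid_var = config.refractive_sd ** 2 - (config.refractive_al_slope * config.axial_length_sd) ** 2
    re_resid_sd = math.sqrt(max(re_resid_var, 0.25))
    refraction = (
        config.refractive_mean
        + config.refractive_al_slope * (al - config.axial_length_mean)
        + rng.normal(0.0, re_resid_sd, size=n)
    )
    sex = np.where(rng.random(n) < config.sex_ratio_male, "M", "F")
    base_logit = math.log(config.ppa_prevalence / (1.0 - config.ppa_prevalence))
    ppa_p = 1.0 / (1.0 + np.exp(-(base_logit + config.ppa_al_slope * (al - config.axial_length_mean))))
    ppa = rng.random(n) < ppa_p

    shared = rng.normal(0.0, 1.0, size=n)
    sectors_um: Dict[str, np.ndarray] = {}
    for s in SECTORS:
        r_sd = config.residual_sd[s]
        lam = math.sqrt(config.residual_shared_frac) * r_sd
        eps_sd = math.sqrt(1.0 - config.residual_shared_frac) * r_sd
        val = (
            config.sector_baselines[s]
            + config.beta_al[s] * (al - config.axial_length_mean)
            + config.beta_pmp[s] * (pmp - config.pmp_mean)
            + config.beta_tilt[s] * (tilt - config.tilt_mean)
            + lam * shared
            + (rng.normal(0.0, eps_sd, size=n) if eps_sd > 0 else 0.0)
        )
        sectors_um[s] = np.clip(val, 1.0, None)

    bcva = np.clip(rng.normal(-0.08, 0.06, size=n), -0.3, 0.1)
    iop = np.clip(rng.normal(14.5, 2.5, size=n), 8.0, 21.0)

    df = pd.DataFrame({
        "eye_id": [f"eye{i:04d}" for i in range(n)],
        "laterality": "right",
        "age_years": age,
        "sex": sex,
        "refractive_error_d": refraction,
        "axial_length_mm": al,
        "pmp_deg": pmp,
        "tilt_px": tilt,
        **{f"ppct_{s.lower()}": sectors_um[s] for s in SECTORS},
        "ppa": ppa,
        "bcva_logmar": bcva,
        "iop_mmhg": iop,
        "has_ocular_disease": False,
        "has_staphyloma": False,
        "has_disc_anomaly": False,
        "prior_surgery": False,
        "poor_image_quality": False,
    })

    n_excl = int(round(config.ineligible_fraction * n))
    if n_excl:
        flagged = rng.choice(n, size=n_excl, replace=False)
        df.loc[flagged, "has_ocular_disease"] = True
    return df[COHORT_COLUMNS]


def landmarks_from_pmp(pmp_deg: float, laterality: str = "right",
                       disc_fovea_distance_um: float = 4500.0) -> FundusLandmarks:
    """Place the fovea at the given PMP angle from a disc at the origin."""
    dx = disc_fovea_distance_um * math.cos(math.radians(pmp_deg))
    dy = disc_fovea_distance_um * math.sin(math.radians(pmp_deg))  # inferior positive (y down)
    x_sign = -1.0 if laterality == "right" else 1.0
    return FundusLandmarks(disc_center=(0.0, 0.0), fovea=(x_sign * dx, dy), laterality=laterality)


def generate_trace(
    eye: pd.Series,
    tconfig: TraceConfig,
    seed: Optional[int] = None,
) -> Tuple[CircumpapillaryTrace, MarkedRpePoints]:
    """Forward-model one eye's circumpapillary boundary traces.

    The RPE trajectory is one sinusoid period with amplitude equal to the
    eye's tilt (px) and a random phase; the sclerochoroidal interface sits
    below it by the eye's angular thickness profile (periodic cubic spline
    through the 8 sector anchors, µm converted to px) plus independent
    interface noise. Manual markings sample the noisy RPE trace at
    ``n_marked_points`` positions with extra marking noise.
    """
    rng = np.random.default_rng(seed)
    n = tconfig.n_ascans
    tilt_px = float(eye["tilt_px"])
    pmp = float(eye["pmp_deg"])
    laterality = str(eye.get("laterality", "right"))

    sector_map = build_sector_map(landmarks_from_pmp(pmp, laterality))
    anchor_angles = np.array([sector_map[s] for s in SECTORS])
    anchor_um = np.array([float(eye[f"ppct_{s.lower()}"]) for s in SECTORS])
    order = np.argsort(anchor_angles)
    ang_sorted = anchor_angles[order]
    val_sorted = anchor_um[order]
    spline = CubicSpline(
        np.append(ang_sorted, ang_sorted[0] + 360.0),
        np.append(val_sorted, val_sorted[0]),
        bc_type="periodic",
    )
    angles = np.arange(n) * (360.0 / n)
    rel = (angles - ang_sorted[0]) % 360.0 + ang_sorted[0]
    profile_px = np.clip(spline(rel), 1.0, None) / tconfig.axial_scale

    c_true = rng.uniform(0.0, 2.0 * math.pi)
    clean_rpe = tconfig.rpe_offset_px + tilt_px * np.sin(2.0 * math.pi * np.arange(n) / n - c_true)
    z_rpe = clean_rpe + rng.normal(0.0, tconfig.rpe_noise_sd, size=n)
    z_csi = z_rpe + profile_px + rng.normal(0.0, tconfig.csi_noise_sd, size=n)
    z_csi = np.maximum(z_csi, z_rpe)  # non-negative choroid invariant

    trace = CircumpapillaryTrace(z_rpe=z_rpe, z_csi=z_csi, axial_scale=tconfig.axial_scale, n_ascans=n)

    # uniform coverage of the full period keeps the sampled sine mean-zero,
    # so recentering leaves no offset for the fit to absorb
    idx = np.unique(np.floor(np.linspace(0, n, tconfig.n_marked_points, endpoint=False)).astype(int))
    marked = MarkedRpePoints(
        x=idx.astype(float),
        y=z_rpe[idx] + rng.normal(0.0, tconfig.marking_noise_sd, size=idx.size),
        scan_width_px=float(n),
    )
    return trace, marked
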