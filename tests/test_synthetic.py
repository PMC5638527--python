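import numpy as np
import pandas as pd
import pytest

from ppct.geometry import SECTORS, build_sector_map
from ppct.stats import spearman
from ppct.synthetic_data import (
    SECTOR_BASELINE_MEAN,
    CohortConfig,
    TraceConfig,
    calibrated_effects,
    generate_cohort,
    generate_trace,
    landmarks_from_pmp,
    TARGET_R_AL,
    TARGET_R_PMP,
    TARGET_R_TILT,
    SECTOR_BASELINE_SD,
)
from ppct.thickness import measure_ppct
from ppct.tilt_fit import measure_tilt

ZERO_EFFECTS = dict(
    beta_al={s: 0.0 for s in SECTORS},
    beta_pmp={s: 0.0 for s in SECTORS},
    beta_tilt={s: 0.0 for s in SECTORS},
)


class TestGenerateCohort:
    def test_same_seed_reproduces_identical_table(self):
        a = generate_cohort(CohortConfig(n_eyes=50, seed=11))
        b = generate_cohort(CohortConfig(n_eyes=50, seed=11))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(n_eyes=50, seed=11))
        b = generate_cohort(CohortConfig(n_eyes=50, seed=12))
        assert not a["axial_length_mm"].equals(b["axial_length_mm"])

    def test_zero_effects_zero_noise_hit_baselines_exactly(self):
        cfg = CohortConfig(n_eyes=20, seed=0, residual_sd={s: 0.0 for s in SECTORS}, **ZERO_EFFECTS)
        df = generate_cohort(cfg)
        for s in SECTORS:
            assert np.allclose(df[f"ppct_{s.lower()}"], SECTOR_BASELINE_MEAN[s])

    def test_axial_length_distribution_matches_configuration(self):
        df = generate_cohort(CohortConfig(n_eyes=5000, seed=21))
        # truncated normal on [22.38, 30.42] has mean ~25.52
        assert df["axial_length_mm"].mean() == pytest.approx(25.46, abs=0.1)
        assert df["axial_length_mm"].between(22.38, 30.42).all()

    def test_programmed_axial_length_effect_direction_recovered(self):
        df = generate_cohort(CohortConfig(n_eyes=5000, seed=22))
        res = spearman(df["axial_length_mm"], df["ppct_t"])
        assert res.r < 0
        assert res.p < 1e-6

    def test_effect_calibration_inverts_to_target_correlations(self):
        b_al, b_pmp, b_tilt, r_sd = calibrated_effects(
            TARGET_R_AL, TARGET_R_PMP, TARGET_R_TILT, SECTOR_BASELINE_SD,
            1.43, 3.47, 23.93, 0.05)
        # forward-substitute the derivation: implied marginal correlations
        # must equal the targets, and variances must sum to the sector SDs
        rho = 0.05
        for s in SECTORS:
            sd_y = SECTOR_BASELINE_SD[s]
            u_a = b_al[s] * 1.43 / sd_y
            u_t = b_tilt[s] * 23.93 / sd_y
            u_p = b_pmp[s] * 3.47 / sd_y
            assert u_a + rho * u_t == pytest.approx(TARGET_R_AL[s], abs=1e-12)
            assert u_p == pytest.approx(TARGET_R_PMP[s], abs=1e-12)
            if TARGET_R_TILT[s] != 0.0:
                assert u_t + rho * u_a == pytest.approx(TARGET_R_TILT[s], abs=1e-12)
            total_var = (u_a**2 + u_t**2 + u_p**2 + 2 * rho * u_a * u_t) * sd_y**2 + r_sd[s]**2
            assert total_var == pytest.approx(sd_y**2, rel=1e-12)

    def test_ineligible_fraction_flags_expected_count(self):
        df = generate_cohort(CohortConfig(n_eyes=200, seed=3, ineligible_fraction=0.1))
        assert int(df["has_ocular_disease"].sum()) == 20

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_eyes=0)
        with pytest.raises(ValueError):
            CohortConfig(residual_shared_frac=1.5)


class TestGenerateTrace:
    def _eye(self, tilt=50.0, pmp=5.0):
        data = {"eye_id": "e0", "laterality": "right", "pmp_deg": pmp, "tilt_px": tilt}
        data.update({f"ppct_{s.lower()}": SECTOR_BASELINE_MEAN[s] for s in SECTORS})
        return pd.Series(data)

    def test_zero_tilt_no_noise_is_flat(self):
        tcfg = TraceConfig(rpe_noise_sd=0.0, csi_noise_sd=0.0, marking_noise_sd=0.0)
        trace, _ = generate_trace(self._eye(tilt=0.0), tcfg, seed=1)
        assert np.allclose(trace.z_rpe, trace.z_rpe[0])

    def test_noiseless_tilt_recovered_by_sine_fit(self):
        tcfg = TraceConfig(rpe_noise_sd=0.0, csi_noise_sd=0.0, marking_noise_sd=0.0)
        _, marked = generate_trace(self._eye(tilt=50.0), tcfg, seed=2)
        fit = measure_tilt(marked)
        assert fit.a == pytest.approx(50.0, abs=1e-4)

    def test_same_seed_reproduces_identical_trace(self):
        tcfg = TraceConfig()
        t1, m1 = generate_trace(self._eye(), tcfg, seed=9)
        t2, m2 = generate_trace(self._eye(), tcfg, seed=9)
        assert np.array_equal(t1.z_rpe, t2.z_rpe)
        assert np.array_equal(t1.z_csi, t2.z_csi)
        assert np.array_equal(m1.y, m2.y)

    def test_noisy_round_trip_recovers_programmed_values(self):
        # stated noise: 2 px boundary jitter, 2 px marking jitter
        eye = self._eye(tilt=53.0, pmp=5.43)
        tcfg = TraceConfig(rpe_noise_sd=2.0, marking_noise_sd=2.0)
        trace, marked = generate_trace(eye, tcfg, seed=4)
        sector_map = build_sector_map(landmarks_from_pmp(5.43))
        thick = measure_ppct(trace, sector_map, window_deg=5.0)
        for s in SECTORS:
            assert thick[s] == pytest.approx(SECTOR_BASELINE_MEAN[s], abs=5.0)
        fit = measure_tilt(marked)
        assert fit.a == pytest.approx(53.0, abs=4.0)
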