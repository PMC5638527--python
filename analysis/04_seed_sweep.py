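"""Replicate the qualitative association pattern across 20 simulated cohorts.

For each seed: does every sector's ppCT correlate negatively with axial
length, and is the disc-tilt correlation significant in exactly the
temporal and inferotemporal sectors? Writes results/seed_sweep.csv.
"""

from pathlib import Path

import pandas as pd

from ppct.geometry import SECTORS
from ppct.pipeline import run_study
from ppct.synthetic_data import CohortConfig, generate_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for seed in range(20):
        grid = run_study(generate_cohort(CohortConfig(n_eyes=114, seed=seed))) \
            .association_grid.set_index(["sector", "predictor"])
        sig_tilt = sorted(s for s in SECTORS if grid.loc[(s, "tilt"), "spearman_p"] < 0.05)
        rows.append({
            "seed": seed,
            "al_all_negative": all(grid.loc[(s, "axial_length"), "spearman_r"] < 0 for s in SECTORS),
            "pmp_all_positive": all(grid.loc[(s, "pmp"), "spearman_r"] > 0 for s in SECTORS),
            "tilt_significant_sectors": "+".join(sig_tilt),
            "tilt_pattern_exact": sig_tilt == ["IT", "T"],
        })
    df = pd.DataFrame(rows)
    ROOT.mkdir(parents=True, exist_ok=True)
    df.to_csv(ROOT / "seed_sweep.csv", index=False)
    print(df.to_string(index=False))
    print(f"\naxial-length correlations negative in all sectors: {df.al_all_negative.sum()}/20 seeds")
    print(f"tilt correlation significant in exactly T and IT:   {df.tilt_pattern_exact.sum()}/20 seeds")


if __name__ == "__main__":
    main()
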