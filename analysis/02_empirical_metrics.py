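#!/usr/bin/env python
"""Model-free accuracy metrics on the simulated study.

Reads the dataset written by 01_simulate_study.py, merges measured skin
tone, and tabulates bias / precision / A_RMS, FNR / FPR at SpO2 thresholds
92% and 94%, AUC and occult hypoxaemia — overall, per device, and per
skin-tone category.  These raw tables are the oracle surface the model
suite is judged against.
"""

from pathlib import Path

import pandas as pd

from oxiskin.empirical import evaluate_by
from oxiskin.io import read_observations, read_skin_tones

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    obs = read_observations(ROOT / "data" / "observations.csv")
    tones = read_skin_tones(ROOT / "data" / "skin_tones.csv")
    df = obs.merge(tones[["patient_id", "ita_degrees", "category"]],
                   on="patient_id")

    out = ROOT / "empirical"
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "overall": evaluate_by(df),
        "by_device": evaluate_by(df, ["device_model"]),
        "by_category": evaluate_by(df, ["category"]),
    }
    for name, tab in tables.items():
        tab.to_csv(out / f"{name}.csv", index=False)

    pd.set_option("display.width", 120)
    print("== overall ==")
    print(tables["overall"].round(3).to_string(index=False))
    print("\n== by skin-tone category ==")
    cols = ["category", "n", "bias_pp", "arms_pp", "fnr92", "fpr92", "auc"]
    order = ["very_light", "light", "intermediate", "tan", "brown", "dark"]
    tab = tables["by_category"].set_index("category").reindex(order)
    print(tab.reset_index()[cols].round(3).to_string(index=False))
    print("\nFalse negative rates rise and false positive rates fall as "
          "skin tone darkens, by construction of the device profiles.")


if __name__ == "__main__":
    main()
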