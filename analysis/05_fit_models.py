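"""Fit and benchmark the oil-prediction linear models.

Per cultivar: the three-band model Y ~ R + G + B, its VIF-reduced version
where the bands are collinear (VIF > 5), and one Y ~ CI model per selected
predictor — all trained and tested on identical random 70/30 partitions,
repeated five times.  Test metrics: R2 (predicted-vs-true squared
correlation), RMSE and MAE in %FW.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from oleohyst import make_splits, run_model_suite

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main():
    try:
        table = pd.read_csv(RESULTS / "index_table.csv")
        selection = pd.read_csv(RESULTS / "selection.csv")
    except FileNotFoundError:
        sys.exit("run 03_build_indexes.py and 04_score_hysteresis.py first")

    frames, resid_rows = [], []
    rng = np.random.default_rng(SEED)
    for name, sub in table.groupby("cultivar", sort=False):
        sub = sub.reset_index(drop=True)
        selected = selection.query("cultivar == @name and selected")["ci_name"].tolist()
        plan = make_splits(len(sub), seed=int(rng.integers(0, 2**31 - 1)))
        metrics, residuals = run_model_suite(sub, selected, plan)
        metrics.insert(0, "cultivar", name)
        frames.append(metrics)
        for mid, vec in residuals.items():
            resid_rows += [{"cultivar": name, "model_id": mid, "residual": v} for v in vec]
    metrics = pd.concat(frames, ignore_index=True)
    metrics.to_csv(RESULTS / "metrics.csv", index=False)
    pd.DataFrame(resid_rows).to_csv(RESULTS / "residuals.csv", index=False)

    print(f"{len(metrics)} (model, iteration) rows -> {RESULTS/'metrics.csv'}")
    rgb = metrics.query("model_id == 'RGB'").groupby("cultivar")
    for name, sub in rgb:
        reduced = metrics.query("cultivar == @name and model_id.str.startswith('RGB_reduced')")
        note = f" (reduced: {reduced.model_id.iloc[0]})" if len(reduced) else ""
        print(f"  {name:10s} RGB model median R2 = {sub.r2.median():.3f}, "
              f"RMSE = {sub.rmse.median():.2f} %FW{note}")


if __name__ == "__main__":
    main()
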