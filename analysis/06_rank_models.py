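"""Rank the benchmark models with the Global Performance Indicator.

Normalizes R2, RMSE and MAE to [0, 1] within each cultivar, sums the
signed deviations from the pooled medians (alpha = -1 for R2, +1 for the
error metrics), and ranks the models by descending GPI.  The model built
from the highest-FI predictor is flagged to inspect how hysteresis-based
selection concords with realized accuracy.
"""

import sys
from pathlib import Path

import pandas as pd

from oleohyst import gpi, normalize_metrics, rank_models

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    try:
        metrics = pd.read_csv(RESULTS / "metrics.csv")
        selection = pd.read_csv(RESULTS / "selection.csv")
    except FileNotFoundError:
        sys.exit("run 05_fit_models.py first")

    ranking = rank_models(gpi(normalize_metrics(metrics)), selection=selection)
    ranking.to_csv(RESULTS / "ranking.csv", index=False)

    print(f"{len(ranking)} ranked models -> {RESULTS/'ranking.csv'}")
    for name, sub in ranking.groupby("cultivar"):
        top = sub.iloc[0]
        flagged = sub.query("is_max_fi")
        fi_rank = int(flagged["rank"].min()) if len(flagged) else None
        print(f"  {name:10s} best: {top.model_id:24s} GPI={top.gpi:6.2f}  "
              f"max-FI predictor rank: {fi_rank}")


if __name__ == "__main__":
    main()
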