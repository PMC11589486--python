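"""Quantify hysteresis, correlation and fitness per (cultivar, predictor).

For every cultivar and candidate predictor (35 CIs + 3 raw bands) this
computes the Hyst index from the oil-vs-CI loop decomposition, the Spearman
rank correlation, and the Fitness Index FI = |Hyst| + |rho|, then selects
the top FI quintile as model predictors.
"""

import sys
from pathlib import Path

import pandas as pd

from oleohyst import score_predictors

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    path = RESULTS / "index_table.csv"
    if not path.exists():
        sys.exit("run 03_build_indexes.py first")
    table = pd.read_csv(path)
    selection = score_predictors(table)
    selection.to_csv(RESULTS / "selection.csv", index=False)

    print(f"scored {len(selection)} (cultivar, predictor) pairs -> {RESULTS/'selection.csv'}")
    for name, sub in selection.groupby("cultivar"):
        sel = sub.query("selected").sort_values("fi", ascending=False)
        lo, hi = sel.fi.min(), sel.fi.max()
        print(f"  {name:10s} selected {len(sel):2d}/{len(sub)}  FI range {lo:.2f}:{hi:.2f}  "
              f"top: {', '.join(sel.ci_name.head(4))}")
    print("Hyst spans", f"{selection.hyst.min():.2f} to {selection.hyst.max():.2f}",
          "(-1 = no hysteresis, +1 = season-wide loop)")


if __name__ == "__main__":
    main()
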