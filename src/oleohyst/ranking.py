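"""Global Performance Indicator (GPI) model ranking.

Within each cultivar, every model's per-iteration R², RMSE and MAE are
min-max normalized to [0, 1] over the pooled set of all models and
iterations, and the GPI sums the signed deviations of each normalized value
from the pooled median of its metric:

    GPI_m = sum_i sum_j alpha_i * (median_i - O_ij^(m)),
    alpha = -1 for R² and +1 for RMSE and MAE,

so a model that beats the median on every metric in every iteration gets a
positive GPI, and the more accurate the model the higher the GPI.  Models
are ranked by descending GPI (ties share the minimum rank) and the model
built from the highest-FI predictor is flagged for the concordance check
between FI-based selection and realised accuracy.

The median is taken over the pooled models-by-iterations values; the
per-model variant (each model's own five-iteration median) is available via
``median_scope="model"`` for sensitivity analysis but cannot separate
models, since each model's deviations then cancel around its own median.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = ["ALPHA", "normalize_metrics", "gpi", "rank_models"]

ALPHA = {"r2": -1.0, "rmse": 1.0, "mae": 1.0}
METRICS = tuple(ALPHA)


def normalize_metrics(metrics: pd.DataFrame, group_col: str | None = "cultivar") -> pd.DataFrame:
    """Long-form table with min-max normalized metric values.

    Input: one row per (model_id, iteration) with columns r2, rmse, mae
    (plus optionally ``cultivar``).  Output: long rows
    (cultivar, model_id, iteration, metric, raw, normalized) where
    normalization is per (cultivar, metric) over all models x iterations.
    A zero-range metric normalizes to all zeros with a warning.
    """
    needed = {"model_id", "iteration", *METRICS}
    missing = needed - set(metrics.columns)
    if missing:
        raise ParameterError(f"metrics table missing columns: {sorted(missing)}")
    df = metrics.copy()
    if group_col not in df.columns:
        df = df.assign(**{group_col or "cultivar": ""})
        group_col = group_col or "cultivar"
    long = df.melt(
        id_vars=[group_col, "model_id", "iteration"],
        value_vars=list(METRICS), var_name="metric", value_name="raw",
    )
    out = []
    for (grp, metric), sub in long.groupby([group_col, "metric"], sort=False):
        raw = sub["raw"].to_numpy(dtype=float)
        finite = raw[np.isfinite(raw)]
        if len(finite) < 2:
            raise ParameterError(f"{grp}/{metric}: need >= 2 finite values to normalize")
        lo, hi = float(finite.min()), float(finite.max())
        if hi == lo:
            warnings.warn(
                f"{grp}/{metric}: zero range, normalized values set to 0 (degenerate comparison)",
                stacklevel=2,
            )
            norm = np.zeros_like(raw)
        else:
            norm = (raw - lo) / (hi - lo)
        out.append(sub.assign(normalized=norm))
    return pd.concat(out, ignore_index=True)


def gpi(normalized: pd.DataFrame, group_col: str = "cultivar",
        median_scope: str = "pooled") -> pd.DataFrame:
    """Per-model GPI from a normalized long-form metric table.

    ``median_scope='pooled'`` (default): the reference median of each metric
    is taken over all models x iterations within the cultivar.  Raises on a
    missing (model, iteration, metric) cell so every model is scored on the
    same grid.
    """
    if median_scope not in ("pooled", "model"):
        raise ParameterError(f"median_scope: 'pooled' or 'model', got {median_scope!r}")
    results = []
    for grp, sub in normalized.groupby(group_col, sort=False):
        counts = sub.groupby(["model_id", "metric"])["iteration"].count()
        if counts.nunique() != 1:
            raise ParameterError(f"{grp}: incomplete (model, iteration, metric) grid")
        medians = sub.groupby("metric")["normalized"].median()
        for model_id, msub in sub.groupby("model_id", sort=False):
            total = 0.0
            for metric in METRICS:
                vals = msub.loc[msub["metric"] == metric, "normalized"].to_numpy(dtype=float)
                center = (float(np.median(vals)) if median_scope == "model"
                          else float(medians[metric]))
                total += ALPHA[metric] * float(np.sum(center - vals))
            results.append({group_col: grp, "model_id": model_id, "gpi": total})
    return pd.DataFrame(results)


def rank_models(gpis: pd.DataFrame, selection: pd.DataFrame | None = None,
                group_col: str = "cultivar") -> pd.DataFrame:
    """Rank models by descending GPI within each cultivar.

    Ties share the minimum rank.  When a selection table (with columns
    cultivar, ci_name, fi) is given, the single-CI model(s) built from the
    highest-FI predictor get ``is_max_fi = True``.  Indexes that are
    monotone transforms of one another (e.g. G/R and (G-R)/(G+R)) carry
    identical Spearman rho and, when monotone in time, identical Hyst, so
    the FI maximum is frequently an exact tie; every exactly-tied maximum
    is flagged, because FI cannot distinguish the tied predictors.
    """
    if len(gpis) < 2:
        raise ParameterError("rank_models: need >= 2 models")
    out = gpis.copy()
    out["rank"] = (
        out.groupby(group_col)["gpi"].rank(method="min", ascending=False).astype(int)
    )
    out["is_max_fi"] = False
    if selection is not None and len(selection):
        for grp, sub in selection.groupby(group_col, sort=False):
            fis = sub.dropna(subset=["fi"])
            if fis.empty:
                continue
            top = float(fis["fi"].max())
            best = fis.loc[fis["fi"] >= top - 1e-9, "ci_name"]
            hit = (out[group_col] == grp) & out["model_id"].isin(
                [f"CI:{b}" for b in best]
            )
            out.loc[hit, "is_max_fi"] = True
    return out.sort_values([group_col, "rank"], kind="stable").reset_index(drop=True)
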