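"""End-to-end driver: simulate -> indexes -> hysteresis -> models -> ranking.

``run_all`` chains the whole analysis on simulated (or user-supplied)
seasonal tables and returns every intermediate product, so scripts, tests
and the CLI all exercise one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cultivars import CultivarParams, default_cultivars
from .hysteresis import score_predictors
from .indexes import compute_index_columns
from .modeling import make_splits, run_model_suite
from .ranking import gpi, normalize_metrics, rank_models
from .simulate import generate_dataset

__all__ = ["PipelineResult", "build_index_tables", "run_all"]


@dataclass
class PipelineResult:
    season: pd.DataFrame                  # all cultivars stacked
    index_table: pd.DataFrame             # season + 35 CI columns
    selection: pd.DataFrame               # per (cultivar, candidate) Hyst/rho/FI/selected
    metrics: pd.DataFrame                 # per (cultivar, model, iteration)
    ranking: pd.DataFrame                 # per (cultivar, model) GPI + rank
    residuals: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)


def build_index_tables(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-cultivar season tables and append the CI columns."""
    season = pd.concat(tables.values(), ignore_index=True)
    ci = compute_index_columns(season)
    return pd.concat([season, ci], axis=1)


def run_all(
    config: list[CultivarParams] | None = None,
    seed: int = 0,
    tables: dict[str, pd.DataFrame] | None = None,
    quintile: float = 0.2,
    include_bands: bool = True,
    spline: bool = True,
    vif_threshold: float = 5.0,
    train_fraction: float = 0.7,
    n_iterations: int = 5,
) -> PipelineResult:
    """Run the full analysis and return every stage's output.

    ``tables`` may carry pre-extracted per-cultivar season tables (e.g. from
    real images); otherwise the synthetic suite in ``config`` (default: the
    six-cultivar presets) is generated from ``seed``.  Model splits derive
    per-cultivar seeds from ``seed`` and are shared across that cultivar's
    models.
    """
    if tables is None:
        config = config if config is not None else default_cultivars()
        tables, _ = generate_dataset(config, seed=seed, with_images=False)
    index_table = build_index_tables(tables)
    selection = score_predictors(index_table, include_bands=include_bands,
                                 quintile=quintile, spline=spline)

    metric_frames, residuals = [], {}
    split_seeds = np.random.SeedSequence(seed).spawn(len(tables))
    for (name, table), ss in zip(tables.items(), split_seeds):
        sub = index_table[index_table["cultivar"] == name].reset_index(drop=True)
        selected = selection.query("cultivar == @name and selected")["ci_name"].tolist()
        plan = make_splits(len(sub), seed=int(np.random.default_rng(ss).integers(0, 2**31 - 1)),
                           train_fraction=train_fraction, n_iterations=n_iterations)
        m, res = run_model_suite(sub, selected, plan, vif_threshold=vif_threshold)
        m.insert(0, "cultivar", name)
        metric_frames.append(m)
        residuals[name] = res
    metrics = pd.concat(metric_frames, ignore_index=True)

    normalized = normalize_metrics(metrics)
    gpis = gpi(normalized)
    ranking = rank_models(gpis, selection=selection)
    season = pd.concat(tables.values(), ignore_index=True)
    return PipelineResult(season=season, index_table=index_table, selection=selection,
                          metrics=metrics, ranking=ranking, residuals=residuals)
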