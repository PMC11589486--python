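"""Oil-prediction linear models under a fixed 70/30 resampling benchmark.

Two model families are compared within each cultivar: the additive
three-band model ``Y ~ Red + Green + Blue`` (optionally reduced by
variance-inflation-factor analysis when the bands are collinear) and
single-predictor models ``Y ~ CI`` for each selected colorimetric index.
All models of a cultivar are trained and tested on byte-identical random
70/30 partitions, repeated five times, so that performance differences
cannot be an artifact of the split.

Test-set accuracy is summarised by R² (squared Pearson correlation of
predicted vs true, the scatter-plot convention; the 1 - RSS/TSS variant is
also reported), RMSE and MAE in response units (%FW).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ParameterError, RankDeficiencyError

__all__ = [
    "SplitPlan",
    "LinearFit",
    "EvalMetrics",
    "make_splits",
    "fit_linear",
    "vif",
    "reduce_by_vif",
    "evaluate",
    "run_model_suite",
]


@dataclass(frozen=True)
class SplitPlan:
    """Benchmark train/test partitions shared by every model of a cultivar."""

    n: int
    train_fraction: float
    n_iterations: int
    seed: int
    assignments: np.ndarray  # (n_iterations, n) bool, True = training row

    @property
    def n_train(self) -> int:
        return int(self.assignments[0].sum())


def make_splits(n: int, seed: int, train_fraction: float = 0.7, n_iterations: int = 5) -> SplitPlan:
    """Draw ``n_iterations`` independent uniform train/test splits.

    The training size is ``round(train_fraction * n)`` with exact
    round-half-even arithmetic (n=45 at 0.7 gives 32), computed via
    fractions so binary float error cannot flip the rounding.
    """
    if n < 10:
        raise ParameterError(f"n: need >= 10 samples to split, got {n}")
    if not 0 < train_fraction < 1:
        raise ParameterError(f"train_fraction: must be in (0, 1), got {train_fraction}")
    n_train = int(round(Fraction(train_fraction).limit_denominator(10**6) * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    assignments = np.zeros((n_iterations, n), dtype=bool)
    for j in range(n_iterations):
        idx = rng.choice(n, size=n_train, replace=False)
        assignments[j, idx] = True
    return SplitPlan(n=n, train_fraction=train_fraction, n_iterations=n_iterations,
                     seed=seed, assignments=assignments)


@dataclass(frozen=True)
class LinearFit:
    """An OLS fit with its diagnostics."""

    model_id: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]   # includes "Intercept"
    p_values: dict[str, float]
    vif: dict[str, float] = field(default_factory=dict)  # empty for 1 predictor
    aic: float = np.nan
    n_obs: int = 0

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        out = np.full(len(design), self.coefficients["Intercept"], dtype=float)
        for name in self.predictors:
            out += self.coefficients[name] * design[name].to_numpy(dtype=float)
        return out


def _design_matrix(design: pd.DataFrame, names) -> np.ndarray:
    X = design[list(names)].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise ParameterError("design contains undefined cells; drop them before fitting")
    return X


def fit_linear(response, design: pd.DataFrame, names=None, model_id: str = "") -> LinearFit:
    """Ordinary least squares with intercept.

    P-values are two-sided t-tests per term; AIC uses the Gaussian profile
    form ``n ln(RSS/n) + 2k`` with ``k = p + 2`` (slopes, intercept and the
    error variance).  A rank-deficient design raises
    :class:`RankDeficiencyError` naming the collinear columns.
    """
    names = tuple(names) if names is not None else tuple(design.columns)
    y = np.asarray(response, dtype=float)
    X = _design_matrix(design, names)
    if len(y) != len(X):
        raise ParameterError("response and design lengths differ")
    if len(y) <= len(names) + 1:
        raise ParameterError(f"need > {len(names) + 1} rows to fit {len(names)} predictors")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        # identify columns that are linear combinations of the preceding ones
        bad = []
        for j in range(1, Xc.shape[1]):
            if np.linalg.matrix_rank(Xc[:, : j + 1]) <= np.linalg.matrix_rank(Xc[:, :j]):
                bad.append(names[j - 1])
        raise RankDeficiencyError(f"rank-deficient design; collinear columns: {bad}", columns=bad)
    res = sm.OLS(y, Xc).fit()
    coef = {"Intercept": float(res.params[0])}
    pval = {"Intercept": float(res.pvalues[0])}
    for i, name in enumerate(names, start=1):
        coef[name] = float(res.params[i])
        pval[name] = float(res.pvalues[i])
    n = len(y)
    rss = float(res.ssr)
    k = len(names) + 2
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    vifs = vif(design[list(names)]) if len(names) >= 2 else {}
    return LinearFit(model_id=model_id or "+".join(names), predictors=names,
                     coefficients=coef, p_values=pval, vif=vifs, aic=float(aic), n_obs=n)


def vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per predictor: ``1 / (1 - R²_p)``.

    ``R²_p`` comes from regressing predictor p on the remaining predictors
    (with intercept).  Perfect collinearity reports ``inf``; a constant
    column reports NaN for that column.
    """
    names = list(design.columns)
    if len(names) < 2:
        raise ParameterError("vif: need >= 2 predictors")
    X = design.to_numpy(dtype=float)
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        xj = X[:, j]
        if np.ptp(xj) == 0:
            out[name] = float("nan")
            continue
        others = np.delete(X, j, axis=1)
        A = sm.add_constant(others, has_constant="add")
        beta, _, _, _ = np.linalg.lstsq(A, xj, rcond=None)
        resid = xj - A @ beta
        tss = float(np.sum((xj - xj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / tss
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def reduce_by_vif(design: pd.DataFrame, threshold: float = 5.0):
    """Iteratively drop the highest-VIF predictor while any VIF > threshold.

    Ties break by column order (earlier column dropped first).  Returns
    ``(retained_names, removal_log)``; stops when one predictor remains.
    """
    names = list(design.columns)
    if len(names) < 2:
        raise ParameterError("reduce_by_vif: need >= 2 predictors")
    removed: list[tuple[str, float]] = []
    while len(names) > 1:
        vifs = vif(design[names])
        finite = {k: (np.inf if np.isinf(v) else v) for k, v in vifs.items() if not np.isnan(v)}
        if not finite or max(finite.values()) <= threshold:
            break
        worst = max(names, key=lambda k: (finite.get(k, -np.inf)))
        removed.append((worst, vifs[worst]))
        names.remove(worst)
    return names, removed


@dataclass(frozen=True)
class EvalMetrics:
    model_id: str
    iteration: int
    r2: float          # squared Pearson correlation, predicted vs true
    r2_rss: float      # 1 - RSS/TSS variant
    rmse: float
    mae: float
    residuals: np.ndarray  # observed - fitted on the test set


def evaluate(fit: LinearFit, test: pd.DataFrame, response_col: str = "oil",
             iteration: int = 0) -> EvalMetrics:
    """Test-set metrics for a fitted model.

    R² follows the predicted-vs-true scatter convention (squared Pearson
    correlation); it is NaN when predictions are constant.  RMSE and MAE are
    computed on raw residuals and always returned; RMSE >= MAE by the
    power-mean inequality.
    """
    if len(test) == 0:
        raise ParameterError("test set is empty")
    y = test[response_col].to_numpy(dtype=float)
    pred = fit.predict(test)
    resid = y - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    if np.ptp(pred) == 0 or np.ptp(y) == 0 or len(y) < 2:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(pred, y)[0, 1] ** 2)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2_rss = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else float("nan")
    return EvalMetrics(model_id=fit.model_id, iteration=iteration, r2=r2,
                       r2_rss=r2_rss, rmse=rmse, mae=mae, residuals=resid)


BAND_MODEL_ID = "RGB"
REDUCED_MODEL_PREFIX = "RGB_reduced"


def run_model_suite(
    table: pd.DataFrame,
    selected: list[str],
    plan: SplitPlan,
    response_col: str = "oil",
    vif_threshold: float = 5.0,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Fit and evaluate every benchmark model on one cultivar's table.

    Models: the full three-band model; its VIF-reduced version when the
    reduction actually removed a band; and one single-CI model per selected
    predictor.  Every model reuses the identical partitions in ``plan``.
    Rows with an undefined value of the model's own predictors are dropped
    pairwise for that model (the plan indexes the full table, so masks are
    intersected).  Returns a metrics table (one row per model x iteration)
    and the residual vectors pooled across iterations per model.
    """
    from .indexes import BAND_COLUMNS

    if plan.n != len(table):
        raise ParameterError(f"plan.n = {plan.n} does not match table rows = {len(table)}")
    missing = [s for s in selected if s not in table.columns]
    if missing:
        raise ParameterError(f"selected predictors not in table: {missing}")

    retained, removal_log = reduce_by_vif(table[BAND_COLUMNS], threshold=vif_threshold)
    model_specs: list[tuple[str, list[str], str]] = [(BAND_MODEL_ID, BAND_COLUMNS, "")]
    if retained != BAND_COLUMNS:
        removed_names = ",".join(n for n, _ in removal_log)
        model_specs.append((f"{REDUCED_MODEL_PREFIX}({'+'.join(retained)})", retained, removed_names))
    for name in selected:
        model_specs.append((f"CI:{name}", [name], ""))

    records = []
    pooled: dict[str, list[np.ndarray]] = {mid: [] for mid, _, _ in model_specs}
    skipped: list[str] = []
    for model_id, predictors, removed_names in model_specs:
        ok = np.ones(len(table), dtype=bool)
        for p in predictors + [response_col]:
            ok &= np.isfinite(table[p].to_numpy(dtype=float))
        for j in range(plan.n_iterations):
            train_mask = plan.assignments[j] & ok
            test_mask = ~plan.assignments[j] & ok
            if train_mask.sum() <= len(predictors) + 1 or test_mask.sum() == 0:
                skipped.append(f"{model_id}@{j}: insufficient rows after undefined-cell removal")
                continue
            train = table.loc[train_mask]
            test = table.loc[test_mask]
            try:
                fit = fit_linear(train[response_col], train[predictors], predictors,
                                 model_id=model_id)
            except RankDeficiencyError as exc:
                skipped.append(f"{model_id}@{j}: {exc}")
                continue
            m = evaluate(fit, test, response_col=response_col, iteration=j)
            pooled[model_id].append(m.residuals)
            records.append({
                "model_id": model_id, "iteration": j, "r2": m.r2, "r2_rss": m.r2_rss,
                "rmse": m.rmse, "mae": m.mae, "aic": fit.aic,
                "n_train": int(train_mask.sum()), "n_test": int(test_mask.sum()),
                "predictors": "+".join(predictors), "removed_by_vif": removed_names,
            })
    metrics = pd.DataFrame(records)
    metrics.attrs["skipped"] = skipped
    residuals = {mid: (np.concatenate(v) if v else np.empty(0)) for mid, v in pooled.items()}
    return metrics, residuals
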