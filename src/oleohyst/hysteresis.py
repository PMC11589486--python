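"""Quantification of the hysteretic oil-vs-CI relationship.

Over a season, oil concentration rises monotonically while many colorimetric
indexes rise and then fall; plotting oil against such a CI therefore traces
an open loop rather than a single-valued curve.  The hysteresis index
condenses that loop into one number in [-1, 1]:

1. find the turning point, the first occurrence of the maximum CI value
   (``CI_max``) in time order;
2. reflect every later (descending-arm) CI value about the maximum,
   ``CI_syn = CI_max + (CI_max - CI_orig)``, so the loop becomes a
   single-valued curve over an extended abscissa;
3. fit one curve through all (abscissa, oil) points, clamp it at zero, and
   integrate it: ``Tot_area`` over the whole abscissa range and
   ``hyst_area`` over the reflected (post-maximum) part only;
4. ``Hyst = (hyst_area - (Tot_area - hyst_area)) / Tot_area``.

``Hyst = -1`` means no descending arm at all (no hysteresis); values near
+1 mean the loop occupies essentially the whole season.  The fitted curve
is a cubic smoothing spline with generalized cross-validation by default; a
plain trapezoid over the raw sorted points (``spline=False``) is kept as an
independent, assumption-free route to the same areas.

A predictor's overall fitness combines loop extent and monotone association:
``FI = |Hyst| + |rho|`` with rho the Spearman rank correlation of oil vs CI;
candidates whose FI falls in the top quintile are promoted to model
predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .errors import ParameterError, SelectionError

__all__ = [
    "HystDecomposition",
    "turning_point",
    "rotate_arm",
    "fit_and_integrate",
    "hyst_index",
    "spearman",
    "fitness_index",
    "select_predictors",
    "score_predictors",
]

_MIN_POINTS = 4
_GRID = 1024  # trapezoid grid for spline integration (>= 512 required)


@dataclass(frozen=True)
class HystDecomposition:
    """Areas and index for one (oil, CI) trajectory."""

    turn_index: int
    ci_max: float
    ci_syn: np.ndarray      # rotated abscissae of the descending arm
    hyst_area: float
    tot_area: float
    hyst: float


def turning_point(ci) -> int:
    """Time-order position of the CI maximum; ties -> first occurrence."""
    ci = np.asarray(ci, dtype=float)
    if ci.ndim != 1 or len(ci) == 0:
        raise ParameterError("ci: need a non-empty 1-D sequence")
    return int(np.argmax(ci))  # argmax returns the first of tied maxima


def rotate_arm(ci_values, ci_max: float):
    """Reflect descending-arm CI values about the maximum.

    ``out = ci_max + (ci_max - ci_orig)``; the distance to ``ci_max`` is
    preserved, and applying the rotation twice is the identity.
    """
    ci_values = np.asarray(ci_values, dtype=float)
    if np.any(ci_values > ci_max + 1e-12):
        raise ParameterError("rotate_arm: input exceeds ci_max")
    return ci_max + (ci_max - ci_values)


def _collapse_duplicates(x, y):
    """Sort by x and average y at duplicate abscissae."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    ux, inverse = np.unique(xs, return_inverse=True)
    uy = np.bincount(inverse, weights=ys) / np.bincount(inverse)
    return ux, uy


def _fitted_curve(x, y, smoothing=None):
    """Cubic (smoothing) spline through the duplicate-collapsed points.

    The abscissa is affinely mapped to [0, 1] before fitting, so the curve
    (and every area ratio built from it) is exactly invariant to positive
    affine rescaling of the CI axis — index values spanning hundreds of
    pixel units and ratios spanning hundredths behave identically.

    GCV-smoothing spline needs >= 5 distinct abscissae; with exactly 4 a
    natural interpolating cubic spline is used, and with fewer (or when the
    smoothing problem is numerically ill-posed) the curve degrades to the
    piecewise-linear interpolant of the points.
    """
    ux, uy = _collapse_duplicates(np.asarray(x, float), np.asarray(y, float))
    span = ux[-1] - ux[0]
    if span <= 0:
        return ux, lambda q: np.full_like(np.asarray(q, float), uy.mean())
    un = (ux - ux[0]) / span
    spl = None
    if len(ux) >= 5:
        try:
            spl = make_smoothing_spline(un, uy, lam=smoothing)
        except Exception:
            try:  # nearly-coincident knots can make GCV ill-posed
                spl = make_smoothing_spline(un, uy, lam=1e-6)
            except Exception:
                spl = None
    elif len(ux) == 4:
        spl = CubicSpline(un, uy, bc_type="natural")
    if spl is None:
        return ux, lambda q: np.interp(q, ux, uy)
    x0 = ux[0]
    return ux, lambda q: spl((np.asarray(q, float) - x0) / span)


def _integrate(curve, lo: float, hi: float) -> float:
    """Trapezoid integral of the zero-clamped curve on a dense grid."""
    if hi <= lo:
        return 0.0
    grid = np.linspace(lo, hi, _GRID)
    vals = np.clip(np.asarray(curve(grid), dtype=float), 0.0, None)
    return float(np.trapezoid(vals, grid))


def fit_and_integrate(x, y, lo: float, hi: float, smoothing=None, spline: bool = True) -> float:
    """Area under the curve fitted to (x, y) between ``lo`` and ``hi``.

    With ``spline=False`` the "curve" is the piecewise-linear interpolant of
    the sorted points (the assumption-free oracle route).  The fitted values
    are clamped at zero before integration, so the area is non-negative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ParameterError("fit_and_integrate: need >= 2 (x, y) pairs of equal length")
    if spline:
        _, curve = _fitted_curve(x, y, smoothing)
    else:
        ux, uy = _collapse_duplicates(x, y)
        curve = lambda q: np.interp(q, ux, uy)  # noqa: E731
    return _integrate(curve, lo, hi)


def hyst_index(ci, oil, smoothing=None, spline: bool = True) -> HystDecomposition:
    """Decompose one time-ordered (CI, oil) trajectory into the Hyst index.

    The same fitted curve provides both areas: ``tot_area`` over the full
    extended abscissa range and ``hyst_area`` over the reflected-arm range
    ``[CI_max, max(CI_syn)]``.  An empty descending arm gives
    ``hyst_area = 0`` and hence ``Hyst = -1`` exactly.
    """
    ci = np.asarray(ci, dtype=float)
    oil = np.asarray(oil, dtype=float)
    if len(ci) != len(oil):
        raise ParameterError("ci and oil must have equal length")
    if len(ci) < _MIN_POINTS:
        raise ParameterError(f"trajectory too short: need >= {_MIN_POINTS} points, got {len(ci)}")
    if np.any(~np.isfinite(ci)) or np.any(~np.isfinite(oil)):
        raise ParameterError("trajectory contains non-finite values; drop undefined cells first")

    turn = turning_point(ci)
    ci_max = float(ci[turn])
    arm = ci[turn + 1 :]
    ci_syn = rotate_arm(arm, ci_max) if len(arm) else np.empty(0)

    x = np.concatenate([ci[: turn + 1], ci_syn])
    lo, hi = float(np.min(x)), float(np.max(x))

    if spline:
        _, curve = _fitted_curve(x, oil, smoothing)
    else:
        ux, uy = _collapse_duplicates(x, oil)
        curve = lambda q: np.interp(q, ux, uy)  # noqa: E731

    tot_area = _integrate(curve, lo, hi)
    if len(ci_syn) == 0 or hi <= ci_max:
        hyst_area = 0.0
    else:
        hyst_area = min(_integrate(curve, ci_max, hi), tot_area)

    if tot_area <= 0:
        hyst = np.nan  # degenerate span (all abscissae equal)
    else:
        hyst = (hyst_area - (tot_area - hyst_area)) / tot_area
    return HystDecomposition(
        turn_index=turn, ci_max=ci_max, ci_syn=ci_syn,
        hyst_area=hyst_area, tot_area=tot_area, hyst=float(hyst),
    )


def spearman(x, y) -> float:
    """Spearman rank correlation (mean ranks at ties); NaN if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ParameterError("spearman: need >= 3 pairs of equal length")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(x, y).statistic
    return float(rho)


def fitness_index(hyst: float, rho: float) -> float:
    """FI = |Hyst| + |rho|, in [0, 2]."""
    for name, v in (("hyst", hyst), ("rho", rho)):
        if not -1 - 1e-9 <= v <= 1 + 1e-9:
            raise ParameterError(f"{name}: must lie in [-1, 1], got {v}")
    return abs(hyst) + abs(rho)


def select_predictors(records: pd.DataFrame, quintile: float = 0.2) -> pd.DataFrame:
    """Mark the top-quintile FI candidates as selected.

    The threshold is the empirical ``1 - quintile`` quantile (linear
    interpolation) of the finite FI values; every record at or above the
    threshold is selected, so threshold ties are all included.  Records with
    undefined FI are excluded from both the threshold and the selection.
    """
    if "fi" not in records.columns:
        raise ParameterError("records: missing 'fi' column")
    fi = records["fi"].to_numpy(dtype=float)
    finite = fi[np.isfinite(fi)]
    if len(finite) == 0:
        raise SelectionError("every FI is undefined; nothing to select")
    if len(finite) < 5:
        raise SelectionError(f"need >= 5 finite FI values to take a quintile, got {len(finite)}")
    threshold = float(np.quantile(finite, 1.0 - quintile, method="linear"))
    out = records.copy()
    with np.errstate(invalid="ignore"):
        out["selected"] = np.isfinite(fi) & (fi >= threshold)
    out.attrs["fi_threshold"] = threshold
    return out


def score_predictors(
    index_table: pd.DataFrame,
    ci_names=None,
    include_bands: bool = True,
    quintile: float = 0.2,
    smoothing=None,
    spline: bool = True,
) -> pd.DataFrame:
    """Per-(cultivar, predictor) Hyst, Spearman rho, FI and selection flag.

    Each cultivar's full pooled seasonal table (replicates as independent
    rows, in time order) forms one trajectory per candidate predictor; the
    candidate pool is the 35 CIs plus, by default, the three raw bands.
    Undefined CI cells are dropped pairwise; a candidate with fewer than 4
    usable points gets undefined scores and drops out of the quintile.
    """
    from .indexes import BAND_COLUMNS, registry

    if ci_names is None:
        ci_names = [d.name for d in registry() if d.name in index_table.columns]
    candidates = list(ci_names) + (BAND_COLUMNS if include_bands else [])
    frames = []
    grouped = index_table.groupby("cultivar", sort=False) if "cultivar" in index_table.columns \
        else [("", index_table)]
    for cultivar, sub in grouped:
        rows = []
        for name in candidates:
            ci = sub[name].to_numpy(dtype=float)
            oil = sub["oil"].to_numpy(dtype=float)
            ok = np.isfinite(ci) & np.isfinite(oil)
            if ok.sum() >= _MIN_POINTS:
                dec = hyst_index(ci[ok], oil[ok], smoothing=smoothing, spline=spline)
                rho = spearman(ci[ok], oil[ok])
                h = dec.hyst
                fi = fitness_index(h, rho) if np.isfinite(h) and np.isfinite(rho) else np.nan
            else:
                h = rho = fi = np.nan
            rows.append({"cultivar": cultivar, "ci_name": name, "hyst": h, "rho": rho, "fi": fi})
        frames.append(select_predictors(pd.DataFrame(rows), quintile=quintile))
    return pd.concat(frames, ignore_index=True)
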