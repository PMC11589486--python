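"""The colorimetric-index (CI) registry and index computation.

A CI is a scalar recombination — ratio, normalized difference, weighted sum
— of the per-sample mean Red, Green and Blue pixel values, used as a
candidate predictor of fruit oil concentration.  The default registry holds
exactly 35 indexes: the members attested for this analysis (NGRDI, VARI,
GLI, NDGBI, NG, GR, GB, BplusG, and the bespoke ``mio_stRGB`` /
``mio_ndRGB``, whose default formulas here are documented placeholders)
plus standard RGB indexes from the vegetation/fruit-color literature.  The
registry can be replaced wholesale from a YAML file of
``name: expression`` entries, so a bespoke roster can be dropped in
verbatim.

Zero denominators yield NaN, the explicit "undefined" marker; downstream
stages exclude the affected (sample, CI) pair only, never the whole row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import JoinError, ParameterError

__all__ = [
    "IndexDefinition",
    "registry",
    "load_registry",
    "compute_indexes",
    "compute_index_columns",
    "normalize_by_oil",
    "build_index_table",
]

BAND_COLUMNS = ["red", "green", "blue"]

# name -> (expression in R, G, B, note on when the denominator vanishes)
_DEFAULT_REGISTRY: list[tuple[str, str, str]] = [
    ("NGRDI", "(G - R) / (G + R)", "G + R != 0"),
    ("VARI", "(G - R) / (G + R - B)", "G + R != B"),
    ("GLI", "(2*G - R - B) / (2*G + R + B)", "2G + R + B != 0"),
    ("NDGBI", "(G - B) / (G + B)", "G + B != 0"),
    ("NG", "G / (R + G + B)", "R + G + B != 0"),
    ("NR", "R / (R + G + B)", "R + G + B != 0"),
    ("NB", "B / (R + G + B)", "R + G + B != 0"),
    ("GR", "G / R", "R != 0"),
    ("GB", "G / B", "B != 0"),
    ("RB", "R / B", "B != 0"),
    ("BR", "B / R", "R != 0"),
    ("BG", "B / G", "G != 0"),
    ("RGRI", "R / G", "G != 0"),
    ("BplusG", "B + G", "always defined"),
    ("RplusG", "R + G", "always defined"),
    ("RplusB", "R + B", "always defined"),
    ("RminusG", "R - G", "always defined"),
    ("RminusB", "R - B", "always defined"),
    ("GminusB", "G - B", "always defined"),
    # bespoke indexes; defaults are placeholders, override via YAML
    ("mio_stRGB", "R + G + B", "always defined"),
    ("mio_ndRGB", "(R - B) / (R + B)", "R + B != 0"),
    ("ExG", "2*G - R - B", "always defined"),
    ("ExR", "1.4*R - G", "always defined"),
    ("ExB", "1.4*B - G", "always defined"),
    ("ExGR", "3*G - 2.4*R - B", "always defined"),
    ("CIVE", "0.441*R - 0.811*G + 0.385*B + 18.78745", "always defined"),
    ("MGRVI", "(G**2 - R**2) / (G**2 + R**2)", "R or G != 0"),
    ("RGBVI", "(G**2 - R*B) / (G**2 + R*B)", "G^2 + RB != 0"),
    ("WI", "(G - B) / (R - G)", "R != G"),
    ("TGI", "G - 0.39*R - 0.61*B", "always defined"),
    ("VEG", "G / (R**0.667 * B**0.333)", "R, B > 0"),
    ("ColorationIndex", "(R - B) / R", "R != 0"),
    ("RdivGB", "R / (G + B)", "G + B != 0"),
    ("GdivRB", "G / (R + B)", "R + B != 0"),
    ("BdivRG", "B / (R + G)", "R + G != 0"),
]


@dataclass(frozen=True)
class IndexDefinition:
    name: str
    expression: str
    domain_note: str = ""

    def __call__(self, R, G, B):
        return _evaluate(self.expression, R, G, B)


def _evaluate(expression: str, R, G, B):
    """Evaluate a CI expression; non-finite results become NaN."""
    ns = {"R": np.asarray(R, dtype=float), "G": np.asarray(G, dtype=float),
          "B": np.asarray(B, dtype=float),
          "sqrt": np.sqrt, "abs": np.abs, "log": np.log, "exp": np.exp}
    with np.errstate(divide="ignore", invalid="ignore"):
        value = eval(expression, {"__builtins__": {}}, ns)  # noqa: S307 - restricted namespace
    value = np.asarray(value, dtype=float)
    value = np.where(np.isfinite(value), value, np.nan)
    return value if value.ndim else float(value)


def registry() -> list[IndexDefinition]:
    """The default roster of exactly 35 colorimetric indexes."""
    defs = [IndexDefinition(n, e, d) for n, e, d in _DEFAULT_REGISTRY]
    assert len({d.name for d in defs}) == len(defs) == 35
    return defs


def load_registry(path) -> list[IndexDefinition]:
    """Load a replacement registry from YAML ``name: expression`` entries."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or not raw:
        raise ParameterError(f"{path}: expected a mapping of index names to expressions")
    defs = [IndexDefinition(str(n), str(e)) for n, e in raw.items()]
    if len({d.name for d in defs}) != len(defs):
        raise ParameterError("registry: duplicate index names")
    return defs


def compute_indexes(sample, defs: Iterable[IndexDefinition] | None = None) -> dict[str, float]:
    """All index values for one color sample (NaN marks undefined)."""
    defs = list(defs) if defs is not None else registry()
    r, g, b = float(sample.red), float(sample.green), float(sample.blue)
    for name, v in (("red", r), ("green", g), ("blue", b)):
        if not 0 <= v <= 255:
            raise ParameterError(f"{name}: mean pixel value {v} outside [0, 255]")
    return {d.name: d(r, g, b) for d in defs}


def compute_index_columns(table: pd.DataFrame, defs=None) -> pd.DataFrame:
    """Vectorized index columns for a table with red/green/blue columns."""
    defs = list(defs) if defs is not None else registry()
    out = {}
    r, g, b = (table[c].to_numpy(dtype=float) for c in BAND_COLUMNS)
    for d in defs:
        out[d.name] = d(r, g, b)
    return pd.DataFrame(out, index=table.index)


def normalize_by_oil(band_mean, oil):
    """Pixel value per unit oil concentration (band / oil), oil > 0."""
    band = np.asarray(band_mean, dtype=float)
    oilv = np.asarray(oil, dtype=float)
    if np.any(oilv <= 0):
        raise ParameterError("oil: must be strictly positive to normalize")
    out = band / oilv
    return out if out.ndim else float(out)


def _resolve_keys(colors: pd.DataFrame, oils: pd.DataFrame) -> list[str]:
    for candidate in (["sample_id"], ["source_id"], ["cultivar", "date_index", "replicate"]):
        if all(c in colors.columns for c in candidate) and all(c in oils.columns for c in candidate):
            return candidate
    raise JoinError(
        "no shared sample key: need 'sample_id', 'source_id' or "
        "('cultivar', 'date_index', 'replicate') on both tables"
    )


def build_index_table(
    colors: pd.DataFrame, oils: pd.DataFrame, defs=None, keys: list[str] | None = None
) -> pd.DataFrame:
    """Inner-join color samples to oil records and append the 35 CI columns.

    Result: key columns + 35 CI columns + red/green/blue + oil.  Duplicate
    keys on either side and empty joins raise :class:`JoinError`; unmatched
    keys are reported on the returned frame's ``attrs['unmatched']``.
    """
    keys = keys or _resolve_keys(colors, oils)
    for side, frame in (("colors", colors), ("oils", oils)):
        dup = frame.loc[frame.duplicated(subset=keys), keys]
        if len(dup):
            raise JoinError(f"duplicated key in {side} table: {dup.iloc[0].tolist()}")
    merged = colors.merge(oils[keys + ["oil"]], on=keys, how="inner")
    if merged.empty:
        raise JoinError("no matching sample keys between colors and oil records")
    ci = compute_index_columns(merged, defs)
    result = pd.concat([merged[keys], ci, merged[BAND_COLUMNS + ["oil"]]], axis=1)
    unmatched_colors = len(colors) - len(merged)
    unmatched_oils = len(oils) - len(merged)
    result.attrs["unmatched"] = {"colors": unmatched_colors, "oils": unmatched_oils}
    return result
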