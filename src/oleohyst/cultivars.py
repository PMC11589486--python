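"""Cultivar parameter sets for the seasonal simulator.

A season is indexed by an integer ``date_index`` running 0 .. ``n_dates``-1
with a nominal 8-day spacing between sampling points; all time-like
parameters (``oil_midpoint``, ``band_fall_onset``, ...) are expressed in
date-index units.  Oil concentration follows a logistic accumulation curve
between ``oil_min`` and ``oil_max`` (% fresh weight), while each color band
follows a rise-then-fall double-logistic whose decline onset
(``band_fall_onset``) differs between cultivars and controls how much of the
hysteresis loop is expressed within the observed season.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError, ParameterError

__all__ = ["CultivarParams", "default_cultivars", "load_config"]


def _as_band_triple(value, name: str) -> tuple[float, float, float]:
    """Broadcast a scalar or length-3 sequence to an (R, G, B) triple."""
    if np.isscalar(value):
        return (float(value),) * 3
    vals = tuple(float(v) for v in value)
    if len(vals) != 3:
        raise ParameterError(f"{name}: expected a scalar or 3 values (R,G,B), got {len(vals)}")
    return vals


@dataclass(frozen=True)
class CultivarParams:
    """Generator settings for one cultivar's season.

    ``band_base``, ``band_rise_amp`` and ``band_fall_amp`` may be given as a
    scalar (shared by R, G, B) or as an (R, G, B) triple of pixel values.
    """

    name: str
    oil_min: float = 5.0            # %FW at season start
    oil_max: float = 15.5           # asymptotic %FW
    oil_midpoint: float = 7.0       # date-index of half-accumulation
    oil_rate: float = 0.5           # logistic steepness, 1/date-index
    band_base: tuple[float, float, float] = (95.0, 110.0, 70.0)
    band_rise_amp: tuple[float, float, float] = (45.0, 45.0, 25.0)
    band_fall_amp: tuple[float, float, float] = (70.0, 65.0, 30.0)
    band_fall_onset: float = 11.5   # date-index where the decline is centred
    # rise dynamics default to the oil dynamics: the early color change and
    # oil accumulation are two faces of the same ripening process, so the
    # band rise tracks the oil logistic unless explicitly decoupled
    band_rise_midpoint: float | None = None
    band_rise_rate: float | None = None
    band_fall_rate: float = 0.9
    noise_oil: float = 0.5          # s.d. of additive Gaussian noise, %FW
    # per-band pixel noise s.d.; blue is noisiest (sensor noise plus
    # blue-background contamination at fruit edges)
    noise_band: tuple[float, float, float] = (1.0, 1.0, 2.5)
    n_dates: int = 15
    replicates: int = 3
    fruit_count_start: int = 120
    fruit_count_end: int = 70

    def __post_init__(self):
        object.__setattr__(self, "band_base", _as_band_triple(self.band_base, "band_base"))
        object.__setattr__(self, "band_rise_amp", _as_band_triple(self.band_rise_amp, "band_rise_amp"))
        object.__setattr__(self, "band_fall_amp", _as_band_triple(self.band_fall_amp, "band_fall_amp"))
        object.__setattr__(self, "noise_band", _as_band_triple(self.noise_band, "noise_band"))
        self.validate()

    def validate(self) -> None:
        if not self.name:
            raise ParameterError("name: must be a non-empty label")
        if not (0 <= self.oil_min < self.oil_max <= 30):
            raise ParameterError(
                f"oil_min/oil_max: require 0 <= oil_min < oil_max <= 30, "
                f"got ({self.oil_min}, {self.oil_max})"
            )
        if self.oil_rate <= 0:
            raise ParameterError(f"oil_rate: must be > 0, got {self.oil_rate}")
        for fname in ("band_base", "band_rise_amp", "band_fall_amp"):
            vals = getattr(self, fname)
            if any(v < 0 or v > 255 for v in vals):
                raise ParameterError(f"{fname}: values must lie in [0, 255], got {vals}")
        if self.n_dates < 4:
            raise ParameterError(f"n_dates: must be >= 4, got {self.n_dates}")
        if self.replicates < 1:
            raise ParameterError(f"replicates: must be >= 1, got {self.replicates}")
        if self.noise_oil < 0:
            raise ParameterError("noise_oil: must be >= 0")
        if any(v < 0 for v in self.noise_band):
            raise ParameterError("noise_band: must be >= 0")
        for fname in ("fruit_count_start", "fruit_count_end"):
            if getattr(self, fname) < 1:
                raise ParameterError(f"{fname}: must be >= 1")

    @property
    def rise_midpoint(self) -> float:
        if self.band_rise_midpoint is not None:
            return self.band_rise_midpoint
        return self.oil_midpoint

    # per-band rate multipliers: anthocyanin-driven red shifts fastest,
    # blue reflectance responds most sluggishly
    _RISE_RATE_MIX = (1.15, 1.0, 0.8)
    _FALL_RATE_MIX = (1.0, 1.1, 0.85)

    def rise_rates(self) -> tuple[float, float, float]:
        base = self.band_rise_rate if self.band_rise_rate is not None else self.oil_rate
        return tuple(base * m for m in self._RISE_RATE_MIX)

    def fall_rates(self) -> tuple[float, float, float]:
        return tuple(self.band_fall_rate * m for m in self._FALL_RATE_MIX)

    def with_(self, **changes) -> "CultivarParams":
        return replace(self, **changes)


def default_cultivars() -> list[CultivarParams]:
    """The six-cultivar default suite.

    Sample sizes give per-cultivar row counts of 45, 40, 40, 45, 45 and 30
    (n_dates x replicates).  Oil asymptotes are ~15.5 %FW except Maiatica
    (~20) and Frantoio (~24).  Band dynamics encode the green-to-purple
    ripening shift: red rises proportionally more early on while green loses
    proportionally more late, so ratio-type indexes (G/R and relatives)
    decline near-monotonically as oil accumulates even though every raw band
    rises then falls.  The band-decline onset is ~3 weeks (about
    2.5 sampling intervals) earlier in Leccino than in the late-ripening
    cultivars, and Koroneiki's red band barely declines at all, so the suite
    spans the full range of incomplete hysteresis loops.  Fruit counts per
    image shrink over the season as fruits grow.
    """
    return [
        CultivarParams(
            name="Arbequina", oil_max=15.5, oil_midpoint=5.5, oil_rate=0.38,
            band_base=(90, 125, 70), band_rise_amp=(55, 22, 15),
            band_fall_amp=(70, 85, 14), band_fall_onset=11.5,
            n_dates=15, replicates=3, fruit_count_start=169, fruit_count_end=97,
        ),
        CultivarParams(
            name="Fasola", oil_max=15.5, oil_midpoint=6.0, oil_rate=0.4,
            band_base=(88, 120, 72), band_rise_amp=(60, 25, 14),
            band_fall_amp=(80, 90, 13), band_fall_onset=15.0,
            n_dates=20, replicates=2, fruit_count_start=47, fruit_count_end=37,
        ),
        CultivarParams(
            name="Frantoio", oil_max=24.0, oil_midpoint=8.0, oil_rate=0.33,
            band_base=(92, 118, 70), band_rise_amp=(50, 20, 16),
            band_fall_amp=(75, 85, 15), band_fall_onset=11.0,
            n_dates=20, replicates=2, fruit_count_start=97, fruit_count_end=57,
        ),
        CultivarParams(
            name="Koroneiki", oil_max=15.5, oil_midpoint=5.5, oil_rate=0.38,
            band_base=(98, 122, 72), band_rise_amp=(45, 18, 16),
            band_fall_amp=(4, 45, 16), band_fall_onset=11.5,
            n_dates=15, replicates=3, fruit_count_start=195, fruit_count_end=111,
        ),
        CultivarParams(
            name="Leccino", oil_max=15.5, oil_midpoint=5.5, oil_rate=0.38,
            band_base=(90, 120, 72), band_rise_amp=(48, 20, 14),
            band_fall_amp=(78, 88, 13), band_fall_onset=8.5,
            n_dates=15, replicates=3, fruit_count_start=118, fruit_count_end=71,
        ),
        CultivarParams(
            name="Maiatica", oil_max=20.0, oil_midpoint=3.5, oil_rate=0.5,
            band_base=(100, 118, 70), band_rise_amp=(35, 7, 14),
            band_fall_amp=(4, 10, 18), band_fall_onset=7.5,
            n_dates=10, replicates=3, fruit_count_start=82, fruit_count_end=52,
        ),
    ]


_FIELD_NAMES = {f.name for f in fields(CultivarParams)}


def load_config(path) -> list[CultivarParams]:
    """Read a YAML config with one mapping per cultivar.

    Layout: ``{cultivar_name: {field: value, ...}, ...}``; fields mirror
    :class:`CultivarParams`, missing fields take the dataclass defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ConfigError(f"{path}: expected a mapping of cultivar names to parameter blocks")
    out = []
    for name, block in raw.items():
        block = dict(block or {})
        block.pop("name", None)
        unknown = set(block) - _FIELD_NAMES
        if unknown:
            raise ConfigError(f"{name}: unknown parameter(s) {sorted(unknown)}")
        out.append(CultivarParams(name=str(name), **block))
    return out


def check_unique_names(cultivars: Sequence[CultivarParams]) -> None:
    names = [c.name for c in cultivars]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ConfigError(f"duplicate cultivar names: {sorted(dupes)}")
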