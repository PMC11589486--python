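"""Synthetic seasonal datasets: oil accumulation, band trajectories, images.

The simulator emulates the statistical structure of a seasonal olive
sampling campaign: oil concentration (%FW) accumulates along a logistic
curve towards a cultivar-specific asymptote, while the mean Red, Green and
Blue pixel values of the fruit rise early in the season and then decline
from a cultivar-specific onset (a double-logistic).  Because oil keeps
rising while the bands turn around, the oil-vs-band relationship traces an
open hysteresis loop whose extent is governed by ``band_fall_onset`` —
exactly the feature the downstream hysteresis quantification measures.

Rendered image fixtures place elliptical "fruits" on a uniform blue
background and re-center the foreground colors so the exact foreground mean
matches the tabulated band values, giving the segmentation stage a ground
truth to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cultivars import CultivarParams, check_unique_names, default_cultivars
from .errors import CapacityError, ParameterError

__all__ = [
    "SEASON_COLUMNS",
    "ImageFixture",
    "season_expectation",
    "generate_season",
    "render_sample_image",
    "generate_dataset",
    "write_dataset",
]

SEASON_COLUMNS = ["cultivar", "date_index", "replicate", "oil", "red", "green", "blue"]

_OIL_FLOOR = 0.1  # %FW; oil is clipped here so it stays strictly positive
_BACKGROUND_RGB = (30, 60, 200)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def season_expectation(params: CultivarParams) -> pd.DataFrame:
    """Noise-free expected trajectories, one row per date.

    oil(t)   = oil_min + (oil_max - oil_min) * logistic(oil_rate * (t - oil_midpoint))
    band_c(t) = base_c + rise_amp_c * logistic(r_rise * (t - t_rise))
                       - fall_amp_c * logistic(r_fall * (t - band_fall_onset))

    both clipped to their physical ranges.
    """
    t = np.arange(params.n_dates, dtype=float)
    oil = params.oil_min + (params.oil_max - params.oil_min) * _logistic(
        params.oil_rate * (t - params.oil_midpoint)
    )
    oil = np.clip(oil, _OIL_FLOOR, None)
    cols = {"date_index": np.arange(params.n_dates), "oil": oil}
    rise_rates, fall_rates = params.rise_rates(), params.fall_rates()
    for i, band in enumerate(("red", "green", "blue")):
        traj = (
            params.band_base[i]
            + params.band_rise_amp[i] * _logistic(rise_rates[i] * (t - params.rise_midpoint))
            - params.band_fall_amp[i] * _logistic(fall_rates[i] * (t - params.band_fall_onset))
        )
        cols[band] = np.clip(traj, 0.0, 255.0)
    return pd.DataFrame(cols)


def generate_season(params: CultivarParams, seed: int) -> pd.DataFrame:
    """Simulate one cultivar's season: ``n_dates`` x ``replicates`` rows.

    Noise is independent Gaussian per cell (``noise_oil`` on oil,
    ``noise_band`` on each band), truncated by clipping bands to [0, 255]
    and oil to > 0.1 %FW.  Identical ``(params, seed)`` give identical
    tables.
    """
    params.validate()
    if seed is None:
        raise ParameterError("seed: required for reproducibility")
    rng = np.random.default_rng(seed)
    expect = season_expectation(params)
    rows = []
    for _, e in expect.iterrows():
        for rep in range(params.replicates):
            oil = e["oil"] + rng.normal(0.0, params.noise_oil) if params.noise_oil else e["oil"]
            bands = {}
            for i, band in enumerate(("red", "green", "blue")):
                sd = params.noise_band[i]
                v = e[band] + rng.normal(0.0, sd) if sd else e[band]
                bands[band] = float(np.clip(v, 0.0, 255.0))
            rows.append(
                {
                    "cultivar": params.name,
                    "date_index": int(e["date_index"]),
                    "replicate": rep,
                    "oil": float(np.clip(oil, _OIL_FLOOR, None)),
                    **bands,
                }
            )
    table = pd.DataFrame(rows, columns=SEASON_COLUMNS)
    return table.sort_values(["date_index", "replicate"], kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class ImageFixture:
    """A rendered multi-fruit image with its segmentation ground truth."""

    image: np.ndarray       # H x W x 3 uint8
    true_mask: np.ndarray   # H x W bool, True = fruit
    true_mean_rgb: tuple[float, float, float]

    def __post_init__(self):
        if self.image.shape[:2] != self.true_mask.shape:
            raise ParameterError("image and mask shapes differ")


def _place_ellipses(rng, n_fruits, width, height, max_retries=200):
    """Non-overlapping ellipse centers/axes on a jittered grid.

    Grid placement guarantees capacity up to ~grid size; random jitter and
    per-fruit axis variation keep the fixtures irregular.
    """
    margin = 4
    # choose the largest cell that can host n_fruits
    best = None
    for cell in range(48, 11, -2):
        nx, ny = (width - 2 * margin) // cell, (height - 2 * margin) // cell
        if nx * ny >= n_fruits:
            best = (cell, nx, ny)
            break
    if best is None:
        raise CapacityError(
            f"cannot place {n_fruits} fruits on a {width}x{height} canvas without overlap"
        )
    cell, nx, ny = best
    slots = [(ix, iy) for iy in range(ny) for ix in range(nx)]
    rng.shuffle(slots)
    half = cell // 2
    out = []
    for ix, iy in slots[:n_fruits]:
        cx = margin + ix * cell + half
        cy = margin + iy * cell + half
        a = rng.uniform(0.55, 0.92) * (half - 1)
        b = rng.uniform(0.55, 0.92) * (half - 1)
        jx = rng.uniform(-(half - a - 1), half - a - 1) if half - a > 1 else 0.0
        jy = rng.uniform(-(half - b - 1), half - b - 1) if half - b > 1 else 0.0
        theta = rng.uniform(0, np.pi)
        out.append((cx + jx, cy + jy, a, b, theta))
    return out


def render_sample_image(
    target_rgb: Sequence[float],
    n_fruits: int,
    seed: int,
    width: int = 640,
    height: int = 480,
    jitter: float = 8.0,
) -> ImageFixture:
    """Render ``n_fruits`` ellipses on a uniform blue background.

    Per-fruit colors are jittered around ``target_rgb`` and then the whole
    foreground is shifted so that, after quantization to 8-bit, the exact
    foreground mean matches ``target_rgb`` within 0.5 per channel.
    """
    if n_fruits < 1:
        raise ParameterError("n_fruits: must be >= 1")
    target = np.asarray(target_rgb, dtype=float)
    if target.shape != (3,) or np.any(target < 0) or np.any(target > 255):
        raise ParameterError(f"target_rgb: need 3 values in [0,255], got {target_rgb}")
    rng = np.random.default_rng(seed)

    img = np.empty((height, width, 3), dtype=float)
    img[:] = _BACKGROUND_RGB
    mask = np.zeros((height, width), dtype=bool)

    yy, xx = np.mgrid[0:height, 0:width]
    for cx, cy, a, b, theta in _place_ellipses(rng, n_fruits, width, height):
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        color = target + (rng.normal(0.0, jitter, size=3) if jitter else 0.0)
        img[inside] = np.clip(color, 1.0, 254.0)
        mask |= inside

    # re-center the foreground mean onto the target, then absorb the
    # residual quantization bias with one correction pass
    for _ in range(4):
        shift = target - img[mask].mean(axis=0)
        img[mask] = np.clip(img[mask] + shift, 0.0, 255.0)
        quant = np.rint(img).astype(np.uint8)
        err = np.abs(quant[mask].mean(axis=0) - target)
        if np.all(err <= 0.5):
            break
        img = quant.astype(float)
    quant = np.rint(img).astype(np.uint8)
    mean = tuple(float(m) for m in quant[mask].mean(axis=0))
    return ImageFixture(image=quant, true_mask=mask, true_mean_rgb=mean)


def generate_dataset(
    config: Sequence[CultivarParams] | None = None,
    seed: int = 0,
    with_images: bool = False,
    image_size: tuple[int, int] = (640, 480),
) -> tuple[dict[str, pd.DataFrame], dict[str, list[ImageFixture]]]:
    """Simulate every cultivar in ``config`` (default: the 6-cultivar suite).

    Returns ``(tables, fixtures)``; ``fixtures`` is empty unless
    ``with_images``.  With images, one fixture is rendered per
    (date, replicate) row, its fruit count interpolated between the
    cultivar's start/end counts and its exact foreground mean matching the
    table's band values.
    """
    cultivars = list(config) if config is not None else default_cultivars()
    if not cultivars:
        raise ParameterError("config: need at least one cultivar")
    check_unique_names(cultivars)
    seeds = np.random.SeedSequence(seed).spawn(len(cultivars))
    tables: dict[str, pd.DataFrame] = {}
    fixtures: dict[str, list[ImageFixture]] = {}
    for params, ss in zip(cultivars, seeds):
        child = np.random.default_rng(ss)
        table_seed = int(child.integers(0, 2**31 - 1))
        table = generate_season(params, seed=table_seed)
        tables[params.name] = table
        if with_images:
            fx = []
            w, h = image_size
            for _, row in table.iterrows():
                frac = row["date_index"] / max(params.n_dates - 1, 1)
                n_fruits = int(round(
                    params.fruit_count_start
                    + frac * (params.fruit_count_end - params.fruit_count_start)
                ))
                fx.append(
                    render_sample_image(
                        (row["red"], row["green"], row["blue"]),
                        n_fruits=max(n_fruits, 1),
                        seed=int(child.integers(0, 2**31 - 1)),
                        width=w,
                        height=h,
                    )
                )
            fixtures[params.name] = fx
    return tables, fixtures


def write_dataset(tables, fixtures, outdir) -> None:
    """Write ``season_<cultivar>.csv`` plus PNG fixtures and a manifest."""
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"cultivars": {}, "columns": SEASON_COLUMNS}
    for name, table in tables.items():
        csv_path = outdir / f"season_{name}.csv"
        table.to_csv(csv_path, index=False)
        entry = {"table": csv_path.name, "rows": int(len(table)), "images": []}
        for i, fx in enumerate(fixtures.get(name, [])):
            img_name = f"fixture_{name}_{i:03d}.png"
            mask_name = f"mask_{name}_{i:03d}.png"
            Image.fromarray(fx.image, mode="RGB").save(outdir / img_name)
            Image.fromarray(fx.true_mask.astype(np.uint8) * 255, mode="L").save(outdir / mask_name)
            entry["images"].append(
                {"image": img_name, "mask": mask_name, "true_mean_rgb": list(fx.true_mean_rgb)}
            )
        manifest["cultivars"][name] = entry
    with open(outdir / "fixtures.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
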