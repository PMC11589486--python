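"""Fruit/background segmentation and mean-RGB extraction.

Photographs place the fruit on a uniform blue background, so a pixel is
classified as background when its blue channel dominates both red and green
by an additive margin (default 20); small connected foreground specks are
removed.  Foreground means are computed in real arithmetic over all fruit
pixels pooled (the behaviour of measuring one selection in an image editor),
not per fruit then averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import label

from .errors import ParameterError, SegmentationError

__all__ = ["ColorSample", "segment_background", "mean_rgb", "process_image_batch"]


@dataclass(frozen=True)
class ColorSample:
    """Per-image mean channel values over the fruit foreground."""

    red: float
    green: float
    blue: float
    n_foreground: int
    source_id: str = ""


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.shape[0] < 1 or image.shape[1] < 1:
        raise ParameterError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    return image


def segment_background(
    image: np.ndarray, margin: float = 20.0, min_object_px: int = 50
) -> np.ndarray:
    """Boolean foreground mask: True where the pixel is fruit.

    Background rule: ``B > R + margin`` and ``B > G + margin`` (blue
    dominance).  Foreground connected components (8-connectivity) smaller
    than ``min_object_px`` are discarded as specks.

    Raises :class:`SegmentationError` if nothing remains.
    """
    image = _check_image(image)
    chan = image.astype(np.int64) if image.dtype.kind in "ui" else image.astype(float)
    r, g, b = chan[..., 0], chan[..., 1], chan[..., 2]
    foreground = ~((b > r + margin) & (b > g + margin))
    if min_object_px > 1 and foreground.any():
        labels = label(foreground, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0  # background label
        keep = counts >= min_object_px
        foreground = keep[labels]
    if not foreground.any():
        raise SegmentationError("no foreground left after background removal and speck filtering")
    return foreground


def mean_rgb(image: np.ndarray, mask: np.ndarray, source_id: str = "") -> ColorSample:
    """Arithmetic mean of each channel over masked pixels (float result)."""
    image = _check_image(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape[:2]:
        raise ParameterError("mask shape does not match image")
    n = int(mask.sum())
    if n < 1:
        raise ParameterError("mask is empty")
    means = image[mask].astype(float).mean(axis=0)
    return ColorSample(
        red=float(means[0]), green=float(means[1]), blue=float(means[2]),
        n_foreground=n, source_id=source_id,
    )


def process_image_batch(
    paths, margin: float = 20.0, min_object_px: int = 50
) -> pd.DataFrame:
    """Extract a :class:`ColorSample` row per image file, in input order.

    Failures (unreadable file, empty segmentation) are recorded in the
    ``error`` column rather than dropped.  Raises
    :class:`SegmentationError` only if every file fails.
    """
    from PIL import Image

    rows = []
    for path in paths:
        path = Path(path)
        entry = {"source_id": path.name, "red": np.nan, "green": np.nan,
                 "blue": np.nan, "n_foreground": 0, "error": ""}
        try:
            with Image.open(path) as im:
                image = np.asarray(im.convert("RGB"))
            mask = segment_background(image, margin=margin, min_object_px=min_object_px)
            sample = mean_rgb(image, mask, source_id=path.name)
            entry.update(
                red=sample.red, green=sample.green, blue=sample.blue,
                n_foreground=sample.n_foreground,
            )
        except Exception as exc:  # per-file failure is data, not a crash
            entry["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(entry)
    table = pd.DataFrame(rows)
    if len(table) and (table["error"] != "").all():
        raise SegmentationError("every image in the batch failed")
    return table
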