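"""Plant-height phenotyping from time-of-flight amplitude images.

The cabinet's ToF camera exports 8-bit grayscale PNGs in which brighter
pixels are farther from the sensor (255 = at the camera's maximum
sensing range, 2000 mm by default, looking down on the canopy).  Height
above the far plane is recovered from the mean intensity of the plant
region:

    height_mm = maxRange × (1 − pixelValue / 255)

A threshold mask separates plant (closer, darker) from background, and a
synthetic scene generator produces images with known ground truth for
testing the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "DepthImage",
    "HeightSeries",
    "height_from_depth",
    "plant_mask",
    "growth_series_stats",
    "synth_depth_scene",
    "read_depth_png",
    "write_depth_png",
    "heights_from_directory",
]


@dataclass(frozen=True)
class DepthImage:
    """8-bit ToF amplitude image plus the camera's range setting."""

    pixels: np.ndarray  # uint8, H x W
    max_range_mm: float = 2000.0

    def __post_init__(self) -> None:
        if self.max_range_mm <= 0:
            raise ValueError("max_range_mm must be positive")
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values outside [0, 255]")
            object.__setattr__(self, "pixels", px.astype(np.uint8))


#: Ordered (week index, height mm) pairs.
HeightSeries = list[tuple[float, float]]


def height_from_depth(image: DepthImage, mask: np.ndarray) -> float:
    """Plant height (mm) from the mean intensity of the masked region."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.pixels.shape:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    mean_px = float(image.pixels[mask].mean())
    return image.max_range_mm * (1.0 - mean_px / 255.0)


def plant_mask(image: DepthImage, threshold: float) -> np.ndarray:
    """Boolean mask of pixels strictly below ``threshold``.

    Plant canopy sits closer to the downward-looking camera than the
    background plane, hence darker.  May be all-false (e.g. bare
    background); :func:`height_from_depth` then raises.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold {threshold} outside [0, 255]")
    return np.asarray(image.pixels < threshold)


def growth_series_stats(series: HeightSeries) -> dict[str, float]:
    """Total growth and average weekly rate from a height series.

    Endpoint-based: total = last − first height, rate = total over the
    week span.  Using only the endpoints makes the rate insensitive to
    mid-series disturbances such as transplanting or pot repositioning.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 points")
    weeks = [w for w, _ in series]
    if any(b <= a for a, b in zip(weeks, weeks[1:])):
        raise ValueError("week indices must be strictly increasing")
    total = series[-1][1] - series[0][1]
    rate = total / (weeks[-1] - weeks[0])
    return {"total_growth_mm": total, "avg_rate_mm_per_week": rate}


def synth_depth_scene(
    true_height_mm: float,
    max_range_mm: float = 2000.0,
    plant_extent: tuple[int, int, int, int] = (40, 80, 50, 110),
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (120, 160),
) -> tuple[DepthImage, np.ndarray]:
    """Synthetic ToF scene with known ground truth.

    Background sits at the far plane (255); plant pixels inside
    ``plant_extent`` (row0, row1, col0, col1) encode ``true_height_mm``,
    with optional per-pixel Gaussian noise in pixel units, clipped to
    [0, 255].  Returns the image and the true plant mask.
    """
    if not 0.0 <= true_height_mm <= max_range_mm:
        raise ValueError("true_height_mm outside [0, max_range_mm]")
    r0, r1, c0, c1 = plant_extent
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError("plant_extent outside image")
    px = np.full(shape, 255, dtype=float)
    value = round(255.0 * (1.0 - true_height_mm / max_range_mm))
    px[r0:r1, c0:c1] = value
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        px[r0:r1, c0:c1] += rng.normal(0.0, noise_sd, size=(r1 - r0, c1 - c0))
    px = np.clip(np.round(px), 0, 255).astype(np.uint8)
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return DepthImage(pixels=px, max_range_mm=max_range_mm), mask


def read_depth_png(path: str | Path, max_range_mm: float = 2000.0) -> DepthImage:
    img = Image.open(path).convert("L")
    return DepthImage(pixels=np.asarray(img, dtype=np.uint8), max_range_mm=max_range_mm)


def write_depth_png(image: DepthImage, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode="L").save(path)


def heights_from_directory(
    directory: str | Path,
    max_range_mm: float = 2000.0,
    threshold: float = 200.0,
) -> HeightSeries:
    """Estimate heights for every PNG in a directory (sorted by name).

    Files are treated as a weekly sequence: the i-th file (0-based) is
    week i + 1.  Images whose threshold mask is empty are skipped.
    """
    series: HeightSeries = []
    paths = sorted(Path(directory).glob("*.png"))
    week = 1
    for p in paths:
        img = read_depth_png(p, max_range_mm)
        mask = plant_mask(img, threshold)
        if mask.any():
            series.append((week, height_from_depth(img, mask)))
        week += 1
    return series
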