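"""Fixation-count grids and Gaussian-smoothed saliency maps.

A subject's gaze samples on an image are first binned into a per-pixel
fixation-count grid (every tracker sample counts once; there is no duration
weighting).  The grid is then convolved with a truncated 2-D Gaussian and
divided by its maximum, giving a heat map in [0, 1] whose peak marks the
most-fixated region.  A personalized saliency map (PSM) is built from one
subject's counts; a universal saliency map (USM) from the cellwise sum of
many subjects' counts.

The default smoothing follows the SALICON convention for full-resolution
(1920x1080) capture: a 168-pixel kernel with sigma = 24 px.  Even kernel
sizes have no centre pixel and would shift the map by half a pixel, so an
even requested size is rounded up to the next odd size (168 -> 169).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import convolve1d
from skimage.transform import resize as _sk_resize

from .gaze_io import MergedSample

__all__ = [
    "CountGrid",
    "SaliencyMap",
    "DEFAULT_KERNEL_SIZE",
    "DEFAULT_SIGMA",
    "count_fixations",
    "smooth_to_map",
    "aggregate_usm",
    "resize_map",
    "estimate_sigma_moment",
    "save_map_png",
    "load_map_png",
    "save_grid_csv",
    "load_grid_csv",
]

DEFAULT_KERNEL_SIZE = 168  # raw size; odd-adjusted to 169 at use
DEFAULT_SIGMA = 24.0


@dataclass
class CountGrid:
    """Per-cell fixation counts plus bookkeeping of dropped samples."""

    counts: np.ndarray  # (height, width) non-negative ints
    n_dropped_missing: int = 0
    n_dropped_oob: int = 0

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def height(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


@dataclass
class SaliencyMap:
    """Max-normalized gaze heat map over image pixels, values in [0, 1]."""

    values: np.ndarray  # (height, width) floats in [0, 1]
    kind: Literal["PSM", "USM", "predicted"] = "PSM"

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def height(self) -> int:
        return self.values.shape[0]


def count_fixations(
    samples: Iterable[MergedSample], width: int, height: int
) -> CountGrid:
    """Bin merged gaze samples into a fixation-count grid.

    Each in-bounds sample increments exactly one cell (coordinates are
    floored to the containing pixel).  Missing and out-of-bounds samples
    are dropped and counted separately.
    """
    if width <= 0 or height <= 0:
        raise ValueError("grid dimensions must be positive")
    counts = np.zeros((height, width), dtype=np.int64)
    n_missing = 0
    n_oob = 0
    xs, ys = [], []
    for s in samples:
        if s.xy is None:
            n_missing += 1
            continue
        x, y = int(np.floor(s.xy[0])), int(np.floor(s.xy[1]))
        if 0 <= x < width and 0 <= y < height:
            xs.append(x)
            ys.append(y)
        else:
            n_oob += 1
    if xs:
        np.add.at(counts, (np.asarray(ys), np.asarray(xs)), 1)
    return CountGrid(counts=counts, n_dropped_missing=n_missing, n_dropped_oob=n_oob)


def _odd_size(kernel_size: int) -> int:
    if kernel_size < 1:
        raise ValueError("kernel_size must be >= 1")
    return kernel_size if kernel_size % 2 == 1 else kernel_size + 1


def gaussian_kernel_1d(kernel_size: int, sigma: float) -> np.ndarray:
    """Truncated 1-D Gaussian on an odd, centered support (unnormalized)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    size = _odd_size(kernel_size)
    r = size // 2
    x = np.arange(-r, r + 1, dtype=float)
    return np.exp(-0.5 * (x / sigma) ** 2)


def smooth_to_map(
    grid: CountGrid,
    kernel_size: int = DEFAULT_KERNEL_SIZE,
    sigma: float = DEFAULT_SIGMA,
    kind: Literal["PSM", "USM", "predicted"] = "PSM",
    normalization: Literal["max", "sum"] = "max",
) -> SaliencyMap:
    """Convolve counts with a truncated 2-D Gaussian and normalize.

    The 2-D kernel is the outer product of two identical 1-D Gaussians, so
    the convolution is applied separably.  Boundary handling is constant
    zero (gaze cannot land off-screen).  ``normalization='max'`` divides by
    the peak so the maximum is 1 (an all-zero grid stays all-zero);
    ``'sum'`` yields a probability-style map summing to 1.
    """
    k = gaussian_kernel_1d(kernel_size, sigma)
    smoothed = convolve1d(grid.counts.astype(float), k, axis=0, mode="constant")
    smoothed = convolve1d(smoothed, k, axis=1, mode="constant")
    return SaliencyMap(values=_normalize(smoothed, normalization), kind=kind)


def _normalize(values: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "max":
        peak = values.max() if values.size else 0.0
        return values / peak if peak > 0 else np.zeros_like(values)
    if normalization == "sum":
        total = values.sum()
        return values / total if total > 0 else np.zeros_like(values)
    raise ValueError(f"unknown normalization {normalization!r}")


def aggregate_usm(
    grids: Sequence[CountGrid],
    kernel_size: int = DEFAULT_KERNEL_SIZE,
    sigma: float = DEFAULT_SIGMA,
) -> SaliencyMap:
    """Sum per-subject count grids cellwise, then smooth and normalize."""
    if not grids:
        raise ValueError("aggregate_usm requires at least one grid")
    shape = grids[0].counts.shape
    for g in grids[1:]:
        if g.counts.shape != shape:
            raise ValueError(
                f"grid shape mismatch: {g.counts.shape} vs {shape}"
            )
    total = CountGrid(counts=np.sum([g.counts for g in grids], axis=0))
    return smooth_to_map(total, kernel_size, sigma, kind="USM")


def resize_map(smap: SaliencyMap, factor: float) -> SaliencyMap:
    """Bilinearly resample a map by ``factor`` and re-normalize to max 1."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if factor == 1:
        return SaliencyMap(values=smap.values.copy(), kind=smap.kind)
    out_shape = (
        max(1, int(round(smap.height * factor))),
        max(1, int(round(smap.width * factor))),
    )
    out = _sk_resize(
        smap.values, out_shape, order=1, anti_aliasing=False, preserve_range=True
    )
    return SaliencyMap(values=_normalize(out, "max"), kind=smap.kind)


def estimate_sigma_moment(smap: SaliencyMap, axis: int = 1) -> float:
    """Estimate the Gaussian width of a map from its second central moment.

    Treats the map as an unnormalized density, marginalizes onto ``axis``
    (1 = x) and returns the SD of the marginal.  For a map produced by
    smoothing a single impulse this recovers the smoothing sigma up to
    kernel truncation.
    """
    v = smap.values
    if v.sum() <= 0:
        raise ValueError("cannot estimate sigma of an all-zero map")
    marg = v.sum(axis=0) if axis == 1 else v.sum(axis=1)
    p = marg / marg.sum()
    x = np.arange(p.size)
    mu = float((p * x).sum())
    return float(np.sqrt((p * (x - mu) ** 2).sum()))


def save_map_png(smap: SaliencyMap, path: str | Path) -> None:
    """Save as 16-bit grayscale PNG (pixel = round(65535 * value))."""
    arr = np.round(np.clip(smap.values, 0, 1) * 65535).astype(np.uint16)
    Image.fromarray(arr).save(path)


def load_map_png(path: str | Path, kind: str = "PSM") -> SaliencyMap:
    arr = np.asarray(Image.open(path), dtype=float) / 65535.0
    return SaliencyMap(values=arr, kind=kind)  # type: ignore[arg-type]


def save_grid_csv(grid: CountGrid, path: str | Path) -> None:
    """Save nonzero cells as sparse ``x,y,count`` CSV."""
    ys, xs = np.nonzero(grid.counts)
    with open(path, "w") as fh:
        fh.write("x,y,count\n")
        for x, y in zip(xs, ys):
            fh.write(f"{x},{y},{grid.counts[y, x]}\n")


def load_grid_csv(path: str | Path, width: int, height: int) -> CountGrid:
    counts = np.zeros((height, width), dtype=np.int64)
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "x,y,count":
            raise ValueError(f"{path}: expected 'x,y,count' header")
        for line in fh:
            x, y, c = line.strip().split(",")
            counts[int(y), int(x)] = int(c)
    return CountGrid(counts=counts)
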