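"""Photon-image accumulation and diagnostics.

Localisations are accumulated into count histograms at native or sub-divided
pixel resolution (1/5-pixel centroiding divides each pixel into 5x5
subpixels). Folding all fractional positions into one pixel gives the
subpixel-occupancy array; the fixed-pattern-noise metric

    FPN = (Nmax - Nmin) / Nmean * 100  [%]

is computed on the folded 5x5 array and quantifies the periodic artefact
caused by any mismatch between event shape and centroiding function. A
13x13 folding of the same positions is used for display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .camera import FrameStack
from .errors import DegenerateInputError
from .localise import Localisation

__all__ = [
    "PhotonImage",
    "SubpixelOccupancy",
    "accumulate_image",
    "sum_stack",
    "subpixel_occupancy",
    "compute_fpn",
    "line_profile",
    "downsample",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhotonImage:
    """Count histogram of localisations at ``subdivision x`` native resolution."""

    counts: np.ndarray  # (height * s, width * s) int64
    subdivision: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SubpixelOccupancy:
    """n x n counts of fractional positions folded over all pixels.

    ``grid[fy_bin, fx_bin]`` — n = 5 for the FPN metric, n = 13 for
    distribution plots.
    """

    grid: np.ndarray

    @property
    def n(self) -> int:
        return self.grid.shape[0]

    @property
    def total(self) -> int:
        return int(self.grid.sum())


def accumulate_image(
    locs: Sequence[Localisation],
    shape: tuple[int, int],
    subdivision: int = 1,
) -> PhotonImage:
    """Histogram localisations into bins of 1/subdivision pixel.

    Each localisation increments bin ``(floor(x*s), floor(y*s))``;
    ``subdivision=1`` is plain one-pixel-accuracy centroiding. Localisations
    outside ``shape`` (height, width) are dropped and counted in the log.
    """
    if subdivision < 1:
        raise ValueError(f"subdivision must be >= 1, got {subdivision}")
    h, w = shape
    s = subdivision
    counts = np.zeros((h * s, w * s), dtype=np.int64)
    dropped = 0
    if locs:
        xs = np.array([l.x_px for l in locs])
        ys = np.array([l.y_px for l in locs])
        ix = np.floor(xs * s).astype(np.int64)
        iy = np.floor(ys * s).astype(np.int64)
        ok = (ix >= 0) & (ix < w * s) & (iy >= 0) & (iy < h * s)
        dropped = int((~ok).sum())
        np.add.at(counts, (iy[ok], ix[ok]), 1)
    if dropped:
        log.info("accumulate_image dropped %d out-of-bounds localisations", dropped)
    return PhotonImage(counts=counts, subdivision=s)


def downsample(image: PhotonImage) -> PhotonImage:
    """Sum each subdivision x subdivision block back to native pixels."""
    s = image.subdivision
    h, w = image.counts.shape[0] // s, image.counts.shape[1] // s
    counts = image.counts.reshape(h, s, w, s).sum(axis=(1, 3))
    return PhotonImage(counts=counts, subdivision=1)


def sum_stack(stack: FrameStack | np.ndarray) -> np.ndarray:
    """Pixel-wise sum over frames (the no-processing comparison image)."""
    arr = stack.as_array() if isinstance(stack, FrameStack) else np.asarray(stack)
    if arr.ndim == 2:
        return arr.astype(np.float64)
    return arr.astype(np.float64).sum(axis=0)


def subpixel_occupancy(locs: Sequence[Localisation], n: int = 5) -> SubpixelOccupancy:
    """Fold fractional positions of all localisations into an n x n grid.

    For each localisation, ``f = x - floor(x)`` (and likewise y) indexes cell
    ``(floor(fx*n), floor(fy*n))``. Fractions live in [0, 1) by construction,
    so the boundary bin n never occurs.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    grid = np.zeros((n, n), dtype=np.int64)
    if locs:
        xs = np.array([l.x_px for l in locs])
        ys = np.array([l.y_px for l in locs])
        fx = xs - np.floor(xs)
        fy = ys - np.floor(ys)
        ix = np.minimum(np.floor(fx * n).astype(np.int64), n - 1)
        iy = np.minimum(np.floor(fy * n).astype(np.int64), n - 1)
        np.add.at(grid, (iy, ix), 1)
    return SubpixelOccupancy(grid=grid)


def compute_fpn(occ: SubpixelOccupancy) -> float:
    """Fixed pattern noise in percent: (Nmax - Nmin) / Nmean * 100.

    Nmax, Nmin and Nmean are taken over the cells of the folded subpixel
    array (5x5 for the standard metric). Undefined for an empty occupancy.
    """
    if occ.total <= 0:
        raise DegenerateInputError("FPN undefined for an empty occupancy grid")
    g = occ.grid.astype(np.float64)
    return float((g.max() - g.min()) / g.mean() * 100.0)


def line_profile(
    image: np.ndarray | PhotonImage, rect: tuple[int, int, int, int]
) -> np.ndarray:
    """Mean profile along the long axis of a rectangle.

    ``rect = (x, y, width, height)`` in image pixel indices. The profile has
    one value per position along the longer rectangle axis, each the mean
    across the shorter axis.
    """
    arr = image.counts if isinstance(image, PhotonImage) else np.asarray(image)
    x, y, w, h = rect
    if w < 1 or h < 1:
        raise ValueError("rect must have positive extent")
    if x < 0 or y < 0 or x + w > arr.shape[1] or y + h > arr.shape[0]:
        raise ValueError(f"rect {rect} outside image of shape {arr.shape}")
    sub = arr[y : y + h, x : x + w].astype(np.float64)
    if w >= h:
        return sub.mean(axis=0)
    return sub.mean(axis=1)
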