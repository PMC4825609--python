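"""Approximate event detection.

A b-spline à-trous wavelet filter isolates event-scale structure; the first
wavelet level F1 is thresholded at a multiple of its per-frame standard
deviation (the peak intensity threshold, PIT); 8-connected components of the
binarised image become candidates at their intensity-weighted centroids, with
a watershed split for components holding several regional maxima.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .camera import Frame
from .errors import DegenerateInputError

__all__ = [
    "Candidate",
    "bspline_kernel",
    "wavelet_filter",
    "detection_threshold",
    "find_candidates",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Candidate:
    """Approximate integer event centre from detection."""

    cx: int  # column (x) pixel index
    cy: int  # row (y) pixel index
    frame: int = 0
    peak_value: float = 0.0


def bspline_kernel(order: int) -> np.ndarray:
    """Normalised 1D b-spline smoothing kernel of the given order.

    Taps are the binomial row of length ``2*order - 1`` (order 3 gives
    [1, 4, 6, 4, 1] / 16), the b-spline sampled at integer nodes.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    n = 2 * (order - 1)
    row = np.array([float(math.comb(n, k)) for k in range(n + 1)])
    return row / row.sum()


def _dilate_kernel(kernel: np.ndarray, scale: int) -> np.ndarray:
    """À-trous dilation: insert ``scale - 1`` zeros between adjacent taps."""
    if scale == 1:
        return kernel
    out = np.zeros((len(kernel) - 1) * scale + 1)
    out[::scale] = kernel
    return out


def wavelet_filter(
    frame: Frame | np.ndarray, order: int = 3, scale: float = 2.0
) -> np.ndarray:
    """First wavelet level F1 = V0 - V1 of the à-trous b-spline transform.

    V0 and V1 are separable convolutions of the input with the b-spline
    kernel and with the same kernel dilated by ``scale`` (zeros inserted
    between taps). Borders are handled by symmetric reflection. The output
    has the frame's dimensions; it is a zero-sum band-pass, so constant
    frames map to zero and the response is linear in the input.
    """
    values = frame.values if isinstance(frame, Frame) else np.asarray(frame)
    values = values.astype(np.float64)
    if scale < 1:
        raise ValueError(f"scale must be >= 1, got {scale}")
    d = int(round(scale))
    k1 = bspline_kernel(order)
    k2 = _dilate_kernel(k1, d)
    if len(k2) > min(values.shape):
        raise DegenerateInputError(
            f"dilated kernel length {len(k2)} exceeds frame dimension {min(values.shape)}"
        )
    # kernels are symmetric, so correlate == convolve; 'reflect' is the
    # symmetric (edge-including) reflection
    v0 = ndimage.correlate1d(values, k1, axis=0, mode="reflect")
    v0 = ndimage.correlate1d(v0, k1, axis=1, mode="reflect")
    v1 = ndimage.correlate1d(values, k2, axis=0, mode="reflect")
    v1 = ndimage.correlate1d(v1, k2, axis=1, mode="reflect")
    return v0 - v1


def detection_threshold(filtered: np.ndarray, multiplier: float = 2.0) -> float:
    """Peak intensity threshold: ``multiplier * std`` of the filtered frame.

    The standard deviation is over all pixels of this frame (per-frame
    thresholding). A zero-variance frame yields threshold 0 with a warning.
    """
    sd = float(np.std(filtered))
    if sd == 0.0:
        warnings.warn("zero-variance filtered frame: detection threshold is 0")
        log.warning("zero-variance filtered frame: threshold set to 0")
    return multiplier * sd


def _round_half_down(c: float) -> int:
    """Round to nearest integer, ties toward the smaller index."""
    return int(np.ceil(c - 0.5))


def find_candidates(
    filtered: np.ndarray,
    threshold: float,
    use_watershed: bool = True,
    frame_index: int = 0,
) -> list[Candidate]:
    """Connected-component candidates from a filtered frame.

    Pixels with ``filtered >= threshold`` are grouped into 8-connected
    components. With ``use_watershed``, components containing more than one
    regional maximum are split by a watershed on the inverted filtered image
    seeded at those maxima. Each region yields one candidate at its
    intensity-weighted centroid (weights are the filtered values), rounded to
    the nearest pixel with ties toward the smaller index.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    filtered = np.asarray(filtered, dtype=np.float64)
    # a threshold of exactly 0 (zero-variance frame) must not select the
    # whole frame; require strictly positive response in that case
    mask = filtered >= threshold if threshold > 0 else filtered > 0
    if not mask.any():
        return []
    structure = np.ones((3, 3), dtype=bool)
    labels, n_comp = ndimage.label(mask, structure=structure)
    # regional maxima (plateau-tolerant): pixels equal to the 3x3 max filter
    if use_watershed:
        maxmask = (filtered == ndimage.maximum_filter(filtered, size=3)) & mask
    candidates: list[Candidate] = []
    slices = ndimage.find_objects(labels)
    for comp_idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        comp_mask = labels[sl] == comp_idx
        sub = filtered[sl]
        regions = [comp_mask]
        if use_watershed:
            mm = maxmask[sl] & comp_mask
            marker_labels, n_max = ndimage.label(mm, structure=structure)
            if n_max > 1:
                ws = watershed(-sub, markers=marker_labels, mask=comp_mask,
                               connectivity=2)
                regions = [ws == k for k in range(1, n_max + 1)]
        oy, ox = sl[0].start, sl[1].start
        for region in regions:
            w = np.where(region, sub, 0.0)
            total = w.sum()
            if total <= 0:
                continue
            ys, xs = np.nonzero(region)
            cx = _round_half_down(float((w[ys, xs] * xs).sum() / total) + ox)
            cy = _round_half_down(float((w[ys, xs] * ys).sum() / total) + oy)
            cy = min(max(cy, 0), filtered.shape[0] - 1)
            cx = min(max(cx, 0), filtered.shape[1] - 1)
            candidates.append(
                Candidate(cx=cx, cy=cy, frame=frame_index,
                          peak_value=float(filtered[cy, cx]))
            )
    return candidates
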