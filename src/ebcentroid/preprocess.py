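"""Ion-event clipping.

Rare ion events are orders of magnitude brighter than photon events. A
per-frame adaptive threshold (a multiple of the filtered-frame standard
deviation) is corrupted by them: the threshold jumps and genuine photon
events are discarded as noise. The remedy is to clip every pixel brighter
than the photon-event maximum to a value slightly above that maximum before
detection. Clipped ion remnants then get localised as (false) photon events,
which is acceptable because ions are rare compared to photons.
"""

from __future__ import annotations

import numpy as np

from .camera import Frame, FrameStack
from .errors import EstimationError

__all__ = ["estimate_photon_event_max", "clip_ion_events", "clip_stack"]

#: Frames whose maximum exceeds this multiple of the median per-frame maximum
#: are treated as ion-contaminated when estimating the photon-event peak.
ION_FRAME_FACTOR = 3.0


def estimate_photon_event_max(stack: FrameStack, quantile: float = 0.999) -> float:
    """Robust upper bound of the photon-event peak grey value (ADU).

    Per-frame maxima are collected; frames whose maximum exceeds
    ``ION_FRAME_FACTOR`` times the median per-frame maximum are excluded as
    ion-contaminated; the given quantile of the remaining maxima is returned.
    """
    if not 0 < quantile <= 1:
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    maxima = np.array([float(np.max(f.values)) for f in stack])
    median = float(np.median(maxima))
    clean = maxima[maxima <= ION_FRAME_FACTOR * median]
    if clean.size == 0:
        raise EstimationError(
            "every frame looks ion-contaminated; cannot estimate photon-event maximum"
        )
    return float(np.quantile(clean, quantile))


def clip_ion_events(
    frame: Frame | np.ndarray, photon_max: float, epsilon: float = 0.05
) -> Frame:
    """Clip pixels brighter than ``photon_max`` to ``photon_max * (1 + epsilon)``.

    "Slightly above" the photon maximum keeps the remnant detectable without
    letting it dominate the per-frame threshold. Pixels at or below
    ``photon_max`` are untouched; the operation is idempotent. Clipping is
    per-pixel, not per-connected-component.
    """
    if photon_max <= 0:
        raise ValueError(f"photon_max must be > 0, got {photon_max}")
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    index = frame.index if isinstance(frame, Frame) else 0
    values = frame.values if isinstance(frame, Frame) else np.asarray(frame)
    clip_value = photon_max * (1.0 + epsilon)
    out = np.where(values > photon_max, clip_value, values.astype(np.float64))
    return Frame(out, index=index)


def clip_stack(
    stack: FrameStack, quantile: float = 0.999, epsilon: float = 0.05
) -> tuple[FrameStack, float]:
    """Clip every frame of a stack; returns the clipped stack and the
    photon-event maximum estimate used."""
    photon_max = estimate_photon_event_max(stack, quantile)
    frames = [clip_ion_events(f, photon_max, epsilon) for f in stack]
    return FrameStack(frames, stack.calibration), photon_max
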