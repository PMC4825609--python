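"""Synthetic EBCCD frame generator with ground truth.

Single photoelectrons accelerated into the CCD produce compact events: a high
central peak with small wings from charge diffusion, widened horizontally by
the CCD read-out, with a narrow pulse-height distribution. Rare ion events
(residual-gas ions striking the photocathode) are far brighter and larger.
The generator renders these on top of a dark offset plus Gaussian read noise,
and returns the true event positions so every pipeline stage can be scored.

Event model
-----------
The vertical profile is a pixel-integrated Gaussian (sigma_y). The horizontal
profile is a pixel-integrated exponentially-modified Gaussian: a Gaussian of
width sigma_x convolved with a one-sided exponential of decay ``tail_x``
pixels toward +x, standing in for the read-out charge smear. ``tail_x = 0``
gives a plain elliptical Gaussian. The ground-truth position of an event is
the Gaussian (arrival) centre, not the smeared centroid.

Coordinates: pixel (i, j) spans [i, i+1) x [j, j+1); its centre is i + 0.5.
Arrays are indexed [y, x].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .camera import CameraCalibration, FrameStack
from .errors import DegenerateInputError

__all__ = [
    "EventShapeModel",
    "IonEventModel",
    "GroundTruthEvent",
    "SceneMap",
    "make_bar_target_scene",
    "sample_events",
    "render_photon_event",
    "simulate_stack",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass(frozen=True)
class EventShapeModel:
    """Photon-event shape and pulse-height parameters.

    Defaults emulate EBCCD events: ~1 px wide, horizontally widened
    (sigma_x > sigma_y plus a read-out smear tail toward +x), integral around
    15000 photoelectrons with a narrow (CV 0.1) pulse-height distribution.
    """

    sigma_x: float = 0.95
    sigma_y: float = 0.85
    tail_x: float = 0.8
    amplitude_mean: float = 15000.0
    amplitude_cv: float = 0.1

    def __post_init__(self) -> None:
        if not (self.sigma_x > 0 and self.sigma_y > 0):
            raise DegenerateInputError("sigma_x and sigma_y must be > 0")
        if self.tail_x < 0:
            raise DegenerateInputError("tail_x must be >= 0")
        if self.amplitude_mean <= 0 or self.amplitude_cv < 0:
            raise DegenerateInputError("amplitude_mean > 0 and amplitude_cv >= 0 required")

    @property
    def asymmetry(self) -> float:
        """Ratio of horizontal to vertical marginal SD (> 1: widened in x)."""
        return math.sqrt(self.sigma_x**2 + self.tail_x**2) / self.sigma_y

    def scaled(self, amplitude_factor: float, size_factor: float) -> "EventShapeModel":
        return EventShapeModel(
            sigma_x=self.sigma_x * size_factor,
            sigma_y=self.sigma_y * size_factor,
            tail_x=self.tail_x * size_factor,
            amplitude_mean=self.amplitude_mean * amplitude_factor,
            amplitude_cv=self.amplitude_cv,
        )

    def sample_amplitude(self, rng: np.random.Generator, size: int | None = None):
        """Draw event integrals from a normal truncated at zero (narrow PHD)."""
        if self.amplitude_cv == 0:
            return (
                self.amplitude_mean
                if size is None
                else np.full(size, self.amplitude_mean)
            )
        sd = self.amplitude_mean * self.amplitude_cv
        a = -self.amplitude_mean / sd  # truncate at 0
        return stats.truncnorm.rvs(
            a, np.inf, loc=self.amplitude_mean, scale=sd, size=size, random_state=rng
        )


@dataclass(frozen=True)
class IonEventModel:
    """Rare bright ion events, expressed relative to the photon-event model."""

    rate_per_frame: float = 1.0 / 3.0
    amplitude_factor: float = 300.0
    size_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.rate_per_frame < 0:
            raise DegenerateInputError("rate_per_frame must be >= 0")
        if self.amplitude_factor <= 1:
            raise DegenerateInputError("amplitude_factor must be > 1")
        if self.size_factor < 1:
            raise DegenerateInputError("size_factor must be >= 1")


@dataclass(frozen=True)
class GroundTruthEvent:
    """True event emitted by the simulator (test oracle)."""

    x: float  # px, pixel-span coordinates
    y: float
    amplitude: float  # integrated photoelectrons
    kind: Literal["photon", "ion"]
    frame: int


@dataclass(frozen=True)
class SceneMap:
    """Relative photon arrival probability per pixel (non-negative weights)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2:
            raise DegenerateInputError("scene weights must be 2D")
        if np.any(w < 0):
            raise DegenerateInputError("scene weights must be non-negative")
        if w.sum() <= 0:
            raise DegenerateInputError("scene weights must have positive sum")
        object.__setattr__(self, "weights", w)

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape


def make_bar_target_scene(
    width: int,
    height: int,
    bar_period: float | None,
    orientation: Literal["horizontal", "vertical"] = "vertical",
) -> SceneMap:
    """Binary bar pattern (resolution-target stand-in).

    Vertical orientation means vertical bars, i.e. the pattern varies along x.
    The first half-period is bright. ``bar_period`` of ``None`` or ``inf``
    yields a uniform (all-ones) scene.
    """
    if width < 1 or height < 1:
        raise DegenerateInputError("scene dimensions must be positive")
    if bar_period is None or math.isinf(bar_period):
        return SceneMap(np.ones((height, width)))
    if bar_period < 2:
        raise DegenerateInputError(f"bar_period must be >= 2, got {bar_period}")
    extent = width if orientation == "vertical" else height
    if bar_period > extent:
        raise DegenerateInputError(
            f"bar_period {bar_period} exceeds scene extent {extent}"
        )
    coord = np.arange(extent)
    bright = (coord % bar_period) < bar_period / 2.0
    if orientation == "vertical":
        weights = np.tile(bright.astype(np.float64), (height, 1))
    else:
        weights = np.tile(bright.astype(np.float64)[:, None], (1, width))
    return SceneMap(weights)


def sample_events(
    scene: SceneMap,
    mean_events_per_frame: float,
    n_frames: int,
    seed: int | np.random.Generator | None = None,
    shape: EventShapeModel | None = None,
) -> list[GroundTruthEvent]:
    """Sample photon arrival positions over a stack.

    Per-frame counts are Poisson(mean); positions are drawn proportional to
    the scene weights, continuous (uniform) within each chosen pixel.
    Amplitudes come from ``shape`` when given, else 1.0.
    """
    if mean_events_per_frame < 0:
        raise DegenerateInputError("mean_events_per_frame must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = scene.shape
    probs = (scene.weights / scene.weights.sum()).ravel()
    events: list[GroundTruthEvent] = []
    for f in range(n_frames):
        n = int(rng.poisson(mean_events_per_frame))
        if n == 0:
            continue
        flat = rng.choice(probs.size, size=n, p=probs)
        iy, ix = np.unravel_index(flat, (h, w))
        xs = ix + rng.uniform(size=n)
        ys = iy + rng.uniform(size=n)
        amps = (
            shape.sample_amplitude(rng, n) if shape is not None else np.ones(n)
        )
        events.extend(
            GroundTruthEvent(float(x), float(y), float(a), "photon", f)
            for x, y, a in zip(xs, ys, amps)
        )
    return events


def _profile_x(shape: EventShapeModel, x0: float, j: np.ndarray) -> np.ndarray:
    """Per-column integral of the horizontal profile over pixel spans [j, j+1)."""
    if shape.tail_x > 0:
        k = shape.tail_x / shape.sigma_x
        cdf = stats.exponnorm.cdf
        return cdf(j + 1, k, loc=x0, scale=shape.sigma_x) - cdf(
            j, k, loc=x0, scale=shape.sigma_x
        )
    return stats.norm.cdf(j + 1, loc=x0, scale=shape.sigma_x) - stats.norm.cdf(
        j, loc=x0, scale=shape.sigma_x
    )


def render_photon_event(
    event: GroundTruthEvent, shape: EventShapeModel
) -> tuple[np.ndarray, tuple[int, int]]:
    """Render one event as a photoelectron patch.

    Pixel values are the event profile integrated over pixel areas
    (difference-of-CDF form per axis) times the amplitude. The patch is
    truncated where the enclosed mass exceeds 99.9%; returns
    ``(patch, (ox, oy))`` with the top-left pixel indices of the patch.
    """
    if event.amplitude <= 0:
        raise DegenerateInputError("event amplitude must be > 0")
    # 4 sigma keeps > 99.99% per Gaussian side; the exponential tail needs
    # ~7 decay lengths for 1e-3 of its mass.
    rx_lo = 4.0 * shape.sigma_x
    rx_hi = 4.0 * shape.sigma_x + 7.0 * shape.tail_x
    ry = 4.0 * shape.sigma_y
    ox = math.floor(event.x - rx_lo)
    oy = math.floor(event.y - ry)
    x1 = math.ceil(event.x + rx_hi)
    y1 = math.ceil(event.y + ry)
    jx = np.arange(ox, x1)
    jy = np.arange(oy, y1)
    gx = _profile_x(shape, event.x, jx)
    gy = stats.norm.cdf(jy + 1, loc=event.y, scale=shape.sigma_y) - stats.norm.cdf(
        jy, loc=event.y, scale=shape.sigma_y
    )
    return event.amplitude * np.outer(gy, gx), (ox, oy)


def _add_patch(image: np.ndarray, patch: np.ndarray, origin: tuple[int, int]) -> None:
    """Accumulate a patch into an image, clipping at the borders."""
    ox, oy = origin
    h, w = image.shape
    ph, pw = patch.shape
    y0, y1 = max(oy, 0), min(oy + ph, h)
    x0, x1 = max(ox, 0), min(ox + pw, w)
    if y0 >= y1 or x0 >= x1:
        return
    image[y0:y1, x0:x1] += patch[y0 - oy : y1 - oy, x0 - ox : x1 - ox]


def simulate_stack(
    scene: SceneMap,
    shape: EventShapeModel | None = None,
    ion_model: IonEventModel | None = None,
    calib: CameraCalibration | None = None,
    mean_events: float = 150.0,
    n_frames: int = 100,
    noise_sd_adu: float = 0.25,
    seed: int | np.random.Generator | None = None,
) -> tuple[FrameStack, list[GroundTruthEvent]]:
    """Simulate an EBCCD stack and return it with its ground truth.

    Each frame is ``base level + Gaussian read noise + Poisson(pe image)/gain``
    rounded to integer ADU (clipped to [0, 65535]). The pe image is the sum of
    rendered photon events plus ion events (photon shape scaled by the ion
    model); ion positions are uniform over the sensor (residual-gas ions do
    not follow the scene). Pass ``ion_model=None`` for an ion-free stack.
    Bitwise reproducible for a fixed integer seed.
    """
    shape = shape or EventShapeModel()
    calib = calib or CameraCalibration(base_level_adu=120.0)
    if calib.base_level_adu is None:
        raise DegenerateInputError("simulate_stack needs calib.base_level_adu set")
    if noise_sd_adu < 0:
        raise DegenerateInputError("noise_sd_adu must be >= 0")
    # independent sub-streams so that an ion-free twin built with the same
    # seed shares the photon ground truth and the camera noise exactly: the
    # photon stream, the ion stream and one camera stream per frame
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2**31))
    ss = np.random.SeedSequence(seed)
    photon_ss, ion_ss, camera_ss = ss.spawn(3)
    rng_photon = np.random.default_rng(photon_ss)
    rng_ion = np.random.default_rng(ion_ss)
    frame_rngs = [np.random.default_rng(s) for s in camera_ss.spawn(n_frames)]
    h, w = scene.shape
    gain = calib.photoelectrons_per_adu
    base = calib.base_level_adu

    truth: list[GroundTruthEvent] = []
    frames = np.empty((n_frames, h, w), dtype=np.uint16)
    ion_shape = (
        shape.scaled(ion_model.amplitude_factor, ion_model.size_factor)
        if ion_model is not None
        else None
    )
    probs = (scene.weights / scene.weights.sum()).ravel()
    for f in range(n_frames):
        pe = np.zeros((h, w), dtype=np.float64)
        n_ph = int(rng_photon.poisson(mean_events))
        if n_ph:
            flat = rng_photon.choice(probs.size, size=n_ph, p=probs)
            iy, ix = np.unravel_index(flat, (h, w))
            xs = ix + rng_photon.uniform(size=n_ph)
            ys = iy + rng_photon.uniform(size=n_ph)
            amps = np.atleast_1d(shape.sample_amplitude(rng_photon, n_ph))
            for x, y, a in zip(xs, ys, amps):
                ev = GroundTruthEvent(float(x), float(y), float(a), "photon", f)
                truth.append(ev)
                patch, origin = render_photon_event(ev, shape)
                _add_patch(pe, patch, origin)
        if ion_model is not None and ion_model.rate_per_frame > 0:
            n_ion = int(rng_ion.poisson(ion_model.rate_per_frame))
            for _ in range(n_ion):
                x = float(rng_ion.uniform(0, w))
                y = float(rng_ion.uniform(0, h))
                a = float(
                    np.atleast_1d(shape.sample_amplitude(rng_ion, 1))[0]
                    * ion_model.amplitude_factor
                )
                ev = GroundTruthEvent(x, y, a, "ion", f)
                truth.append(ev)
                patch, origin = render_photon_event(ev, ion_shape)
                _add_patch(pe, patch, origin)
        rng_f = frame_rngs[f]
        # read noise drawn before the shot-noise sampling keeps ion-free
        # twin frames without ions bitwise identical
        noise = (
            rng_f.normal(0.0, noise_sd_adu, size=(h, w)) if noise_sd_adu > 0 else 0.0
        )
        counts = rng_f.poisson(pe).astype(np.float64)
        adu = base + counts / gain + noise
        frames[f] = np.clip(np.rint(adu), 0, 65535).astype(np.uint16)
    return FrameStack.from_array(frames, calib), truth


# ---------------------------------------------------------------------------
# Ground-truth I/O

def write_ground_truth(path: str | Path, events: Sequence[GroundTruthEvent]) -> None:
    pd.DataFrame(
        {
            "frame": [e.frame for e in events],
            "x_px": [e.x for e in events],
            "y_px": [e.y for e in events],
            "amplitude_pe": [e.amplitude for e in events],
            "kind": [e.kind for e in events],
        }
    ).to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> list[GroundTruthEvent]:
    df = pd.read_csv(path)
    return [
        GroundTruthEvent(
            float(r.x_px), float(r.y_px), float(r.amplitude_pe), str(r.kind), int(r.frame)
        )
        for r in df.itertuples()
    ]
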