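"""Shared fixtures: calibrations, event shapes and noisy-patch factories.

All synthetic inputs are generated at test time from seeded generators; no
fixture files are stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from ebcentroid import CameraCalibration, EventShapeModel, GroundTruthEvent
from ebcentroid.simulate import _add_patch, render_photon_event


@pytest.fixture
def calib() -> CameraCalibration:
    """Paper-style calibration: 80 nm/px, 36 pe/ADU, base 120 ADU."""
    return CameraCalibration(80.0, 36.0, 120.0)


@pytest.fixture
def symmetric_shape() -> EventShapeModel:
    """Round, tail-free event shape for bias-sensitive checks."""
    return EventShapeModel(sigma_x=0.95, sigma_y=0.95, tail_x=0.0)


@pytest.fixture
def ebccd_shape() -> EventShapeModel:
    """Default EBCCD-like shape: horizontally widened with read-out smear."""
    return EventShapeModel()


# Electron-bombarded gain crushes CCD read noise far below one photoelectron;
# the residual per-pixel Gaussian term that survives in photoelectron units is
# the A/D quantisation of the 36 pe/ADU digitiser (SD = 36/sqrt(12) ~ 10.4 pe).
QUANTISATION_NOISE_PE = 36.0 / np.sqrt(12.0)


def make_event_patch(
    rng: np.random.Generator,
    shape: EventShapeModel,
    x: float,
    y: float,
    amplitude: float = 15000.0,
    size: int = 15,
    noise: bool = True,
    read_noise_pe: float = QUANTISATION_NOISE_PE,
) -> np.ndarray:
    """Render one event into a size x size photoelectron patch.

    With ``noise`` the patch carries Poisson counting noise plus a Gaussian
    term of SD ``read_noise_pe`` (default: the A/D quantisation equivalent),
    clamped at zero as the camera model does. Pass ``read_noise_pe=0`` for
    the photoelectron-resolved (pure Poisson) regime, e.g. for
    likelihood-ratio calibration checks.
    """
    pe = np.zeros((size, size))
    ev = GroundTruthEvent(x, y, amplitude, "photon", 0)
    patch, origin = render_photon_event(ev, shape)
    _add_patch(pe, patch, origin)
    if noise:
        pe = rng.poisson(pe).astype(float)
        if read_noise_pe > 0:
            pe = pe + rng.normal(0.0, read_noise_pe, pe.shape)
    return np.maximum(pe, 0.0)


def make_pair_patch(
    rng: np.random.Generator,
    shape: EventShapeModel,
    centre: float,
    separation: float,
    angle: float,
    amplitude: float = 15000.0,
    size: int = 15,
    noise: bool = True,
    read_noise_pe: float = QUANTISATION_NOISE_PE,
) -> tuple[np.ndarray, tuple[tuple[float, float], tuple[float, float]]]:
    """Two equal events ``separation`` px apart, rotated by ``angle``."""
    dx = 0.5 * separation * np.cos(angle)
    dy = 0.5 * separation * np.sin(angle)
    pts = ((centre - dx, centre - dy), (centre + dx, centre + dy))
    pe = np.zeros((size, size))
    for (x, y) in pts:
        patch, origin = render_photon_event(
            GroundTruthEvent(x, y, amplitude, "photon", 0), shape
        )
        _add_patch(pe, patch, origin)
    if noise:
        pe = rng.poisson(pe).astype(float)
        if read_noise_pe > 0:
            pe = pe + rng.normal(0.0, read_noise_pe, pe.shape)
    return np.maximum(pe, 0.0), pts
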