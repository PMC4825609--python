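"""Frames, camera calibration and grey-value → photoelectron conversion.

An electron-bombarded CCD digitises each pixel to A/D counts (ADU). The
calibration maps ADU back to photoelectrons: subtract the dark offset (base
level) and multiply by the gain in photoelectrons per ADU. The base level
drifts with sensor temperature, so it can be estimated per stack (or per
chunk) as the average of the per-frame minimum grey values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import tifffile
import yaml

from .errors import CalibrationError, EmptyStackError


@dataclass(frozen=True)
class CameraCalibration:
    """Static camera parameters.

    Parameters
    ----------
    pixel_size_nm:
        Length of one sensor pixel in the image plane, nanometres.
    photoelectrons_per_adu:
        Gain conversion, photoelectrons per A/D count.
    base_level_adu:
        Dark offset in ADU. ``None`` means "estimate from the stack".
    """

    pixel_size_nm: float = 80.0
    photoelectrons_per_adu: float = 36.0
    base_level_adu: float | None = None

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0:
            raise CalibrationError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        if not self.photoelectrons_per_adu > 0:
            raise CalibrationError(
                f"photoelectrons_per_adu must be > 0, got {self.photoelectrons_per_adu}"
            )
        if self.base_level_adu is not None and self.base_level_adu < 0:
            raise CalibrationError(f"base_level_adu must be >= 0, got {self.base_level_adu}")

    def with_base_level(self, base_level_adu: float) -> "CameraCalibration":
        return CameraCalibration(
            self.pixel_size_nm, self.photoelectrons_per_adu, float(base_level_adu)
        )


@dataclass(frozen=True)
class Frame:
    """A single 2D frame of grey values (ADU) with its position in the stack."""

    values: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"frame must be 2D, got shape {v.shape}")
        if np.any(v < 0):
            raise ValueError("grey values must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # (height, width)


@dataclass
class FrameStack:
    """Ordered, homogeneous sequence of frames plus calibration context."""

    frames: list[Frame]
    calibration: CameraCalibration = field(default_factory=CameraCalibration)

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyStackError("FrameStack must contain at least one frame")
        shape = self.frames[0].shape
        for f in self.frames:
            if f.shape != shape:
                raise ValueError("all frames in a stack must share dimensions")

    @classmethod
    def from_array(
        cls, values: np.ndarray, calibration: CameraCalibration | None = None
    ) -> "FrameStack":
        """Build a stack from a (n_frames, height, width) array."""
        values = np.asarray(values)
        if values.ndim == 2:
            values = values[None]
        if values.ndim != 3:
            raise ValueError(f"expected 2D or 3D array, got shape {values.shape}")
        frames = [Frame(values[i], index=i) for i in range(values.shape[0])]
        return cls(frames, calibration or CameraCalibration())

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def as_array(self) -> np.ndarray:
        return np.stack([f.values for f in self.frames])

    def chunks(self, chunk_size: int | None) -> Iterator["FrameStack"]:
        """Split into consecutive sub-stacks of at most ``chunk_size`` frames."""
        if chunk_size is None or chunk_size >= len(self):
            yield self
            return
        if chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        for start in range(0, len(self), chunk_size):
            yield FrameStack(self.frames[start : start + chunk_size], self.calibration)


def adu_to_photoelectrons(
    frame: Frame | np.ndarray,
    calib: CameraCalibration,
    base_level_adu: float | None = None,
) -> np.ndarray:
    """Convert grey values to photoelectrons.

    ``pe = max(0, ADU - base) * gain``. Values below the base level clamp to
    zero: Poisson photon counts cannot be negative and the ML fitters require
    non-negative data.

    The base level comes from ``base_level_adu`` if given, otherwise from the
    calibration; one of the two must be set.
    """
    values = frame.values if isinstance(frame, Frame) else np.asarray(frame)
    base = base_level_adu if base_level_adu is not None else calib.base_level_adu
    if base is None:
        raise CalibrationError(
            "no base level: set CameraCalibration.base_level_adu or pass base_level_adu"
        )
    if base < 0:
        raise CalibrationError(f"base level must be >= 0, got {base}")
    return np.maximum(values.astype(np.float64) - base, 0.0) * calib.photoelectrons_per_adu


def estimate_base_level(stack: FrameStack | Sequence[Frame]) -> float:
    """Estimate the dark offset as the mean of per-frame minimum grey values.

    The minimum is taken within each frame and then averaged over frames
    (the alternative reading — minimum of per-frame averages — is not used).
    """
    frames = list(stack)
    if not frames:
        raise EmptyStackError("cannot estimate base level of an empty stack")
    minima = [float(np.min(f.values)) for f in frames]
    return float(np.mean(minima))


# ---------------------------------------------------------------------------
# I/O

def read_stack(path: str | Path, calibration: CameraCalibration | None = None) -> FrameStack:
    """Read a multi-page TIFF stack (16-bit unsigned grey values)."""
    values = tifffile.imread(str(path))
    return FrameStack.from_array(values, calibration)


def write_stack(path: str | Path, stack: FrameStack | np.ndarray) -> None:
    """Write a stack as multi-page 16-bit TIFF."""
    arr = stack.as_array() if isinstance(stack, FrameStack) else np.asarray(stack)
    tifffile.imwrite(
        str(path),
        np.clip(np.rint(arr), 0, 65535).astype(np.uint16),
        photometric="minisblack",
    )


def load_calibration(source: str | Path | dict) -> CameraCalibration:
    """Load calibration from a YAML file or a dict.

    Recognised keys: ``pixel_size_nm``, ``pe_per_adu`` (or
    ``photoelectrons_per_adu``), ``base_level_adu`` (optional — when absent
    the base level is estimated from the data).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise CalibrationError(f"calibration source must be a mapping, got {type(data)}")
    gain = data.get("pe_per_adu", data.get("photoelectrons_per_adu"))
    if gain is None:
        raise CalibrationError("calibration needs pe_per_adu")
    return CameraCalibration(
        pixel_size_nm=float(data.get("pixel_size_nm", 80.0)),
        photoelectrons_per_adu=float(gain),
        base_level_adu=(
            float(data["base_level_adu"]) if data.get("base_level_adu") is not None else None
        ),
    )
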