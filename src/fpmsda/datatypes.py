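"""Core containers shared across the FPM pipeline."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

#: Frame illumination classes.  BF frames see the unscattered beam inside the
#: objective pupil; DF frames carry only scattered light; HYBRID frames contain
#: both and are excluded before correction/reconstruction.
BF = "BF"
DF = "DF"
HYBRID = "HYBRID"

#: Roles an image stack may take along the correction pipeline.
STACK_ROLES = ("S1", "S2", "S2prime", "S3", "S4")


class InvalidGeometryError(ValueError):
    """LED geometry with non-physical parameters."""


class ConfigurationError(ValueError):
    """Simulation / reconstruction configuration that cannot be realized."""


@dataclass
class ComplexObject:
    """High-resolution complex specimen field.

    Parameters
    ----------
    amplitude : ndarray
        Non-negative real transmission amplitude.
    phase : ndarray
        Phase in radians, same shape as ``amplitude``.
    pixel_size : float
        Sample-plane pixel pitch in micrometres.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase must share one shape")
        if self.amplitude.ndim != 2:
            raise ValueError("ComplexObject fields must be 2-D")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape

    @property
    def field(self) -> np.ndarray:
        """Complex field ``amplitude * exp(i * phase)``."""
        return self.amplitude * np.exp(1j * self.phase)


@dataclass
class ImageStack:
    """Ordered set of equally shaped non-negative intensity frames.

    ``led_index`` maps each frame to its LED; ``labels`` carries the BF/DF/
    HYBRID class of the illumination.  ``role`` records the pipeline stage
    (raw S1 through the SdA products S3/S4).  Only S1 stacks may still carry
    HYBRID frames.
    """

    frames: np.ndarray
    led_index: np.ndarray
    role: str
    labels: Sequence[str]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.led_index = np.asarray(self.led_index, dtype=int)
        self.labels = list(self.labels)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        n = self.frames.shape[0]
        if len(self.led_index) != n or len(self.labels) != n:
            raise ValueError("led_index and labels must match the frame count")
        if self.role not in STACK_ROLES:
            raise ValueError(f"unknown stack role {self.role!r}")
        if self.role != "S1" and HYBRID in self.labels:
            raise ValueError("only role-S1 stacks may carry HYBRID frames")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def select(self, keep: np.ndarray, role: str | None = None) -> "ImageStack":
        """Subset of frames (boolean or index array), order preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ImageStack(
            frames=self.frames[keep],
            led_index=self.led_index[keep],
            role=role if role is not None else self.role,
            labels=[self.labels[i] for i in keep],
        )

    def with_frames(self, frames: np.ndarray, role: str) -> "ImageStack":
        """Same indexing/labels with replaced pixel data and role."""
        return replace(self, frames=np.asarray(frames, dtype=float), role=role)

    def label_mask(self, label: str) -> np.ndarray:
        return np.array([lab == label for lab in self.labels], dtype=bool)


@dataclass
class MetricsReport:
    """Image-quality summary for one reconstruction versus a reference."""

    ssim: float
    mse: float
    snr_db: float | None = None
    contrast: float | None = None
    radial_freq: np.ndarray | None = None
    radial_log_power: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {"ssim": float(self.ssim), "mse": float(self.mse)}
        if self.snr_db is not None:
            out["snr_db"] = float(self.snr_db)
        if self.contrast is not None:
            out["contrast"] = float(self.contrast)
        if self.radial_freq is not None:
            out["radial_freq"] = [float(v) for v in self.radial_freq]
            out["radial_log_power"] = [float(v) for v in self.radial_log_power]
        return out
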