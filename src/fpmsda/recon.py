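"""Sequential Gauss-Newton FPM phase retrieval.

The reconstructor stitches the low-resolution measurements together in the
Fourier domain: starting from an upsampled on-axis brightfield image, each
frame's passband of the high-resolution spectrum is forward-projected through
the (ideal, binary) pupil, its real-space modulus is replaced by the measured
square-root intensity, and the passband is updated with a second-order
(Gauss-Newton) step

    O(k) <- O(k) + |P| conj(P) (Psi' - Psi) / (|P|_max (|P|^2 + delta))

with a small regularizer ``delta``.  The pupil is held fixed (no aberration
recovery).  Differentially corrected stacks can be substituted per iteration:
by default the rescaled low-SBR stack S4 drives iterations 1..N-1 and the
intensity-preserving stack S3 the final iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .datatypes import BF, HYBRID, ComplexObject, ConfigurationError, ImageStack
from .forward import (
    _fft2c,
    _ifft2c,
    pupil_mask,
    pupil_radius_pixels,
    shift_pixels,
)
from .geometry import IlluminationGeometry

logger = logging.getLogger(__name__)


class UnusableDatasetError(ValueError):
    """Stack left without brightfield frames after filtering."""


def exclude_hybrid_frames(stack: ImageStack) -> tuple[ImageStack, int]:
    """Drop frames labelled HYBRID (mixed BF/DF content), order preserved.

    Returns the filtered stack and the number of frames removed.  Raises
    :class:`UnusableDatasetError` if no BF frame survives.
    """
    keep = np.array([lab != HYBRID for lab in stack.labels], dtype=bool)
    removed = int((~keep).sum())
    out = stack.select(keep)
    if not any(lab == BF for lab in out.labels):
        raise UnusableDatasetError("no brightfield frames remain after exclusion")
    if removed:
        logger.info("excluded %d hybrid BF/DF frames", removed)
    return out, removed


@dataclass
class ReconSchedule:
    """Iteration plan for the sequential reconstruction.

    ``stack_per_iteration`` maps the 1-based iteration number to a stack
    role.  The default SdA schedule uses S4 for iterations 1..N-1 and S3 for
    the final iteration; when a single stack is passed to
    :func:`reconstruct` it is used throughout.
    """

    n_iterations: int = 10
    stack_per_iteration: dict[int, str] | None = None
    step_size: float = 1.0
    regularizer: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.step_size <= 0 or self.regularizer <= 0:
            raise ValueError("step_size and regularizer must be positive")

    def role_for(self, iteration: int, available: Sequence[str]) -> str:
        if self.stack_per_iteration is not None:
            try:
                return self.stack_per_iteration[iteration]
            except KeyError:
                raise ConfigurationError(f"no stack role for iteration {iteration}")
        if len(available) == 1:
            return next(iter(available))
        if "S3" in available and "S4" in available:
            return "S4" if iteration < self.n_iterations else "S3"
        raise ConfigurationError(
            "ambiguous schedule: pass stack_per_iteration for roles "
            f"{sorted(available)}"
        )


@dataclass
class ReconResult:
    """Reconstructed complex field plus convergence diagnostics."""

    field: np.ndarray
    per_iteration_residual: np.ndarray
    synthetic_na: float
    pixel_size: float

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.field)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.field)


def align_global_phase(field: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Remove the global-phase ambiguity by anchoring to a reference field."""
    inner = np.vdot(reference, field)
    if inner == 0:
        return field
    return field * np.exp(-1j * np.angle(inner))


def reconstruct(
    stacks: Mapping[str, ImageStack] | ImageStack,
    geometry: IlluminationGeometry,
    schedule: ReconSchedule | None = None,
    init: ComplexObject | None = None,
    hr_shape: int | None = None,
    pixel_size: float | None = None,
) -> ReconResult:
    """Run sequential Gauss-Newton phase retrieval.

    Parameters
    ----------
    stacks : mapping role -> ImageStack, or a single ImageStack
        Measurement stacks; all must share frame shape and LED indexing and
        contain no HYBRID frames.
    geometry : IlluminationGeometry
        The LED geometry the stacks were captured under.  Frames reference
        LEDs through ``led_index``.
    schedule : ReconSchedule
        Iteration count and per-iteration stack substitution.
    init : ComplexObject, optional
        Initial guess; defaults to the upsampled on-axis BF amplitude with
        zero phase.
    hr_shape : int, optional
        Reconstruction grid size; required if ``init`` is None.
    pixel_size : float, optional
        HR pixel size in micrometres (defines the frequency grid); required
        if ``init`` is None.
    """
    if isinstance(stacks, ImageStack):
        stacks = {stacks.role: stacks}
    if schedule is None:
        schedule = ReconSchedule()
    roles = list(stacks.keys())
    for it in range(1, schedule.n_iterations + 1):
        role = schedule.role_for(it, roles)
        if role not in stacks:
            raise ConfigurationError(f"schedule requests missing stack role {role!r}")

    first = next(iter(stacks.values()))
    for s in stacks.values():
        if s.frame_shape != first.frame_shape or len(s) != len(first):
            raise ValueError("all stacks must share shape and LED indexing")
        if HYBRID in s.labels:
            raise ValueError("exclude HYBRID frames before reconstruction")

    if init is not None:
        hr_shape = init.shape[0]
        pixel_size = init.pixel_size
    if hr_shape is None or pixel_size is None:
        raise ConfigurationError("hr_shape and pixel_size required without init")

    nl = first.frame_shape[0]
    nh = hr_shape
    r_px = pupil_radius_pixels(geometry, (nh, nh), pixel_size)
    pupil = pupil_mask((nl, nl), r_px)
    all_shifts = shift_pixels(geometry, (nh, nh), pixel_size)
    na_all = geometry.illumination_na()
    labels_all = geometry.labels()

    led_of_frame = first.led_index
    shifts = all_shifts[led_of_frame]
    na_frames = na_all[led_of_frame]
    # center-out sequence: ascending illumination NA, stable
    frame_order = np.argsort(na_frames, kind="stable")

    used_na = float(na_frames.max())
    synthetic_na = geometry.objective_na + used_na

    # coverage check: warn on gaps between adjacent passbands
    sorted_na = np.sort(na_frames)
    k_step = np.diff(sorted_na) / geometry.wavelength_um
    df = 1.0 / (nh * pixel_size)
    if k_step.size and np.any(k_step / df > 2 * r_px):
        logger.warning("passband coverage gap: adjacent passbands do not overlap")

    # initial spectrum
    if init is not None:
        spectrum = _fft2c(init.field)
    else:
        bf_candidates = [
            i
            for i in range(len(first))
            if labels_all[led_of_frame[i]] == BF
        ]
        if not bf_candidates:
            raise UnusableDatasetError("no BF frame available for initialization")
        i0 = min(bf_candidates, key=lambda i: na_frames[i])
        # scale such that the embedded passband reproduces the measured
        # on-axis amplitude when forward-projected onto the LR grid
        amp0 = np.sqrt(first.frames[i0])
        small = _fft2c(amp0)
        spectrum = np.zeros((nh, nh), dtype=complex)
        c, half = nh // 2, nl // 2
        spectrum[c - half : c - half + nl, c - half : c - half + nl] = small
    # keep the initial guess inside the objective passband
    spectrum *= pupil_mask((nh, nh), r_px)

    delta = schedule.regularizer  # ideal pupil: |P|^2_max = 1
    c, half = nh // 2, nl // 2
    residuals = np.empty(schedule.n_iterations)
    for it in range(1, schedule.n_iterations + 1):
        role = schedule.role_for(it, roles)
        frames = stacks[role].frames
        res = 0.0
        for j in frame_order:
            sr, sc = shifts[j]
            r0, c0 = c + sr - half, c + sc - half
            view = spectrum[r0 : r0 + nl, c0 : c0 + nl]
            psi_hat = view * pupil
            psi = _ifft2c(psi_hat)
            meas = np.sqrt(np.clip(frames[j], 0.0, None))
            mod = np.abs(psi)
            res += float(np.sum((meas - mod) ** 2))
            phase = np.where(mod > 0, psi / np.where(mod > 0, mod, 1.0), 1.0)
            psi_new = meas * phase
            psi_new_hat = _fft2c(psi_new)
            update = pupil * (psi_new_hat - psi_hat) / (1.0 + delta)
            view += schedule.step_size * update
        residuals[it - 1] = res

    # return to the measurement amplitude scale: the LR/HR grid ratio enters
    # through the DFT normalization of the cropped passband
    field = _ifft2c(spectrum) * (nh / nl) ** 2
    return ReconResult(
        field=field,
        per_iteration_residual=residuals,
        synthetic_na=synthetic_na,
        pixel_size=pixel_size,
    )
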