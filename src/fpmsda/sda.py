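"""Structure-dependent amplification (SdA) background correction.

Darkfield FPM frames carry weak scattered signal on top of a noisy camera
background; subtracting a single global threshold either leaves background
artefacts (threshold too low) or destroys high-frequency object signal
(threshold too high).  SdA side-steps the trade-off by exploiting real-space
redundancy across the stack: pixels are classified object/background from the
summed bright- and darkfield frames, object pixels are amplified so that a
``mean + 3*std`` background threshold can no longer clip them, and surviving
pixels are restored to their original intensities.

Pipeline (all statistics taken over the structure-free mask ``M``):

1. ``M``: Otsu-binarize the on-axis BF frame, dilate the object class by a
   disc ``s1``; ``M`` is the complement.
2. ``S2 = max(S1 - mean[S1(M)], 0)`` per DF frame (BF frames pass through).
3. ``I_BF``: reciprocal of the BF sum, background maximum subtracted,
   binarized and dilated by a disc ``s2`` — a conservative object map.
4. ``I_DF = max(sum_DF S2 - mean[sum_DF S2 (M)], 0)`` — amplification weights.
5. ``A = S2 * (I_DF * I_BF + I_BF^C)`` amplifies object pixels only.
6. ``S2' = max(A * I_BF - (mean[A(M)] + 3 std[A(M)]), 0)`` selects pixels.
7. ``S3``: original S2 intensity where ``S2' > 0``, else 0.
8. ``S4``: equal to S3 for frames with signal-to-background ratio SBR > 1;
   low-SBR frames instead carry ``S2'`` rescaled to the S2 frame maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk

from .datatypes import BF, DF, HYBRID, ImageStack

logger = logging.getLogger(__name__)


class MaskConstructionError(ValueError):
    """Background mask could not be built (constant frame or empty mask)."""


@dataclass
class SdAParams:
    """Tunable SdA parameters.

    ``s1_radius`` (default 20 px) controls how far the coarse object class is
    grown before taking the background complement; ``s2_radius`` (default
    8 px) fills holes and weak edges in the object map.  The defaults suit
    frames of a few hundred pixels; scale them down for smaller frames.
    ``sbr_threshold`` separates the direct-reassignment (S3) branch from the
    rescaling (S4) branch and is fixed at 1 by the method definition.
    """

    s1_radius: int = 20
    s2_radius: int = 8
    sbr_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.s1_radius < 1 or self.s2_radius < 1:
            raise ValueError("structuring-element radii must be positive integers")


@dataclass
class SdAMaps:
    """Masks and maps produced by the SdA classification stage."""

    M: np.ndarray
    I_BF: np.ndarray
    I_DF: np.ndarray
    s1_radius: int
    s2_radius: int
    sbr: np.ndarray | None = None  # per-DF-frame SBR, filled by amplification


def _object_class(frame: np.ndarray) -> np.ndarray:
    """Binary object class of a BF image via Otsu thresholding.

    Absorbing (stained) samples are darker than the background, so the
    below-threshold class is taken as object; if that class covers the
    majority of the frame the sample is brighter than its background and the
    classes are swapped (logged).
    """
    if np.all(frame == frame.flat[0]):
        raise MaskConstructionError("constant frame: Otsu threshold undefined")
    thresh = threshold_otsu(frame, nbins=256)
    obj = frame < thresh
    if obj.mean() > 0.5:
        logger.info("bright-object sample detected; swapping Otsu classes")
        obj = ~obj
    return obj


def build_background_mask(bf_on_axis: np.ndarray, s1_radius: int = 20) -> np.ndarray:
    """Structure-free pixel mask M from the normal-incidence BF frame.

    Otsu-binarizes the frame, dilates the object class with a disc of radius
    ``s1_radius`` (reclassifying object pixels that leaked into the
    background), and returns the complement.
    """
    bf_on_axis = np.asarray(bf_on_axis, dtype=float)
    if np.any(bf_on_axis < 0):
        raise ValueError("BF frame must be non-negative")
    obj = _object_class(bf_on_axis)
    grown = dilation(obj, disk(int(s1_radius)))
    M = ~grown
    if not M.any():
        raise MaskConstructionError(
            "background mask is empty: object fills the frame at this s1 radius"
        )
    return M


def subtract_initial_background(stack: ImageStack, M: np.ndarray) -> ImageStack:
    """Step 2: remove the mean background of each DF frame (role S1 -> S2)."""
    _check_mask(M, stack)
    if HYBRID in stack.labels:
        raise ValueError("exclude HYBRID frames before background subtraction")
    out = stack.frames.copy()
    for i, lab in enumerate(stack.labels):
        if lab == DF:
            out[i] = np.clip(stack.frames[i] - stack.frames[i][M].mean(), 0.0, None)
    return stack.with_frames(out, role="S2")


def compute_object_map(
    stack: ImageStack, M: np.ndarray, s2_radius: int = 8
) -> np.ndarray:
    """Step 3: binary object map I_BF from the reciprocal of the BF sum.

    Zero-valued pixels of the BF sum (where the reciprocal diverges) are
    assigned the largest finite reciprocal and logged.
    """
    _check_mask(M, stack)
    bf = stack.label_mask(BF)
    if not bf.any():
        raise ValueError("at least one BF frame required")
    s = stack.frames[bf].sum(axis=0)
    zero = s == 0
    with np.errstate(divide="ignore"):
        t = np.where(zero, np.inf, 1.0 / np.where(zero, 1.0, s))
    if zero.any():
        logger.warning(
            "%d zero-valued BF-sum pixels; reciprocal set to max finite value",
            int(zero.sum()),
        )
        t[zero] = t[~zero].max() if (~zero).any() else 1.0
    t = t - t[M].max()
    binary = t > 0
    return dilation(binary, disk(int(s2_radius)))


def compute_amplification_map(stack: ImageStack, M: np.ndarray) -> np.ndarray:
    """Step 4: non-negative amplification map I_DF from the DF sum."""
    _check_mask(M, stack)
    df = stack.label_mask(DF)
    if not df.any():
        raise ValueError("at least one DF frame required")
    s = stack.frames[df].sum(axis=0)
    return np.clip(s - s[M].mean(), 0.0, None)


def amplify_and_build_stacks(
    stack: ImageStack, maps: SdAMaps, params: SdAParams | None = None
) -> tuple[ImageStack, ImageStack, np.ndarray]:
    """Steps 5-7: amplify, threshold, and emit the corrected stacks S3 and S4.

    Returns ``(S3, S4, sbr)`` where ``sbr`` holds the signal-to-background
    ratio of each frame (NaN for BF frames, which pass through unchanged).
    """
    if params is None:
        params = SdAParams()
    M = np.asarray(maps.M, dtype=bool)
    I_BF = np.asarray(maps.I_BF, dtype=bool)
    I_DF = np.asarray(maps.I_DF, dtype=float)
    if np.any(I_DF < 0):
        raise ValueError("I_DF must be non-negative")
    _check_mask(M, stack)
    if I_BF.shape != stack.frame_shape or I_DF.shape != stack.frame_shape:
        raise ValueError("maps must match the frame shape")

    s3 = stack.frames.copy()
    s4 = stack.frames.copy()
    sbr = np.full(len(stack), np.nan)
    obj = I_BF
    comp = ~I_BF
    for i, lab in enumerate(stack.labels):
        if lab != DF:
            continue
        s2f = stack.frames[i]
        amplified = s2f * (I_DF * obj + comp)
        thresh = amplified[M].mean() + 3.0 * amplified[M].std()
        s2p = np.clip(amplified * obj - thresh, 0.0, None)
        s3f = np.where(s2p > 0, s2f, 0.0)
        s3[i] = s3f

        bg_mean = s2f[M].mean()
        if bg_mean == 0:
            frame_sbr = np.inf
        elif not obj.any():
            frame_sbr = 0.0
        else:
            with np.errstate(over="ignore"):  # denormal background -> inf SBR
                frame_sbr = s2f[obj].mean() / bg_mean
        sbr[i] = frame_sbr

        if frame_sbr > params.sbr_threshold:
            s4[i] = s3f
        else:
            peak = s2p.max()
            if peak == 0:
                logger.warning(
                    "frame %d: S2' is identically zero in the low-SBR branch; "
                    "emitting an all-zero frame",
                    i,
                )
                s4[i] = np.zeros_like(s2f)
            else:
                s4[i] = np.where(s2p > 0, s2p / peak * s2f.max(), 0.0)

    return (
        stack.with_frames(s3, role="S3"),
        stack.with_frames(s4, role="S4"),
        sbr,
    )


def run_sda(
    stack: ImageStack, params: SdAParams | None = None
) -> tuple[ImageStack, ImageStack, SdAMaps]:
    """Full SdA pipeline on a HYBRID-free raw stack (role S1).

    Convenience wrapper chaining mask construction, initial subtraction,
    map computation and amplification.  The on-axis BF frame is taken as the
    BF frame of lowest illumination NA present, assumed first in BF order.
    """
    if params is None:
        params = SdAParams()
    bf_idx = np.flatnonzero(stack.label_mask(BF))
    if bf_idx.size == 0:
        raise ValueError("SdA requires at least one BF frame")
    M = build_background_mask(stack.frames[bf_idx[0]], params.s1_radius)
    s2 = subtract_initial_background(stack, M)
    I_BF = compute_object_map(s2, M, params.s2_radius)
    I_DF = compute_amplification_map(s2, M)
    # a pixel is never both background and object
    M = M & ~I_BF
    if not M.any():
        raise MaskConstructionError("background mask emptied by the object map")
    maps = SdAMaps(
        M=M, I_BF=I_BF, I_DF=I_DF, s1_radius=params.s1_radius, s2_radius=params.s2_radius
    )
    s3, s4, sbr = amplify_and_build_stacks(s2, maps, params)
    maps.sbr = sbr
    logger.info(
        "SdA: %d DF frames, SBR range [%.3g, %.3g]",
        int(np.isfinite(sbr).sum() + np.isinf(sbr).sum()),
        np.nanmin(sbr) if np.isfinite(sbr).any() else float("nan"),
        np.nanmax(sbr[np.isfinite(sbr)]) if np.isfinite(sbr).any() else float("nan"),
    )
    return s3, s4, maps


def _check_mask(M: np.ndarray, stack: ImageStack) -> None:
    M = np.asarray(M)
    if M.dtype != bool:
        raise ValueError("M must be boolean")
    if M.shape != stack.frame_shape:
        raise ValueError("mask shape must match the frame shape")
    if not M.any():
        raise MaskConstructionError("background mask is empty")
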