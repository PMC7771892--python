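"""Reference darkfield background-correction methods.

These are the conventional corrections SdA is benchmarked against: global
subtraction of a scalar background estimate taken over a structure-free
region ('mean' and 'mean + 3 sigma'), and the classical rolling-ball
background (Sternberg), realized as a grayscale opening with a ball-shaped
structuring function.  Brightfield frames are never background-subtracted.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .datatypes import DF, ImageStack
from .sda import _check_mask


def global_subtract(stack: ImageStack, M: np.ndarray, k_sigma: float = 0.0) -> ImageStack:
    """Subtract ``mean + k_sigma * std`` over M from each DF frame and clamp.

    ``k_sigma = 0`` is the 'mean' method; ``k_sigma = 3`` the 'mean + 3 sigma'
    method, which drives ~99.7% of Gaussian background pixels to zero.
    """
    _check_mask(np.asarray(M, dtype=bool), stack)
    M = np.asarray(M, dtype=bool)
    out = stack.frames.copy()
    for i, lab in enumerate(stack.labels):
        if lab == DF:
            frame = stack.frames[i]
            thresh = frame[M].mean() + k_sigma * frame[M].std()
            out[i] = np.clip(frame - thresh, 0.0, None)
    return stack.with_frames(out, role=stack.role)


def _ball_structure(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-flat ball structuring function (heights) and its disc footprint."""
    x = np.arange(-radius, radius + 1)
    yy, xx = np.meshgrid(x, x, indexing="ij")
    d2 = yy**2 + xx**2
    footprint = d2 <= radius**2
    heights = np.where(footprint, np.sqrt(np.clip(radius**2 - d2, 0.0, None)), 0.0)
    return heights, footprint


def rolling_ball_background(frame: np.ndarray, radius: int) -> np.ndarray:
    """Rolling-ball background: grayscale opening with a ball structuring
    function (erosion then dilation), nearest-edge boundary handling."""
    frame = np.asarray(frame, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if 2 * radius + 1 > min(frame.shape):
        raise ValueError("rolling-ball radius larger than the frame")
    heights, footprint = _ball_structure(int(radius))
    eroded = ndi.grey_erosion(frame, structure=heights, footprint=footprint, mode="nearest")
    return ndi.grey_dilation(eroded, structure=heights, footprint=footprint, mode="nearest")


def rolling_ball_subtract(stack: ImageStack, radius: int) -> ImageStack:
    """Per-DF-frame rolling-ball background subtraction (clamped at zero).

    The radius is a tunable: it must exceed the scale of real image features
    for the background estimate not to swallow them.
    """
    out = stack.frames.copy()
    for i, lab in enumerate(stack.labels):
        if lab == DF:
            bg = rolling_ball_background(stack.frames[i], radius)
            out[i] = np.clip(stack.frames[i] - bg, 0.0, None)
    return stack.with_frames(out, role=stack.role)
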