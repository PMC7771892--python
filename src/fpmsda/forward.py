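"""Coherent FPM forward model and camera-noise degradation.

Image formation: for illumination wavevector ``k`` the objective transmits
the object spectrum inside a circular pupil of radius ``NA_obj / lambda``
centred at ``k``.  On the discrete grid this is realized by cropping an
``lr_shape`` window, centred at the wavevector rounded to the nearest
frequency pixel, out of the DC-centred high-resolution spectrum, masking it
with the pupil disc, and taking the squared modulus of its inverse transform.
Because the low-resolution pixel pitch is ``dx * n_hr / n_lr`` the frequency
pixel spacing of the HR and LR grids coincide, so pupil radius and wavevector
shift share one unit (frequency pixels of ``1 / (n_hr * dx)`` um^-1).

The camera model adds a constant offset (dark current + stray light), shot
noise (Poisson, applied on the photo-electron scale so SNR grows as the
square root of the signal) and additive white Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ComplexObject, ConfigurationError, ImageStack
from .geometry import IlluminationGeometry, compute_wavevectors


def _fft2c(x: np.ndarray) -> np.ndarray:
    """DC-centred 2-D FFT."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x)))


def _ifft2c(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_fft2c`."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x)))


def pupil_mask(shape: tuple[int, int], radius_px: float) -> np.ndarray:
    """Binary circular pupil on a DC-centred frequency grid."""
    fy = np.arange(shape[0]) - shape[0] // 2
    fx = np.arange(shape[1]) - shape[1] // 2
    yy, xx = np.meshgrid(fy, fx, indexing="ij")
    return (yy**2 + xx**2) <= radius_px**2


def frequency_pixel(obj_shape: tuple[int, int], pixel_size: float) -> float:
    """Frequency-pixel spacing (um^-1) of the DC-centred HR spectrum grid."""
    if obj_shape[0] != obj_shape[1]:
        raise ConfigurationError("square object grids required")
    return 1.0 / (obj_shape[0] * pixel_size)


def shift_pixels(
    geometry: IlluminationGeometry, obj_shape: tuple[int, int], pixel_size: float
) -> np.ndarray:
    """Per-LED passband-centre shift in (row, col) frequency pixels (rounded)."""
    k, _ = compute_wavevectors(geometry)
    df = frequency_pixel(obj_shape, pixel_size)
    # rows index ky, columns kx
    return np.rint(np.column_stack([k[:, 1], k[:, 0]]) / df).astype(int)


def pupil_radius_pixels(
    geometry: IlluminationGeometry, obj_shape: tuple[int, int], pixel_size: float
) -> float:
    df = frequency_pixel(obj_shape, pixel_size)
    return geometry.objective_na / geometry.wavelength_um / df


def simulate_lr_stack(
    obj: ComplexObject,
    geometry: IlluminationGeometry,
    lr_shape: int | tuple[int, int],
    intensity_scale: float = 1.0,
) -> ImageStack:
    """Simulate the noise-free raw (role S1) low-resolution intensity stack.

    Parameters
    ----------
    obj : ComplexObject
        Ground-truth high-resolution complex field.
    geometry : IlluminationGeometry
        LED array; one frame is produced per LED, in LED order.
    lr_shape : int or (int, int)
        Low-resolution frame size in pixels (must be square and smaller than
        the object grid).
    intensity_scale : float
        Detected counts per unit object intensity: a uniform unit-amplitude
        object yields an on-axis BF frame of ``intensity_scale`` counts.
    """
    if isinstance(lr_shape, int):
        lr_shape = (lr_shape, lr_shape)
    nh = obj.shape[0]
    nl = lr_shape[0]
    if lr_shape[0] != lr_shape[1]:
        raise ConfigurationError("lr_shape must be square")
    if nl >= nh:
        raise ConfigurationError("lr_shape must be smaller than the HR grid")

    r_px = pupil_radius_pixels(geometry, obj.shape, obj.pixel_size)
    if r_px < 2:
        raise ConfigurationError(
            f"pupil radius {r_px:.2f} px < 2; increase grid size or pixel size"
        )
    if r_px > nl // 2:
        raise ConfigurationError(
            f"pupil radius {r_px:.2f} px exceeds the LR frequency grid ({nl // 2} px)"
        )

    shifts = shift_pixels(geometry, obj.shape, obj.pixel_size)
    if np.any(np.abs(shifts) + nl // 2 > nh // 2):
        raise ConfigurationError(
            "HR grid too small for the largest illumination angle: "
            "shifted passband wraps around the spectrum edge"
        )

    spectrum = _fft2c(obj.field)
    pupil = pupil_mask(lr_shape, r_px)
    c = nh // 2
    half = nl // 2
    # normalization such that a uniform unit object maps to unit intensity
    norm = (nl / nh) ** 4
    frames = np.empty((geometry.n_leds, nl, nl))
    for i, (sr, sc) in enumerate(shifts):
        r0 = c + sr - half
        c0 = c + sc - half
        patch = spectrum[r0 : r0 + nl, c0 : c0 + nl] * pupil
        psi = _ifft2c(patch)
        frames[i] = np.abs(psi) ** 2 * norm * intensity_scale
    return ImageStack(
        frames=frames,
        led_index=np.arange(geometry.n_leds),
        role="S1",
        labels=geometry.labels(),
    )


def band_limited_reference(
    obj: ComplexObject, geometry: IlluminationGeometry, support: str = "coverage"
) -> np.ndarray:
    """Ground-truth field restricted to the recoverable frequency support.

    ``support='coverage'`` (default) keeps the union of the sampled
    passbands — the frequencies any reconstruction from this geometry can
    actually recover.  ``support='disc'`` uses the full synthetic-NA disc,
    an isotropic upper bound that LED grids only reach along their densest
    directions.
    """
    df = frequency_pixel(obj.shape, obj.pixel_size)
    nh = obj.shape[0]
    if support == "disc":
        cutoff_px = geometry.synthetic_na / geometry.wavelength_um / df
        mask = pupil_mask(obj.shape, cutoff_px)
    elif support == "coverage":
        r_px = pupil_radius_pixels(geometry, obj.shape, obj.pixel_size)
        fy = np.arange(nh) - nh // 2
        yy, xx = np.meshgrid(fy, fy, indexing="ij")
        mask = np.zeros(obj.shape, dtype=bool)
        labels = geometry.labels()
        for (sr, sc), lab in zip(shift_pixels(geometry, obj.shape, obj.pixel_size), labels):
            if lab == "HYBRID":
                continue
            mask |= (yy - sr) ** 2 + (xx - sc) ** 2 <= r_px**2
    else:
        raise ValueError("support must be 'coverage' or 'disc'")
    return _ifft2c(_fft2c(obj.field) * mask)


@dataclass
class NoiseModel:
    """Camera degradation: constant offset, shot noise, Gaussian read noise.

    ``poisson_gain`` is the counts-per-photo-electron conversion; 0 disables
    shot noise.  ``seed`` fully determines the degradation (one sub-stream
    per frame, derived from ``(seed, frame index)``).
    """

    offset: float = 0.0
    gaussian_sigma: float = 0.0
    poisson_gain: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.poisson_gain < 0:
            raise ValueError("poisson_gain must be >= 0")


def degrade_stack(stack: ImageStack, noise: NoiseModel) -> ImageStack:
    """Apply the noise model to a raw stack (role S1 in, role S1 out).

    Per frame: ``clip(offset + Poisson(frame / gain) * gain + N(0, sigma), 0)``.
    Reproducible bit-exactly for a fixed ``NoiseModel.seed``.
    """
    if stack.role != "S1":
        raise ValueError("degradation applies to raw (role S1) stacks")
    out = np.empty_like(stack.frames)
    for i, frame in enumerate(stack.frames):
        rng = np.random.default_rng([int(noise.seed), i])
        f = frame.astype(float)
        if noise.poisson_gain > 0:
            f = rng.poisson(f / noise.poisson_gain).astype(float) * noise.poisson_gain
        f = f + noise.offset
        if noise.gaussian_sigma > 0:
            f = f + rng.normal(0.0, noise.gaussian_sigma, size=f.shape)
        out[i] = np.clip(f, 0.0, None)
    return stack.with_frames(out, role="S1")
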