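"""Synthetic ground-truth objects.

Two object families cover the cases used throughout testing and in the
experiment driver: a resolution bar target (groups of dark bars of graded
pitch in two orientations on a bright background, in the spirit of a USAF
1951 chart) and a seeded procedural texture with natural-image-like 1/f
spectral falloff and sharp edges.  Both couple phase to amplitude:
``phase = pi * amplitude / max(amplitude)``, i.e. the amplitude scaled to
[0, pi].
"""

from __future__ import annotations

import numpy as np

from .datatypes import ComplexObject


class AliasingError(ValueError):
    """Bar period below the 2-pixel sampling limit."""


def _phase_from_amplitude(amplitude: np.ndarray) -> np.ndarray:
    peak = amplitude.max()
    return np.pi * amplitude / peak if peak > 0 else np.zeros_like(amplitude)


def _bar_layout(
    shape: tuple[int, int], bar_periods: list[int], fill_fraction: float
) -> list[tuple[int, int, int, int, int, str]]:
    """Bar-block placements (r0, r1, c0, c1, period, orientation).

    Bar groups live inside a central square covering ``fill_fraction`` of
    the field side, leaving a wide empty background around them — FPM test
    scenes (chart portions, blood films) are sparse, and the structure-free
    surround is what the background corrections estimate their statistics
    from.
    """
    n_r, n_c = shape
    s = int(round(min(n_r, n_c) * fill_fraction))
    r_off = (n_r - s) // 2
    c_off = (n_c - s) // 2
    gap = max(s // 12, 2)
    row_h = s // len(bar_periods)
    block_w = (s - gap) // 2
    blocks = []
    for k, p in enumerate(bar_periods):
        r0 = r_off + k * row_h
        r1 = min(r0 + row_h - gap, r_off + s)
        if r1 <= r0:
            continue
        blocks.append((r0, r1, c_off, c_off + block_w, int(p), "vertical"))
        blocks.append(
            (r0, r1, c_off + block_w + gap, c_off + s, int(p), "horizontal")
        )
    return blocks


def make_bar_target(
    shape: int | tuple[int, int],
    bar_periods: list[int],
    pixel_size: float,
    bar_amplitude: float = 0.2,
    fill_fraction: float = 0.4,
) -> ComplexObject:
    """Resolution bar target with the given bar pitches (pixels).

    One row of bar blocks per period inside a central square, each row
    holding a vertical-bar block (intensity varies along columns) and a
    horizontal-bar block.  Bars have amplitude ``bar_amplitude`` on a
    background of 1; a bar group of pitch ``p`` pixels puts its fundamental
    at ``1 / (p * pixel_size)`` um^-1.
    """
    if isinstance(shape, int):
        shape = (shape, shape)
    if min(bar_periods) < 2:
        raise AliasingError("bar periods below 2 pixels alias on the grid")
    amp = np.ones(shape)
    for r0, r1, c0, c1, p, orient in _bar_layout(shape, bar_periods, fill_fraction):
        if orient == "vertical":
            cols = np.arange(c1 - c0)
            wave = np.where((cols % p) < p / 2.0, bar_amplitude, 1.0)
            amp[r0:r1, c0:c1] = wave[None, :]
        else:
            rows = np.arange(r1 - r0)
            wave = np.where((rows % p) < p / 2.0, bar_amplitude, 1.0)
            amp[r0:r1, c0:c1] = wave[:, None]
    return ComplexObject(
        amplitude=amp, phase=_phase_from_amplitude(amp), pixel_size=pixel_size
    )


def bar_target_regions(
    shape: int | tuple[int, int],
    bar_periods: list[int],
    fill_fraction: float = 0.4,
) -> dict:
    """Canonical evaluation regions for :func:`make_bar_target`.

    Returns a dict with ``snr_region`` — an (r, c, h, w) homogeneous
    background patch in the empty top-left corner — and ``profiles`` — one
    ``(coords, period)`` pair per bar group, each a line of (row, col)
    coordinates crossing the vertical-bar block perpendicular to the bars.
    """
    if isinstance(shape, int):
        shape = (shape, shape)
    n_r, n_c = shape
    side = max(n_r // 8, 4)
    off = max(n_r // 48, 2)
    snr_region = (off, off, side, side)
    profiles = []
    for r0, r1, c0, c1, p, orient in _bar_layout(shape, bar_periods, fill_fraction):
        if orient != "vertical":
            continue
        row = (r0 + r1) // 2
        n_per = max((c1 - c0) // p, 1)
        cols = np.arange(c0, c0 + n_per * p)
        coords = np.column_stack([np.full(cols.shape, row), cols])
        profiles.append((coords, p))
    return {"snr_region": snr_region, "profiles": profiles}


def make_texture_object(
    shape: int | tuple[int, int], seed: int, pixel_size: float = 0.3
) -> ComplexObject:
    """Seeded procedural texture with 1/f-like spectrum and sharp edges.

    A smooth pink-noise field supplies the natural-image spectral falloff;
    thresholding a second, coarser field adds step edges.  Amplitude is
    normalized to span [0, 1] exactly; reproducible per seed.
    """
    if isinstance(shape, int):
        shape = (shape, shape)
    if min(shape) < 64:
        raise ValueError("texture objects require shape >= 64x64")
    rng = np.random.default_rng(seed)
    base = _pink_field(shape, rng, exponent=1.2)
    coarse = _pink_field(shape, rng, exponent=2.0)
    edges = (coarse > np.median(coarse)).astype(float)
    amp = 0.65 * _unit(base) + 0.35 * edges
    amp = _unit(amp)
    return ComplexObject(
        amplitude=amp, phase=_phase_from_amplitude(amp), pixel_size=pixel_size
    )


def _pink_field(shape: tuple[int, int], rng: np.random.Generator, exponent: float) -> np.ndarray:
    """Real random field with isotropic 1/f^exponent amplitude spectrum."""
    white = rng.normal(size=shape)
    spec = np.fft.fft2(white)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.hypot(fy, fx)
    f0 = 1.0 / max(shape)
    spec *= 1.0 / (f + f0) ** exponent
    return np.real(np.fft.ifft2(spec))


def _unit(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)
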