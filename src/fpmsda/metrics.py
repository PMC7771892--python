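"""Image-quality metrics for reconstruction assessment.

SSIM and MSE against a noise-free reference reconstruction, SNR in a
homogeneous region, Michelson contrast across resolution-target bar
profiles, and the azimuthally averaged power spectrum used to judge the
frequency support of a reconstruction.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

from .datatypes import MetricsReport


def compare_images(test: np.ndarray, reference: np.ndarray) -> tuple[float, float]:
    """SSIM and MSE of a test image against a reference.

    SSIM uses a 7-pixel window and the standard K1/K2 constants with the
    data range set by the joint dynamic range of the two images.  Amplitude
    and phase images are compared separately by calling this twice.
    """
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.shape != reference.shape:
        raise ValueError("shape mismatch between test and reference")
    lo = min(test.min(), reference.min())
    hi = max(test.max(), reference.max())
    data_range = hi - lo if hi > lo else 1.0
    ssim = structural_similarity(
        reference, test, win_size=7, data_range=data_range
    )
    mse = float(np.mean((test - reference) ** 2))
    return float(ssim), mse


def snr_db(region: np.ndarray, convention: str = "amplitude") -> float:
    """SNR of a homogeneous region: ``20 log10(mean / std)`` (dB).

    ``convention='intensity'`` switches to ``10 log10``.  The region must be
    non-constant with positive mean.
    """
    region = np.asarray(region, dtype=float)
    mu = region.mean()
    sd = region.std()
    if sd == 0:
        raise ValueError("zero standard deviation: SNR undefined")
    if mu <= 0:
        raise ValueError("region mean must be positive")
    factor = 20.0 if convention == "amplitude" else 10.0
    return float(factor * np.log10(mu / sd))


def line_contrast(
    amplitude: np.ndarray,
    profiles: list[np.ndarray],
    period: int | None = None,
) -> float:
    """Average Michelson contrast across bar-target line profiles.

    Each profile is an (n, 2) integer array of (row, col) pixel coordinates
    crossing one or more full bar periods.  The profile is chopped into
    periods of ``period`` samples (estimated from the dominant Fourier
    component when not given); Michelson contrast
    ``(Imax - Imin) / (Imax + Imin)`` is computed per period and averaged
    over periods and profiles.  A flat profile has contrast 0.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    values_list = []
    for prof in profiles:
        prof = np.asarray(prof, dtype=int)
        values_list.append(amplitude[prof[:, 0], prof[:, 1]])

    contrasts = []
    for vals in values_list:
        if np.ptp(vals) == 0:
            contrasts.append(0.0)
            continue
        p = period if period is not None else _dominant_period(vals)
        if p is None or p < 2 or p > len(vals):
            # fewer than one resolvable period: fall back to whole profile
            chunks = [vals]
        else:
            n_per = len(vals) // p
            chunks = [vals[i * p : (i + 1) * p] for i in range(n_per)]
        per_period = []
        for ch in chunks:
            hi, lo = ch.max(), ch.min()
            per_period.append(0.0 if hi + lo == 0 else (hi - lo) / (hi + lo))
        contrasts.append(float(np.mean(per_period)))
    return float(np.mean(contrasts))


def _dominant_period(values: np.ndarray) -> int | None:
    """Period (samples) of the strongest non-DC Fourier component."""
    spec = np.abs(np.fft.rfft(values - values.mean()))
    if spec.size < 2:
        return None
    k = int(np.argmax(spec[1:]) + 1)
    return int(round(len(values) / k))


def radial_power_spectrum(
    amplitude: np.ndarray, pixel_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthally averaged log power spectrum.

    Returns (frequency in um^-1, log10 power) where the power in each
    1-frequency-pixel-wide annulus of the DC-centred 2-D spectrum is
    averaged.  Non-square inputs are zero-padded to square.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    n = max(amplitude.shape)
    if amplitude.shape != (n, n):
        padded = np.zeros((n, n))
        padded[: amplitude.shape[0], : amplitude.shape[1]] = amplitude
        amplitude = padded
    spec = np.fft.fftshift(np.fft.fft2(amplitude))
    power = np.abs(spec) ** 2
    c = n // 2
    yy, xx = np.indices((n, n))
    rad = np.hypot(yy - c, xx - c)
    bins = np.arange(0, c + 1)
    idx = np.clip(np.rint(rad).astype(int), 0, None)
    keep = idx <= c
    profile = np.bincount(idx[keep], weights=power[keep], minlength=c + 1)
    counts = np.bincount(idx[keep], minlength=c + 1)
    profile = profile / np.maximum(counts, 1)
    freq = bins / (n * pixel_size)
    floor = profile.max() * 1e-15 if profile.max() > 0 else 1e-300
    return freq, np.log10(np.maximum(profile, floor))


def evaluate(
    test_amplitude: np.ndarray,
    reference_amplitude: np.ndarray,
    pixel_size: float,
    snr_region: tuple[int, int, int, int] | None = None,
    profiles: list[np.ndarray] | None = None,
    profile_period: int | None = None,
) -> MetricsReport:
    """Full metric suite for one reconstruction against a reference.

    ``snr_region`` is (row, col, height, width) of a homogeneous patch.
    """
    ssim, mse = compare_images(test_amplitude, reference_amplitude)
    snr = None
    if snr_region is not None:
        r, c, h, w = snr_region
        snr = snr_db(test_amplitude[r : r + h, c : c + w])
    contrast = None
    if profiles:
        contrast = line_contrast(test_amplitude, profiles, profile_period)
    freq, log_power = radial_power_spectrum(test_amplitude, pixel_size)
    return MetricsReport(
        ssim=ssim,
        mse=mse,
        snr_db=snr,
        contrast=contrast,
        radial_freq=freq,
        radial_log_power=log_power,
    )
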