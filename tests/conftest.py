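"""Shared fixtures: small, fast FPM scenes used across the unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from fpmsda import (
    ComplexObject,
    ImageStack,
    band_limited_reference,
    exclude_hybrid_frames,
    led_grid,
    make_bar_target,
    simulate_lr_stack,
)

HR = 128
LR = 48
PIXEL = 0.3


@pytest.fixture(scope="session")
def small_geometry():
    """9x9 LED grid: 9 BF, 4 HYBRID, 68 DF frames at NA 0.16."""
    return led_grid(9, pitch=5.0, array_height=60.0, wavelength=532.0, objective_na=0.16)


@pytest.fixture(scope="session")
def small_object(small_geometry):
    """Band-limited bar target on the 128-px grid (recoverable content only)."""
    obj = make_bar_target(HR, [12, 8], PIXEL)
    field = band_limited_reference(obj, small_geometry)
    return ComplexObject(np.abs(field), np.angle(field), PIXEL)


@pytest.fixture(scope="session")
def clean_stack(small_object, small_geometry):
    """Noise-free raw stack (role S1, HYBRID frames still present)."""
    return simulate_lr_stack(small_object, small_geometry, LR, intensity_scale=1.0)


@pytest.fixture(scope="session")
def clean_kept(clean_stack):
    stack, _ = exclude_hybrid_frames(clean_stack)
    return stack


def toy_stack(frames, labels, role="S1"):
    """ImageStack from a list of arrays and labels (LED index = position)."""
    frames = np.asarray(frames, dtype=float)
    return ImageStack(
        frames=frames,
        led_index=np.arange(frames.shape[0]),
        role=role,
        labels=labels,
    )
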