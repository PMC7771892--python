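"""LED-array illumination geometry.

An FPM dataset is captured by lighting one LED of a planar array at a time.
Each LED at lateral offset ``(x, y)`` mm and height ``h`` mm below the sample
illuminates the specimen as a tilted plane wave with illumination numerical
aperture ``NA_ill = sin(atan(r / h)) = r / sqrt(r^2 + h^2)`` and transverse
spatial frequency ``k = NA_ill / lambda`` (micrometre^-1).  Frames are
classified brightfield (BF) when the unscattered beam falls inside the
objective pupil, darkfield (DF) when it falls outside, and HYBRID within a
small NA band around the pupil edge where both regimes coexist in one frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import BF, DF, HYBRID, InvalidGeometryError


@dataclass
class IlluminationGeometry:
    """LED positions and optical parameters of the FPM system.

    Parameters
    ----------
    led_positions : (n, 2) array
        Lateral LED offsets (x, y) in millimetres relative to the optical axis.
    array_height : float
        Sample-to-array distance in millimetres.
    wavelength : float
        Illumination wavelength in nanometres.
    objective_na : float
        Numerical aperture of the objective lens.
    hybrid_band : float
        Half-width (in NA units) of the band around ``objective_na`` within
        which a frame is labelled HYBRID.  Default 0.02.
    """

    led_positions: np.ndarray
    array_height: float
    wavelength: float
    objective_na: float
    hybrid_band: float = 0.02

    def __post_init__(self) -> None:
        self.led_positions = np.atleast_2d(np.asarray(self.led_positions, dtype=float))
        if self.led_positions.shape[1] != 2:
            raise InvalidGeometryError("led_positions must be (n, 2)")
        if self.array_height <= 0:
            raise InvalidGeometryError("array_height must be positive")
        if self.wavelength <= 0:
            raise InvalidGeometryError("wavelength must be positive")
        if not 0 < self.objective_na < 1:
            raise InvalidGeometryError("objective_na must lie in (0, 1)")
        if self.hybrid_band < 0:
            raise InvalidGeometryError("hybrid_band must be non-negative")

    @property
    def n_leds(self) -> int:
        return self.led_positions.shape[0]

    @property
    def wavelength_um(self) -> float:
        return self.wavelength * 1e-3

    def illumination_na(self) -> np.ndarray:
        """Per-LED illumination NA, ``r / sqrt(r^2 + h^2)`` (in [0, 1))."""
        r = np.hypot(self.led_positions[:, 0], self.led_positions[:, 1])
        return r / np.hypot(r, self.array_height)

    def labels(self) -> list[str]:
        """BF/DF/HYBRID class per LED from its illumination NA."""
        na = self.illumination_na()
        out = []
        for v in na:
            if v <= self.objective_na - self.hybrid_band:
                out.append(BF)
            elif v >= self.objective_na + self.hybrid_band:
                out.append(DF)
            else:
                out.append(HYBRID)
        return out

    @property
    def max_illumination_na(self) -> float:
        return float(self.illumination_na().max())

    @property
    def synthetic_na(self) -> float:
        """Objective NA plus the largest illumination NA (frequency cutoff)."""
        return self.objective_na + self.max_illumination_na


def compute_wavevectors(geometry: IlluminationGeometry) -> tuple[np.ndarray, list[str]]:
    """Per-LED transverse spatial frequencies and BF/DF/HYBRID labels.

    Returns
    -------
    wavevectors : (n, 2) array
        ``(kx, ky)`` in micrometre^-1.  Sign convention: an LED displaced to
        positive x shifts the captured passband centre to positive kx, i.e.
        ``k = (x, y) / (lambda * sqrt(x^2 + y^2 + h^2))``.
    labels : list of str
        Illumination class per LED.
    """
    pos = geometry.led_positions
    h = geometry.array_height
    norm = np.sqrt(pos[:, 0] ** 2 + pos[:, 1] ** 2 + h**2)
    k = pos / (norm[:, None] * geometry.wavelength_um)
    return k, geometry.labels()


def led_grid(
    n_side: int,
    pitch: float,
    array_height: float,
    wavelength: float,
    objective_na: float,
    hybrid_band: float = 0.02,
    max_radius: float | None = None,
) -> IlluminationGeometry:
    """Square LED grid centred on the optical axis.

    Parameters
    ----------
    n_side : int
        LEDs per side (odd values place one LED on-axis).
    pitch : float
        LED spacing in millimetres.
    max_radius : float, optional
        Keep only LEDs within this lateral radius (mm) — selects a filled
        circle from the square array, as in typical FPM hardware.
    """
    if n_side < 1:
        raise InvalidGeometryError("n_side must be >= 1")
    half = (n_side - 1) / 2.0
    coords = (np.arange(n_side) - half) * pitch
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    pos = np.column_stack([xx.ravel(), yy.ravel()])
    if max_radius is not None:
        pos = pos[np.hypot(pos[:, 0], pos[:, 1]) <= max_radius]
    # stable center-out order: sort by lateral radius (ascending illumination NA)
    order = np.argsort(np.hypot(pos[:, 0], pos[:, 1]), kind="stable")
    return IlluminationGeometry(
        led_positions=pos[order],
        array_height=array_height,
        wavelength=wavelength,
        objective_na=objective_na,
        hybrid_band=hybrid_band,
    )
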