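"""TIFF / JSON artifact I/O.

Stacks travel as multi-page 32-bit float TIFF, frame order = LED index
order, with a JSON sidecar (same stem, ``.json``) holding role, per-frame
LED index, BF/DF/HYBRID labels and, when available, LED positions.  Complex
objects and reconstructions are two-page TIFFs (amplitude, phase) with a
JSON sidecar for pixel size and reconstruction metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .datatypes import ComplexObject, ImageStack
from .geometry import IlluminationGeometry
from .recon import ReconResult


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_stack(
    path: str | Path, stack: ImageStack, geometry: IlluminationGeometry | None = None
) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {
        "role": stack.role,
        "led_index": [int(i) for i in stack.led_index],
        "labels": list(stack.labels),
    }
    if geometry is not None:
        meta["led_positions_mm"] = [
            [float(x), float(y)] for x, y in geometry.led_positions
        ]
        meta["array_height_mm"] = float(geometry.array_height)
        meta["wavelength_nm"] = float(geometry.wavelength)
        meta["objective_na"] = float(geometry.objective_na)
        meta["hybrid_band"] = float(geometry.hybrid_band)
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_stack(path: str | Path) -> tuple[ImageStack, dict]:
    """Read a stack and its sidecar metadata dict."""
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(_sidecar(path).read_text())
    stack = ImageStack(
        frames=frames,
        led_index=np.asarray(meta["led_index"], dtype=int),
        role=meta["role"],
        labels=meta["labels"],
    )
    return stack, meta


def geometry_from_meta(meta: dict) -> IlluminationGeometry:
    return IlluminationGeometry(
        led_positions=np.asarray(meta["led_positions_mm"], dtype=float),
        array_height=meta["array_height_mm"],
        wavelength=meta["wavelength_nm"],
        objective_na=meta["objective_na"],
        hybrid_band=meta.get("hybrid_band", 0.02),
    )


def save_object(path: str | Path, obj: ComplexObject) -> None:
    path = Path(path)
    pages = np.stack([obj.amplitude, obj.phase]).astype(np.float32)
    tifffile.imwrite(path, pages)
    _sidecar(path).write_text(
        json.dumps({"pixel_size_um": float(obj.pixel_size), "pages": ["amplitude", "phase"]})
    )


def load_object(path: str | Path) -> ComplexObject:
    path = Path(path)
    pages = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(_sidecar(path).read_text())
    return ComplexObject(
        amplitude=pages[0], phase=pages[1], pixel_size=meta["pixel_size_um"]
    )


def save_recon(path: str | Path, result: ReconResult) -> None:
    path = Path(path)
    pages = np.stack([result.amplitude, result.phase]).astype(np.float32)
    tifffile.imwrite(path, pages)
    _sidecar(path).write_text(
        json.dumps(
            {
                "pages": ["amplitude", "phase"],
                "synthetic_na": float(result.synthetic_na),
                "pixel_size_um": float(result.pixel_size),
                "per_iteration_residual": [
                    float(v) for v in result.per_iteration_residual
                ],
            },
            indent=1,
        )
    )


def save_maps(path: str | Path, M: np.ndarray, I_BF: np.ndarray, I_DF: np.ndarray) -> None:
    """SdA maps as a three-page TIFF (M, I_BF, I_DF)."""
    pages = np.stack(
        [M.astype(np.float32), I_BF.astype(np.float32), np.asarray(I_DF, dtype=np.float32)]
    )
    tifffile.imwrite(Path(path), pages)
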