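"""Focal-stack container and TIFF round-trip IO.

A focal stack is a 3D intensity volume, axis order (z, y, x), tagged with its
units — raw camera digital numbers ("DN") or gain-normalized photoelectrons
("e-") — and the voxel geometry.  Volumes are written as 32-bit float
multi-page TIFF with a JSON sidecar carrying the metadata TIFF does not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["FocalStack", "read_stack", "write_stack", "export_8bit"]

UNITS_DN = "DN"
UNITS_E = "e-"


@dataclass
class FocalStack:
    """3D intensity volume with unit tag and voxel geometry."""

    values: np.ndarray
    units: str = UNITS_DN
    dxy_nm: float | None = None
    dz_nm: float | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_3d(np.asarray(self.values))
        if self.values.ndim != 3:
            raise ValueError("focal stack must be 3D (z, y, x)")
        if self.units not in (UNITS_DN, UNITS_E):
            raise ValueError(f"unknown unit tag {self.units!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, units: str | None = None) -> "FocalStack":
        return replace(self, values=values, units=self.units if units is None else units)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path: str | Path, stack: FocalStack, extra: dict | None = None) -> None:
    """Write a stack as float32 multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.values.astype(np.float32), photometric="minisblack")
    meta = {
        "units": stack.units,
        "dxy_nm": stack.dxy_nm,
        "dz_nm": stack.dz_nm,
        "shape": list(stack.values.shape),
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_stack(path: str | Path, units: str | None = None) -> FocalStack:
    """Read a grayscale multi-page TIFF as a focal stack.

    A single page becomes a volume with nz = 1.  Metadata is restored from
    the JSON sidecar when present; an explicit ``units`` argument overrides.
    """
    path = Path(path)
    values = tifffile.imread(path)
    values = np.asarray(values)
    if values.ndim == 2:
        values = values[None]
    if values.ndim != 3:
        raise ValueError(
            f"{path} is not a grayscale z-stack (got array of shape {values.shape})"
        )
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return FocalStack(
        values=values,
        units=units or meta.get("units", UNITS_DN),
        dxy_nm=meta.get("dxy_nm"),
        dz_nm=meta.get("dz_nm"),
    )


def export_8bit(volume: np.ndarray, saturate_frac: float = 0.01) -> np.ndarray:
    """Scale a volume to uint8 for visualization.

    ``saturate_frac`` of the pixels are saturated in total, split evenly
    between black (0) and white (255).
    """
    v = np.asarray(volume, dtype=float)
    lo = np.quantile(v, saturate_frac / 2.0)
    hi = np.quantile(v, 1.0 - saturate_frac / 2.0)
    if hi <= lo:
        return np.zeros_like(v, dtype=np.uint8)
    out = np.clip((v - lo) / (hi - lo) * 255.0, 0.0, 255.0)
    return np.round(out).astype(np.uint8)
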