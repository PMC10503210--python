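"""Minimal 3D volume container used throughout the pipeline.

A :class:`Volume` is a 3D scalar grid with physical spacing and origin.
Axis order is fixed as (x, y, z) with axial slices stacked along the last
axis, matching the multi-station acquisition (stations are slabs of z).
NIfTI-1 serialisation is delegated to nibabel; the affine is diagonal
(RAS-aligned), which is all the synthetic pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import nibabel as nib
import numpy as np

__all__ = ["Volume", "DWISeries"]


@dataclass(frozen=True)
class Volume:
    """A 3D scalar grid with physical geometry.

    Parameters
    ----------
    values : numpy.ndarray
        3D array, axis order (x, y, z); slices along z.
    spacing : tuple of float
        Voxel size (dx, dy, dz) in mm; all positive.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"Volume requires a 3D array, got ndim={arr.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    # -- geometry -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of a single voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def same_grid(self, other: "Volume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_values(self, values: np.ndarray) -> "Volume":
        """Return a new Volume on this grid holding ``values``."""
        return replace(self, values=np.asarray(values))

    def astype(self, dtype) -> "Volume":
        return self.with_values(self.values.astype(dtype))

    # -- NIfTI I/O ------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(np.asarray(self.values), affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected 3D NIfTI, got shape {data.shape}")
        zooms = img.header.get_zooms()[:3]
        origin = tuple(np.asarray(img.affine)[:3, 3])
        return cls(values=np.asarray(data), spacing=tuple(zooms), origin=origin)


def _check_shared_grid(volumes: Mapping[float, Volume]) -> None:
    vols = list(volumes.values())
    for v in vols[1:]:
        if not vols[0].same_grid(v):
            raise ValueError("all members of a DWISeries must share one grid")


@dataclass(frozen=True)
class DWISeries:
    """Co-registered diffusion-weighted volumes indexed by b-value (s/mm^2)."""

    volumes: dict[float, Volume] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[float, Volume] = {}
        for b, vol in self.volumes.items():
            b = float(b)
            if b < 0:
                raise ValueError(f"b-values must be >= 0, got {b}")
            if b in cleaned:
                raise ValueError(f"duplicate b-value {b}")
            cleaned[b] = vol
        _check_shared_grid(cleaned)
        object.__setattr__(self, "volumes", dict(sorted(cleaned.items())))

    @property
    def bvalues(self) -> list[float]:
        return list(self.volumes.keys())

    @property
    def grid(self) -> Volume:
        """An arbitrary member volume, used as grid reference."""
        return next(iter(self.volumes.values()))

    def __getitem__(self, b: float) -> Volume:
        return self.volumes[float(b)]

    def __contains__(self, b: float) -> bool:
        return float(b) in self.volumes

    def __iter__(self) -> Iterator[float]:
        return iter(self.volumes)

    def to_directory(self, out_dir: str | Path, prefix: str = "dwi") -> list[Path]:
        """Write one NIfTI per b-value plus an FSL-style ``.bval`` sidecar."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for b, vol in self.volumes.items():
            p = out_dir / f"{prefix}_b{int(round(b))}.nii.gz"
            vol.to_nifti(p)
            paths.append(p)
        (out_dir / f"{prefix}.bval").write_text(
            " ".join(str(int(round(b))) for b in self.bvalues) + "\n"
        )
        return paths
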