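"""3-D scalar volumes with physical geometry.

A :class:`Volume` is the universal image currency of the package: a 3-D
scalar grid together with a NIfTI-style 4x4 voxel-to-world affine.  World
coordinates are millimetres; the x axis is oriented so that positive world
x is the subject's Right (and negative x the Left) — the convention every
side call in the package relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume", "read_volume", "write_volume"]


@dataclass
class Volume:
    """A 3-D scalar grid with voxel-to-world geometry.

    Parameters
    ----------
    data
        3-D array of voxel values (any float or integer dtype).
    affine
        4x4 voxel-index -> world-mm affine, NIfTI convention.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.data.ndim}-D")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("volume contains NaN/Inf voxels")
        if (self.spacing <= 0).any():
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm per axis (norms of the affine columns)."""
        return np.asarray(nib.affines.voxel_sizes(self.affine))

    @property
    def origin(self) -> np.ndarray:
        """World coordinate (mm) of voxel (0, 0, 0)."""
        return self.affine[:3, 3].copy()

    @property
    def axis_codes(self) -> tuple[str, str, str]:
        """Anatomical orientation codes, e.g. ``('R', 'A', 'S')``."""
        return nib.aff2axcodes(self.affine)

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to world mm."""
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_grid(self, other: "Volume", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def with_data(self, data: np.ndarray) -> "Volume":
        """A new volume on this grid holding ``data``."""
        return Volume(np.asarray(data), self.affine.copy())

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())


def read_volume(path) -> Volume:
    """Read a single-file NIfTI-1 image as a :class:`Volume`.

    Rejects non-3-D images and images containing NaN/Inf voxels.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D image at {path}")
    if np.issubdtype(data.dtype, np.floating) and not np.isfinite(data).all():
        raise ValueError(f"volume at {path} contains NaN/Inf voxels")
    return Volume(data, np.asarray(img.affine))


def write_volume(vol: Volume, path) -> None:
    """Write a :class:`Volume` as single-file NIfTI-1, preserving dtype."""
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_data_dtype(vol.data.dtype)
    nib.save(img, str(path))
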