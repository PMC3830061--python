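"""Core in-memory containers: scalar volumes, label maps, sampling grids.

World coordinates are RAS millimetres.  A volume is a 3-D array plus a 4x4
voxel-to-world affine; phantom and halfway grids use diagonal affines
(axis-aligned, positive spacing) but externally loaded images may carry an
arbitrary orthogonal direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ImageVolume",
    "LabelMap",
    "Labels",
    "same_grid",
]


class Labels:
    """Integer tissue codes shared by every label map in the package."""

    BG = 0
    CSF = 1
    GM = 2
    WM = 3
    LESION = 4
    SKULL = 5


@dataclass
class ImageVolume:
    """3-D scalar intensity grid with voxel spacing and voxel-to-world affine.

    Parameters
    ----------
    data
        3-D array of intensities (float) or labels (int).
    affine
        4x4 voxel-index -> world (mm) homogeneous matrix.
    valid
        Optional boolean array flagging voxels observed in the original
        field of view; ``None`` means all voxels are valid.
    """

    data: np.ndarray
    affine: np.ndarray
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D data, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape:
                raise ValueError("validity mask shape mismatch")

    # -- grid geometry -------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Millimetres per voxel along each array axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_extent(self) -> np.ndarray:
        """Bounding box of voxel centers in world mm, shape (2, 3)."""
        corners = np.array(
            [[i, j, k] for i in (0, self.shape[0] - 1)
             for j in (0, self.shape[1] - 1)
             for k in (0, self.shape[2] - 1)],
            dtype=float,
        )
        w = self.voxel_to_world(corners)
        return np.stack([w.min(axis=0), w.max(axis=0)])

    def center_world(self) -> np.ndarray:
        """World coordinates of the grid center."""
        c = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.voxel_to_world(c)

    # -- convenience ---------------------------------------------------
    def like(self, data: np.ndarray, valid: str | np.ndarray | None = "keep") -> "ImageVolume":
        """New volume on this grid.  ``valid='keep'`` copies the validity mask."""
        if isinstance(valid, str) and valid == "keep":
            v = None if self.valid is None else self.valid.copy()
        else:
            v = valid
        return ImageVolume(np.asarray(data), self.affine.copy(), v)

    def copy(self) -> "ImageVolume":
        return ImageVolume(
            self.data.copy(), self.affine.copy(),
            None if self.valid is None else self.valid.copy(),
        )

    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.shape, dtype=bool)
        return self.valid


class LabelMap(ImageVolume):
    """Integer tissue labels sharing an :class:`ImageVolume` grid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = np.rint(self.data).astype(np.int16)

    def mask(self, *labels: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given labels."""
        return np.isin(self.data, labels)

    def brain_mask(self) -> np.ndarray:
        """CSF + GM + WM + lesion (everything inside the skull)."""
        return self.mask(Labels.CSF, Labels.GM, Labels.WM, Labels.LESION)

    def like_labels(self, data: np.ndarray) -> "LabelMap":
        return LabelMap(np.asarray(data), self.affine.copy(),
                        None if self.valid is None else self.valid.copy())


def same_grid(a: ImageVolume, b: ImageVolume, tol: float = 1e-6) -> bool:
    """True when two volumes share shape and affine (within ``tol``)."""
    return a.shape == b.shape and bool(np.allclose(a.affine, b.affine, atol=tol))
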