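"""Dense displacement fields on a named grid (halfway space by convention)."""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import nibabel as nib
import numpy as np
import scipy.ndimage as ndi

from .image import ImageVolume

__all__ = ["DisplacementField", "load_external_field", "save_field"]


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacement (mm, world axes) on a reference grid.

    ``vectors`` has shape ``grid.shape + (3,)``.  ``direction`` records which
    way the field maps ("baseline->followup" or "followup->baseline").
    Interpreted as the mapping ``x -> x + u(x)`` in world coordinates.
    """

    vectors: np.ndarray
    grid: ImageVolume
    direction: str = "baseline->followup"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.vectors.shape != tuple(self.grid.shape) + (3,):
            raise ValueError(
                f"field shape {self.vectors.shape} does not match grid "
                f"{self.grid.shape} + (3,)"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")

    @classmethod
    def zeros(cls, grid: ImageVolume, direction: str = "baseline->followup"):
        return cls(np.zeros(tuple(grid.shape) + (3,), dtype=np.float32), grid, direction)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def sample_world(self, xyz: np.ndarray) -> np.ndarray:
        """Linearly interpolate the field at world positions (n, 3) -> (n, 3)."""
        vox = self.grid.world_to_voxel(xyz).T  # (3, n)
        out = np.empty((xyz.shape[0], 3), dtype=np.float32)
        for c in range(3):
            out[:, c] = ndi.map_coordinates(self.vectors[..., c], vox, order=1,
                                            mode="nearest")
        return out


def save_field(field: DisplacementField, path) -> None:
    """Write as 4-D NIfTI (x, y, z, 3), vectors in mm along world axes."""
    img = nib.Nifti1Image(np.asarray(field.vectors, dtype=np.float32), field.grid.affine)
    img.header["descrip"] = field.direction.encode()[:79]
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def load_external_field(path) -> DisplacementField:
    """Read a displacement field written by this package or an external tool.

    Expects a 4-D NIfTI whose last axis holds 3-vectors in mm (world axes);
    a trailing singleton time axis (x,y,z,1,3) is squeezed.  Lets users plug
    in fields computed by an external registrar in place of the in-repo one.
    """
    from .io import FormatError

    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(
            f"{path}: expected a 4-D displacement field with a final axis of "
            f"length 3, got shape {data.shape}"
        )
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: field contains non-finite values")
    grid = ImageVolume(np.zeros(data.shape[:3], dtype=np.float32),
                       np.asarray(img.affine, dtype=float))
    direction = str(img.header["descrip"].tobytes().decode(errors="ignore")).strip("\x00")
    return DisplacementField(np.asarray(data, dtype=np.float32), grid,
                             direction or "baseline->followup")
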