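"""NIfTI-1 volume input/output and ASCII transform files."""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .image import ImageVolume, LabelMap

__all__ = ["read_nifti", "write_nifti", "read_labels", "FormatError"]


class FormatError(ValueError):
    """Raised when an on-disk file does not match the expected format."""


def read_nifti(path: str | os.PathLike, labels: bool = False) -> ImageVolume:
    """Load a 3-D NIfTI-1 volume (.nii or .nii.gz).

    Parameters
    ----------
    labels
        When True return a :class:`LabelMap` (integer data).

    Raises
    ------
    FormatError
        If the file is not NIfTI or is not 3-D.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3-D volume, got dimensionality {data.ndim} "
            "(displacement fields go through the field reader)"
        )
    affine = np.asarray(img.affine, dtype=float)
    cls = LabelMap if labels else ImageVolume
    return cls(data, affine)


def read_labels(path: str | os.PathLike) -> LabelMap:
    return read_nifti(path, labels=True)


def write_nifti(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1; gzip chosen by the .gz suffix."""
    data = volume.data
    if isinstance(volume, LabelMap):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
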