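"""Symmetric dense nonlinear registration of two halfway-space images.

A multi-resolution demons-style registrar in which both images carry half of
the deformation: the baseline image is warped by ``+v`` and the follow-up by
``-v``, and the update reduces their intensity mismatch at the midpoint.
This makes the output antisymmetric under swapping the inputs by
construction.  The full baseline-to-followup map is recovered by composing
the two half-maps: ``T = (I - v) o (I + v)^{-1} = I + 2 * inv(v)``.

An external registrar's field can be substituted through
:func:`load_external_field`; everything downstream consumes the same
:class:`DisplacementField` type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.ndimage as ndi

from .field import DisplacementField, load_external_field, save_field
from .image import ImageVolume, same_grid

__all__ = [
    "DemonsParams",
    "symmetric_register",
    "compose_fields",
    "invert_field",
    "load_external_field",
    "save_field",
]


@dataclass
class DemonsParams:
    """Tunables of the symmetric demons registrar.

    ``levels`` downsampling factors coarse-to-fine; ``field_sigma_mm`` the
    elastic (field) Gaussian regularization applied every iteration;
    ``update_sigma_mm`` the fluid smoothing of each update; ``iters`` per
    level; ``step`` scales the normalized demons update; ``presmooth_mm``
    smooths the intensity images before matching.
    """

    levels: tuple = (1,)
    field_sigma_mm: float = 0.8
    update_sigma_mm: float = 1.0
    iters: int = 50
    step: float = 1.0
    presmooth_mm: float = 1.5


def _warp(img: np.ndarray, disp_vox: np.ndarray, base_idx: np.ndarray) -> np.ndarray:
    coords = base_idx + np.moveaxis(disp_vox, -1, 0)
    return ndi.map_coordinates(img, coords, order=1, mode="nearest")


def _downsample(img: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return img
    sm = ndi.gaussian_filter(img, 0.5 * f)
    return sm[::f, ::f, ::f]


def symmetric_register(
    half_baseline: ImageVolume,
    half_followup: ImageVolume,
    params: Optional[DemonsParams] = None,
    mask: Optional[np.ndarray] = None,
) -> tuple[DisplacementField, DisplacementField]:
    """Register the two halfway-resampled images symmetrically.

    Returns ``(fwd, bwd)`` displacement fields (mm, world axes) on the
    halfway grid mapping baseline->followup and followup->baseline
    coordinates respectively.  The mean squared intensity difference is
    tracked per level and must not increase from level to level; a
    non-positive Jacobian determinant inside ``mask`` raises (the
    regularization is then too weak for the data).
    """
    params = params or DemonsParams()
    if not same_grid(half_baseline, half_followup):
        raise ValueError("halfway images must share one grid")
    spacing = half_baseline.spacing
    if not np.allclose(spacing, spacing[0], rtol=1e-3):
        raise ValueError("halfway grid must be isotropic")
    h = float(spacing[0])

    B = np.asarray(half_baseline.data, dtype=np.float32)
    F = np.asarray(half_followup.data, dtype=np.float32)
    # joint robust normalization to [0, 1]
    hi_val = float(np.percentile(np.concatenate([B.ravel(), F.ravel()]), 99.5))
    if hi_val <= 0:
        raise ValueError("images are empty")
    B = np.clip(B / hi_val, 0, 1.2)
    F = np.clip(F / hi_val, 0, 1.2)
    if params.presmooth_mm > 0:
        s = params.presmooth_mm / h
        B = ndi.gaussian_filter(B, s)
        F = ndi.gaussian_filter(F, s)

    v = None  # half-displacement, mm
    msd_per_level = []
    for f in params.levels:
        Bl = _downsample(B, f)
        Fl = _downsample(F, f)
        hl = h * f
        shape = Bl.shape
        base_idx = np.indices(shape, dtype=np.float32)
        if v is None:
            v = np.zeros(shape + (3,), dtype=np.float32)
        else:
            zoom = [s / vs for s, vs in zip(shape, v.shape[:3])]
            v = np.stack([ndi.zoom(v[..., c], zoom, order=1) for c in range(3)],
                         axis=-1).astype(np.float32)
        sig_f = params.field_sigma_mm / hl
        sig_u = params.update_sigma_mm / hl
        for _ in range(params.iters):
            vv = v / hl
            Bw = _warp(Bl, vv, base_idx)
            Fw = _warp(Fl, -vv, base_idx)
            diff = Fw - Bw
            gB = np.gradient(Bw, hl)
            gF = np.gradient(Fw, hl)
            gx = 0.5 * (gB[0] + gF[0])
            gy = 0.5 * (gB[1] + gF[1])
            gz = 0.5 * (gB[2] + gF[2])
            g2 = gx * gx + gy * gy + gz * gz
            denom = g2 + (diff * diff) / (hl * hl)
            with np.errstate(invalid="ignore", divide="ignore"):
                w = np.where(denom > 1e-12, diff / denom, 0.0)
            delta = np.stack([w * gx, w * gy, w * gz], axis=-1)
            if sig_u > 0.2:
                for c in range(3):
                    delta[..., c] = ndi.gaussian_filter(delta[..., c], sig_u)
            v = v + (0.5 * params.step) * delta
            if sig_f > 0.2:
                for c in range(3):
                    v[..., c] = ndi.gaussian_filter(v[..., c], sig_f)
        vv = v / hl
        msd = float(np.mean((_warp(Fl, -vv, base_idx) - _warp(Bl, vv, base_idx)) ** 2))
        msd_per_level.append(msd)

    # full-resolution half field on the input grid
    if v.shape[:3] != B.shape:
        zoom = [s / vs for s, vs in zip(B.shape, v.shape[:3])]
        v = np.stack([ndi.zoom(v[..., c], zoom, order=1) for c in range(3)],
                     axis=-1).astype(np.float32)

    q_f = _invert_perturbation(v, h)          # q = -v(I + q)
    q_b = _invert_perturbation(-v, h)
    fwd = DisplacementField(2.0 * q_f, half_baseline, "baseline->followup")
    bwd = DisplacementField(2.0 * q_b, half_baseline, "followup->baseline")
    fwd.msd_per_level = msd_per_level
    bwd.msd_per_level = msd_per_level

    from .jacobian import jacobian_determinant  # local import avoids a cycle
    if mask is not None and mask.any():
        dj = jacobian_determinant(fwd).data
        if np.any(dj[mask] <= 0):
            raise RuntimeError(
                "non-positive Jacobian determinant inside the mask: "
                "increase field_sigma_mm or reduce step")
    return fwd, bwd


def _invert_perturbation(v: np.ndarray, h, iters: int = 10) -> np.ndarray:
    """Solve q(y) = -v(y + q(y)) by fixed point (displacements in mm)."""
    h = np.asarray(h, dtype=np.float32).reshape(1, 1, 1, -1)
    base_idx = np.indices(v.shape[:3], dtype=np.float32)
    q = -v.copy()
    for _ in range(iters):
        qv = q / h
        sampled = np.stack([_warp(v[..., c], qv, base_idx) for c in range(3)], axis=-1)
        q = -sampled
    return q


def invert_field(field: DisplacementField) -> DisplacementField:
    """Numeric inverse of ``x -> x + u(x)`` on the same grid (diagonal affine)."""
    q = _invert_perturbation(field.vectors, field.grid.spacing)
    direction = field.direction
    if "->" in direction:
        a, b = direction.split("->")
        direction = f"{b}->{a}"
    return DisplacementField(q, field.grid, direction)


def compose_fields(f: DisplacementField, g: DisplacementField) -> DisplacementField:
    """Composition ``(f o g)(x) = g(x) + f(x + g(x))``, linear interp of f."""
    if not same_grid(f.grid, g.grid):
        raise ValueError("fields must share one grid")
    h = np.asarray(f.grid.spacing, dtype=np.float32).reshape(1, 1, 1, -1)
    base_idx = np.indices(f.vectors.shape[:3], dtype=np.float32)
    gv = g.vectors / h
    sampled = np.stack([_warp(f.vectors[..., c], gv, base_idx) for c in range(3)],
                       axis=-1)
    return DisplacementField(g.vectors + sampled, f.grid, f.direction)
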