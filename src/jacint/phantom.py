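"""Synthetic longitudinal brain phantoms with analytically known deformations.

The phantom is a nested-ellipsoid head: skull shell, CSF layer, cortical
gray-matter ribbon, white-matter core and central CSF ventricle, each with a
Gaussian T1-like intensity (CSF < GM < WM).  Atrophy is applied as an
analytic deformation whose Jacobian determinant is known in closed form, so
every stage of the measurement pipeline can be checked against ground truth
without any acquired data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from typing import Optional, Sequence

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import brentq

from .field import DisplacementField
from .image import ImageVolume, LabelMap, Labels
from .linreg import AffineTransform, make_affine, make_grid, resample

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "apply_atrophy",
    "apply_miscalibration",
    "add_bias_field",
    "add_noise",
    "insert_lesions",
    "degrade_resolution",
    "make_pair",
]


@dataclass
class PhantomSpec:
    """Geometry, intensity and noise parameters of a synthetic head.

    Ellipsoid sizes are fractions: ``brain_axes_frac`` scales the half-extent
    of the field of view per axis (outer cortical surface); the remaining
    fractions are relative to the brain ellipsoid.
    """

    shape: tuple = (96, 96, 96)
    spacing: tuple = (1.0, 1.0, 1.0)          # mm, emulating 1 mm isotropic T1
    intensity_means: dict = dfield(default_factory=lambda: {
        Labels.CSF: 30.0, Labels.GM: 70.0, Labels.WM: 100.0, Labels.SKULL: 90.0})
    intensity_sds: dict = dfield(default_factory=lambda: {
        Labels.CSF: 0.0, Labels.GM: 0.0, Labels.WM: 0.0, Labels.SKULL: 0.0})
    brain_axes_frac: tuple = (0.60, 0.70, 0.64)
    wm_frac: float = 0.75
    ventricle_frac: float = 0.22
    csf_frac: float = 1.22
    skull_inner_frac: float = 1.26
    skull_outer_frac: float = 1.36
    lesion_count: int = 0
    lesion_radius_mm: tuple = (2.0, 4.0)
    lesion_intensity_factor: float = 0.7
    bias_amplitude: float = 0.0               # multiplicative, unitless
    bias_scale_mm: float = 40.0
    noise_sd: float = 0.0                     # additive, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.spacing) <= 0):
            raise ValueError("spacing must be positive")
        if min(self.shape) < 32:
            raise ValueError("phantom grid must be at least 32^3 voxels")
        m = self.intensity_means
        if not (m[Labels.CSF] < m[Labels.GM] < m[Labels.WM]):
            raise ValueError("T1-like intensities require CSF < GM < WM")

    def brain_semiaxes_mm(self) -> np.ndarray:
        half_extent = np.asarray(self.shape) * np.asarray(self.spacing) / 2.0
        return np.asarray(self.brain_axes_frac) * half_extent


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a synthetic longitudinal pair."""

    mode: str = "none"
    affine: Optional[AffineTransform] = None       # applied inter-timepoint affine
    field_params: dict = dfield(default_factory=dict)
    true_pvc: dict = dfield(default_factory=dict)  # per tissue label, percent
    bias_fields: dict = dfield(default_factory=dict)  # timepoint -> ndarray
    field: Optional[DisplacementField] = None      # forward baseline->followup

    def detj(self, grid: ImageVolume) -> np.ndarray:
        """Closed-form Jacobian determinant of the applied field on ``grid``."""
        return _analytic_detj(self.mode, self.field_params, grid)

    def to_json(self, path) -> None:
        d = {
            "mode": self.mode,
            "affine": None if self.affine is None else self.affine.matrix.tolist(),
            "field_params": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                             for k, v in self.field_params.items()},
            "true_pvc": {str(k): float(v) for k, v in self.true_pvc.items()},
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


# ----------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------

def _label_array(spec: PhantomSpec, grid: ImageVolume) -> np.ndarray:
    """Evaluate the nested-ellipsoid inequalities at every voxel center."""
    idx = np.indices(spec.shape, dtype=np.float64)
    xyz = np.moveaxis(idx, 0, -1).reshape(-1, 3)
    world = grid.voxel_to_world(xyz)
    c = grid.center_world()
    b = spec.brain_semiaxes_mm()
    z = (world - c) / b
    r = np.linalg.norm(z, axis=1)
    rv = np.linalg.norm(z / spec.ventricle_frac, axis=1)

    lab = np.zeros(r.shape, dtype=np.int16)
    lab[r <= spec.skull_outer_frac] = Labels.SKULL
    lab[r <= spec.skull_inner_frac] = Labels.CSF  # subarachnoid CSF layer
    lab[r <= 1.0] = Labels.GM
    lab[r <= spec.wm_frac] = Labels.WM
    lab[rv <= 1.0] = Labels.CSF                   # central ventricle
    return lab.reshape(spec.shape)


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelMap]:
    """Build the baseline image and label map for a phantom specification.

    Voxel intensities are per-tissue Gaussian draws (``intensity_sds``); with
    all SDs zero every voxel carries exactly its tissue mean.  The same seed
    always yields bit-identical volumes.
    """
    grid = make_grid(spec.shape, spec.spacing)
    lab = _label_array(spec, grid)
    rng = np.random.default_rng(spec.seed)
    img = np.zeros(spec.shape, dtype=np.float32)
    for label, mean in spec.intensity_means.items():
        m = lab == label
        sd = spec.intensity_sds.get(label, 0.0)
        if sd > 0:
            img[m] = rng.normal(mean, sd, size=int(m.sum()))
        else:
            img[m] = mean
    labels = LabelMap(lab, grid.affine.copy())
    return ImageVolume(img, grid.affine.copy()), labels


# ----------------------------------------------------------------------
# analytic atrophy fields
# ----------------------------------------------------------------------

def _radial_profile(r: np.ndarray, r0: float, rp: float,
                    r1: float) -> tuple[np.ndarray, np.ndarray]:
    """Compact-support C^1 bump rising from r0, peaking at rp, zero at r1.

    ``w = sin^2(pi/2 (r-r0)/(rp-r0))`` on the rise and
    ``cos^2(pi/2 (r-rp)/(r1-rp))`` on the fall; zero displacement (and zero
    slope) at r0 and r1 keeps the WM core and the skull static while the
    GM/CSF boundary moves inward.
    """
    w = np.zeros_like(r)
    dw = np.zeros_like(r)
    up = (r > r0) & (r <= rp)
    t = (r[up] - r0) / (rp - r0)
    w[up] = np.sin(0.5 * np.pi * t) ** 2
    dw[up] = (np.pi / (rp - r0)) * np.sin(0.5 * np.pi * t) * np.cos(0.5 * np.pi * t)
    dn = (r > rp) & (r < r1)
    t = (r[dn] - rp) / (r1 - rp)
    w[dn] = np.cos(0.5 * np.pi * t) ** 2
    dw[dn] = -(np.pi / (r1 - rp)) * np.sin(0.5 * np.pi * t) * np.cos(0.5 * np.pi * t)
    return w, dw


def _z_coords(params: dict, grid: ImageVolume) -> tuple[np.ndarray, np.ndarray]:
    idx = np.indices(grid.shape, dtype=np.float64)
    xyz = np.moveaxis(idx, 0, -1).reshape(-1, 3)
    world = grid.voxel_to_world(xyz)
    z = (world - np.asarray(params["center"])) / np.asarray(params["semiaxes"])
    return world, z


def _analytic_detj(mode: str, params: dict, grid: ImageVolume) -> np.ndarray:
    if mode == "none":
        return np.ones(grid.shape)
    if mode == "global_scale":
        return np.full(grid.shape, float(params["scale"]) ** 3)
    if mode == "radial_gm":
        _, z = _z_coords(params, grid)
        r = np.linalg.norm(z, axis=1)
        beta, r0, rp, r1 = (params["beta"], params["r0"], params["rp"], params["r1"])
        w, dw = _radial_profile(r, r0, rp, r1)
        h = r - beta * w
        hp = 1.0 - beta * dw
        with np.errstate(invalid="ignore", divide="ignore"):
            detj = hp * (h / r) ** 2
        detj[r == 0] = 1.0
        return detj.reshape(grid.shape)
    raise ValueError(f"unknown atrophy mode {mode!r}")


def _forward_displacement(mode: str, params: dict, grid: ImageVolume) -> np.ndarray:
    """Forward field u with baseline -> followup map x + u(x), in mm."""
    world, z = _z_coords(params, grid)
    if mode == "global_scale":
        s = float(params["scale"])
        u = (s - 1.0) * (world - np.asarray(params["center"]))
    elif mode == "radial_gm":
        r = np.linalg.norm(z, axis=1)
        beta, r0, rp, r1 = (params["beta"], params["r0"], params["rp"], params["r1"])
        w, _ = _radial_profile(r, r0, rp, r1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fac = np.where(r > 0, -beta * w / r, 0.0)
        u = fac[:, None] * z * np.asarray(params["semiaxes"])
    else:
        raise ValueError(f"unknown atrophy mode {mode!r}")
    return u.reshape(tuple(grid.shape) + (3,)).astype(np.float32)


def _inverse_displacement(mode: str, params: dict, grid: ImageVolume) -> np.ndarray:
    """Pull-back field v with followup(y) = baseline(y + v(y)), in mm."""
    world, zy = _z_coords(params, grid)
    c = np.asarray(params["center"])
    if mode == "global_scale":
        s = float(params["scale"])
        v = (1.0 / s - 1.0) * (world - c)
    elif mode == "radial_gm":
        ry = np.linalg.norm(zy, axis=1)
        beta, r0, rp, r1 = (params["beta"], params["r0"], params["rp"], params["r1"])
        # solve h(r) = ry for r by Newton iteration (h monotone)
        r = ry.copy()
        for _ in range(30):
            w, dw = _radial_profile(r, r0, rp, r1)
            f = r - beta * w - ry
            fp = 1.0 - beta * dw
            r = r - f / fp
        with np.errstate(invalid="ignore", divide="ignore"):
            fac = np.where(ry > 0, r / ry - 1.0, 0.0)
        v = fac[:, None] * zy * np.asarray(params["semiaxes"])
    else:
        raise ValueError(f"unknown atrophy mode {mode!r}")
    return v.reshape(tuple(grid.shape) + (3,)).astype(np.float32)


def apply_atrophy(
    image: ImageVolume,
    labels: LabelMap,
    target_pvc: float,
    mode: str = "radial_gm",
    spec: Optional[PhantomSpec] = None,
) -> tuple[ImageVolume, DisplacementField, PhantomTruth]:
    """Deform the phantom by a known field hitting ``target_pvc`` in the GM.

    ``global_scale`` applies the uniform scale ``s = (1+pvc/100)^(1/3)``
    about the head center (detJ constant everywhere); ``radial_gm`` applies
    a smooth compact-support radial contraction whose analytic Jacobian
    integral over the GM label is calibrated numerically to the target
    within 0.05 percentage points.  Returns the follow-up image (baseline
    resampled through the exact inverse map), the forward displacement
    field (baseline -> followup, mm) and the ground truth.
    """
    if not -50.0 <= target_pvc <= 50.0:
        raise ValueError("target_pvc must lie in [-50, 50]")
    if mode not in ("global_scale", "radial_gm"):
        raise ValueError(f"unknown atrophy mode {mode!r}")
    spec = spec or PhantomSpec(shape=image.shape,
                               spacing=tuple(image.spacing))
    grid = image
    center = grid.center_world()
    params: dict = {"center": center, "semiaxes": spec.brain_semiaxes_mm()}

    if mode == "global_scale":
        params["scale"] = (1.0 + target_pvc / 100.0) ** (1.0 / 3.0)
    else:
        gm = labels.mask(Labels.GM)
        # displacement vanishes at the WM/GM boundary and at the skull,
        # peaking at the GM/CSF boundary: GM compresses, CSF expands
        params.update(r0=spec.wm_frac, rp=1.0,
                      r1=min(spec.csf_frac, spec.skull_inner_frac - 0.02))
        target = 1.0 + target_pvc / 100.0

        def mean_detj(beta: float) -> float:
            p = dict(params, beta=beta)
            return float(_analytic_detj("radial_gm", p, grid)[gm].mean())

        if target_pvc == 0:
            beta = 0.0
        else:
            hi = 0.02 if target_pvc < 0 else -0.02
            while np.sign(mean_detj(hi) - target) == np.sign(1.0 - target):
                hi *= 2.0
                if abs(hi) > 0.5:
                    raise RuntimeError("radial field calibration failed to bracket")
            beta = brentq(lambda b: mean_detj(b) - target, 0.0, hi, xtol=1e-12)
        params["beta"] = beta

    truth = PhantomTruth(mode=mode, affine=None, field_params=params)
    for label in (Labels.CSF, Labels.GM, Labels.WM):
        m = labels.mask(label)
        if m.any():
            dj = _analytic_detj(mode, params, grid)[m]
            truth.true_pvc[label] = 100.0 * (float(dj.mean()) - 1.0)

    v = _inverse_displacement(mode, params, grid)
    pullback = DisplacementField(v, grid, direction="followup->baseline")
    followup = resample(image, pullback, grid, interp="windowed_sinc")
    followup.valid = None

    fwd = DisplacementField(_forward_displacement(mode, params, grid), grid,
                            direction="baseline->followup")
    truth.field = fwd
    return followup, fwd, truth


def apply_miscalibration(image: ImageVolume, scale: float | Sequence[float],
                         truth: Optional[PhantomTruth] = None
                         ) -> tuple[ImageVolume, AffineTransform]:
    """Emulate scanner voxel-size miscalibration at the second time-point.

    The image content is rescaled by ``scale`` about the head center, as if
    the follow-up scanner's gradients were calibrated ``scale`` too large.
    Returns the altered image and the applied world affine (the skull-based
    registration should recover its inverse).
    """
    a = make_affine(scale=scale, center=image.center_world())
    out = resample(image, a, image, interp="windowed_sinc")
    out.valid = None
    if truth is not None:
        truth.affine = a
    return out, a


# ----------------------------------------------------------------------
# intensity corruptions
# ----------------------------------------------------------------------

def add_bias_field(image: ImageVolume, amplitude: float, scale_mm: float = 40.0,
                   seed: int = 0) -> ImageVolume:
    """Multiply by exp(smooth zero-mean random field) of the given amplitude.

    The field is white noise low-passed at ``scale_mm`` and renormalized to
    unit SD, so ``amplitude`` is the SD of the log-bias.  The true
    multiplicative field is attached as ``out.true_bias``.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    if amplitude == 0:
        out = image.like(image.data.copy())
        out.true_bias = np.ones(image.shape, dtype=np.float32)
        return out
    sigma_vox = np.asarray(scale_mm) / image.spacing
    g = rng.standard_normal(image.shape)
    g = ndi.gaussian_filter(g, sigma_vox)
    g = (g - g.mean()) / g.std()
    bias = np.exp(amplitude * g).astype(np.float32)
    out = image.like(image.data * bias)
    out.true_bias = bias
    return out


def add_noise(image: ImageVolume, sigma: float, model: str = "gaussian",
              seed: int = 0) -> ImageVolume:
    """Additive Gaussian or Rician magnitude noise of scale ``sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise model {model!r}")
    if sigma == 0:
        return image.like(image.data.copy())
    rng = np.random.default_rng(seed)
    data = np.asarray(image.data, dtype=np.float32)
    if model == "gaussian":
        out = data + rng.normal(0.0, sigma, size=data.shape)
    else:
        n1 = rng.normal(0.0, sigma, size=data.shape)
        n2 = rng.normal(0.0, sigma, size=data.shape)
        out = np.sqrt((data + n1) ** 2 + n2 ** 2)
    return image.like(out.astype(np.float32))


def insert_lesions(image: ImageVolume, labels: LabelMap, n: int,
                   radius_range_mm: tuple = (2.0, 4.0),
                   intensity_factor: float = 0.7, seed: int = 0,
                   max_tries: int = 500) -> tuple[ImageVolume, LabelMap]:
    """Place ``n`` non-overlapping hypointense spherical lesions inside WM."""
    if not 0 < intensity_factor < 1 and n > 0:
        raise ValueError("lesions must be hypointense: 0 < intensity_factor < 1")
    if n == 0:
        return image.like(image.data.copy()), labels.like_labels(labels.data.copy())
    rng = np.random.default_rng(seed)
    wm = labels.mask(Labels.WM)
    idx = np.indices(image.shape, dtype=np.float32)
    world = np.stack([image.voxel_to_world(np.moveaxis(idx, 0, -1).reshape(-1, 3))[:, c]
                      .reshape(image.shape) for c in range(3)])
    wm_idx = np.argwhere(wm)
    placed: list[tuple[np.ndarray, float]] = []
    lab = labels.data.copy()
    img = np.asarray(image.data, dtype=np.float32).copy()
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries * n:
            raise RuntimeError(
                f"could not place {n} non-overlapping lesions inside WM "
                f"after {tries} tries")
        r = rng.uniform(*radius_range_mm)
        c_vox = wm_idx[rng.integers(len(wm_idx))]
        c_world = image.voxel_to_world(c_vox.astype(float))
        if any(np.linalg.norm(c_world - pc) <= r + pr + 1.0 for pc, pr in placed):
            continue
        d2 = sum((world[c] - c_world[c]) ** 2 for c in range(3))
        sphere = d2 <= r ** 2
        if not np.all(wm[sphere]):
            continue
        lab[sphere] = Labels.LESION
        img[sphere] *= intensity_factor
        placed.append((c_world, r))
    return image.like(img), labels.like_labels(lab)


def degrade_resolution(image: ImageVolume, new_spacing: Sequence[float]) -> ImageVolume:
    """Box-average slab downsampling to a coarser (integer-factor) spacing.

    Emulates thick-slice acquisitions (e.g. 1 mm -> 3 mm axial slabs).  The
    mm extent of the volume is preserved to within one slab; upsampling
    requests are rejected.
    """
    new_spacing = np.asarray(new_spacing, dtype=float)
    old = image.spacing
    fac = new_spacing / old
    if np.any(fac < 1 - 1e-9):
        raise ValueError("degrade_resolution cannot upsample")
    ifac = np.rint(fac).astype(int)
    if not np.allclose(fac, ifac, atol=1e-6):
        raise ValueError("new spacing must be an integer multiple of the native spacing")
    data = np.asarray(image.data, dtype=np.float32)
    trim = [s - (s % f) for s, f in zip(data.shape, ifac)]
    data = data[:trim[0], :trim[1], :trim[2]]
    ns = [t // f for t, f in zip(trim, ifac)]
    data = data.reshape(ns[0], ifac[0], ns[1], ifac[1], ns[2], ifac[2]).mean(axis=(1, 3, 5))
    A = image.affine.copy()
    A[:3, :3] = A[:3, :3] @ np.diag(ifac)
    # first output voxel center sits at the mean of its source block
    A[:3, 3] = image.voxel_to_world((np.asarray(ifac, dtype=float) - 1) / 2.0)
    return ImageVolume(data.astype(np.float32), A)


# ----------------------------------------------------------------------
# convenience: full longitudinal pair
# ----------------------------------------------------------------------

def make_pair(spec: PhantomSpec, target_pvc: float, mode: str = "radial_gm",
              miscalibration_scale: float = 1.0
              ) -> tuple[ImageVolume, ImageVolume, LabelMap, PhantomTruth]:
    """Baseline/follow-up pair under the spec's noise, bias and lesion model.

    Applies, in order: lesions (both time-points share the lesion mask),
    analytic atrophy, optional scanner-scale miscalibration of the
    follow-up, then independent bias fields and noise per time-point, all
    seeded from ``spec.seed``.
    """
    base, labels = make_phantom(spec)
    if spec.lesion_count > 0:
        base, labels = insert_lesions(base, labels, spec.lesion_count,
                                      spec.lesion_radius_mm,
                                      spec.lesion_intensity_factor,
                                      seed=spec.seed + 11)
    follow, fwd, truth = apply_atrophy(base, labels, target_pvc, mode=mode, spec=spec)
    if miscalibration_scale != 1.0:
        follow, _ = apply_miscalibration(follow, miscalibration_scale, truth)
    b0 = add_bias_field(base, spec.bias_amplitude, spec.bias_scale_mm, seed=spec.seed + 1)
    b1 = add_bias_field(follow, spec.bias_amplitude, spec.bias_scale_mm, seed=spec.seed + 2)
    truth.bias_fields = {0: b0.true_bias, 1: b1.true_bias}
    out0 = add_noise(b0, spec.noise_sd, seed=spec.seed + 3)
    out1 = add_noise(b1, spec.noise_sd, seed=spec.seed + 4)
    truth.field = fwd
    return out0, out1, labels, truth
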