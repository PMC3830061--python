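"""Affine registration machinery.

Implements the linear half of the longitudinal pipeline: normalized mutual
information (NMI) scoring, staged Nelder-Mead affine registration
(rotations -> translation -> multi-start global scale -> scales+shears),
skull-constrained intra-subject registration in the style of FSL's pairreg,
log-Euclidean matrix averaging for unbiased subject templates, halfway-space
decomposition via the principal matrix square root, and grid resampling
(nearest / linear / windowed-sinc).

Conventions
-----------
An :class:`AffineTransform` maps world coordinates (mm) of the *moving*
image into world coordinates of the *fixed* image.  ``resample(moving, T,
fixed)`` therefore aligns the moving image onto the fixed grid by pulling
back through ``T^{-1}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.ndimage as ndi
from scipy.optimize import minimize

from .image import ImageVolume, LabelMap, same_grid

__all__ = [
    "AffineTransform",
    "RegistrationStagePlan",
    "nmi",
    "symmetry_rotation",
    "hierarchical_affine",
    "pairreg_like",
    "matrix_average",
    "halfway_decompose",
    "concatenate",
    "resample",
    "make_affine",
    "make_grid",
]


# ----------------------------------------------------------------------
# transforms
# ----------------------------------------------------------------------

@dataclass
class AffineTransform:
    """4x4 homogeneous world-to-world matrix (moving -> fixed), det > 0."""

    matrix: np.ndarray
    flags: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-9):
            raise ValueError("bottom row must be (0,0,0,1)")
        if np.linalg.det(self.matrix[:3, :3]) <= 0:
            raise ValueError("linear part must have positive determinant")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def det3(self) -> float:
        return float(np.linalg.det(self.matrix[:3, :3]))

    # ASCII 4-line row-major serialization
    def save(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.17g")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        m = np.loadtxt(path)
        if m.shape != (4, 4):
            raise ValueError(f"{path}: expected a 4x4 ASCII matrix")
        return cls(m)


def concatenate(outer: AffineTransform, inner: AffineTransform) -> AffineTransform:
    """Compose two transforms, applying ``inner`` first."""
    return AffineTransform(outer.matrix @ inner.matrix)


def _rot3(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def make_affine(
    rot: Sequence[float] = (0.0, 0.0, 0.0),
    trans: Sequence[float] = (0.0, 0.0, 0.0),
    scale: float | Sequence[float] = 1.0,
    shear: Sequence[float] = (0.0, 0.0, 0.0),
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> AffineTransform:
    """Build an affine acting about ``center`` (world mm).

    ``rot`` are x/y/z rotations in radians, ``shear`` the (xy, xz, yz)
    off-diagonal terms, ``scale`` a scalar or per-axis triple.
    """
    s = np.asarray([scale] * 3 if np.isscalar(scale) else scale, dtype=float)
    K = np.array([[1.0, shear[0], shear[1]],
                  [0.0, 1.0, shear[2]],
                  [0.0, 0.0, 1.0]])
    L = K @ np.diag(s) @ _rot3(*rot)
    c = np.asarray(center, dtype=float)
    A = np.eye(4)
    A[:3, :3] = L
    A[:3, 3] = c - L @ c + np.asarray(trans, dtype=float)
    return AffineTransform(A)


def matrix_average(transforms: Iterable[AffineTransform]) -> AffineTransform:
    """Log-Euclidean mean: exp of the arithmetic mean of matrix logarithms.

    Used to build the unbiased subject-specific linear template from all
    pairwise inter-time-point transforms; for ``{A, A^{-1}}`` it returns the
    identity, so no time-point is privileged.
    """
    transforms = list(transforms)
    if not transforms:
        raise ValueError("need at least one transform")
    logs = []
    for t in transforms:
        if t.det3() <= 0:
            raise ValueError("matrix_average requires positive determinants")
        lg = scipy.linalg.logm(t.matrix)
        if np.max(np.abs(lg.imag)) > 1e-8:
            raise ValueError("matrix logarithm is not real; transforms too far apart")
        logs.append(lg.real)
    mean = np.mean(logs, axis=0)
    out = scipy.linalg.expm(mean).real
    out[3] = [0, 0, 0, 1]
    return AffineTransform(out)


def halfway_decompose(a: AffineTransform) -> tuple[AffineTransform, AffineTransform]:
    """Split ``a`` (followup world -> baseline world) into two half-transforms.

    Returns ``(to_half_from_baseline, to_half_from_followup)`` =
    ``(a^{-1/2}, a^{+1/2})`` via the principal matrix square root, so each
    image travels half of ``a`` and interpolation burden is symmetric.
    The recomposition identity ``h_f^{-1} . h_b = a^{-1}`` holds exactly.
    """
    eig = np.linalg.eigvals(a.matrix)
    if np.any((eig.real < 0) & (np.abs(eig.imag) < 1e-12)):
        raise ValueError(
            "principal matrix square root does not exist "
            "(negative real eigenvalue); apply a rigid pre-alignment first"
        )
    s = scipy.linalg.sqrtm(a.matrix)
    if np.max(np.abs(np.asarray(s).imag)) > 1e-8:
        raise ValueError("matrix square root is not real; rigid pre-alignment needed")
    s = np.asarray(s).real
    s[3] = [0, 0, 0, 1]
    half_f = AffineTransform(s)                      # a^{+1/2}
    half_b = AffineTransform(np.linalg.inv(s))       # a^{-1/2}
    return half_b, half_f


# ----------------------------------------------------------------------
# resampling
# ----------------------------------------------------------------------

def make_grid(shape: Sequence[int], spacing: Sequence[float],
              origin: Sequence[float] = None) -> ImageVolume:
    """Empty reference volume describing a diagonal-affine grid.

    When ``origin`` is omitted the grid is centered on world (0,0,0).
    """
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing, dtype=float)
    if origin is None:
        origin = -(np.asarray(shape) - 1) / 2.0 * spacing
    A = np.eye(4)
    A[:3, :3] = np.diag(spacing)
    A[:3, 3] = origin
    return ImageVolume(np.zeros(shape, dtype=np.float32), A)


def _voxel_map(moving: ImageVolume, transform: Optional[AffineTransform],
               target: ImageVolume) -> np.ndarray:
    """4x4 voxel->voxel matrix: target voxel index -> moving voxel index."""
    T = np.eye(4) if transform is None else np.linalg.inv(transform.matrix)
    return np.linalg.inv(moving.affine) @ T @ target.affine


_ORDER = {"nearest": 0, "linear": 1, "windowed_sinc": None}


def resample(
    image: ImageVolume,
    transform_or_field,
    target_grid: ImageVolume,
    interp: str = "linear",
) -> ImageVolume:
    """Pull-back resampling of ``image`` onto ``target_grid``.

    ``transform_or_field`` is an :class:`AffineTransform` mapping moving
    world coordinates into target world coordinates, ``None`` (identity), or
    a :class:`~jacint.nonlinreg.DisplacementField` whose vectors (mm, world
    axes) displace each target-grid sample position before lookup.
    Out-of-field voxels are zeroed and flagged in the validity mask.
    """
    if interp not in _ORDER:
        raise ValueError(f"unknown interpolation {interp!r}")
    from .nonlinreg import DisplacementField  # local import avoids a cycle

    is_label = isinstance(image, LabelMap)
    if is_label and interp != "nearest":
        raise ValueError("label maps must be resampled with nearest interpolation")

    if isinstance(transform_or_field, DisplacementField):
        return _resample_field(image, transform_or_field, target_grid, interp)

    transform = transform_or_field
    if transform is not None and abs(np.linalg.det(transform.matrix)) < 1e-12:
        raise ValueError("singular transform")

    if (interp == "nearest" and transform is None and same_grid(image, target_grid)):
        return image.like(image.data.copy())

    if interp == "windowed_sinc":
        data = _sitk_resample(image, transform, target_grid)
    else:
        M = _voxel_map(image, transform, target_grid)
        data = ndi.affine_transform(
            np.asarray(image.data, dtype=np.float32), M[:3, :3], M[:3, 3],
            output_shape=target_grid.shape, order=_ORDER[interp],
            mode="constant", cval=0.0, prefilter=False,
        )
    valid = _resample_validity(image, transform, target_grid)
    if is_label:
        return LabelMap(np.rint(data).astype(np.int16), target_grid.affine.copy(), valid)
    return ImageVolume(data, target_grid.affine.copy(), valid)


def _resample_validity(image: ImageVolume, transform, target: ImageVolume) -> np.ndarray:
    M = _voxel_map(image, transform, target)
    src = image.valid_mask().astype(np.float32)
    v = ndi.affine_transform(src, M[:3, :3], M[:3, 3], output_shape=target.shape,
                             order=0, mode="constant", cval=0.0)
    return v > 0.5


def _resample_field(image: ImageVolume, field, target: ImageVolume,
                    interp: str) -> ImageVolume:
    # sample positions: world coords of target voxels displaced by the field
    idx = np.indices(target.shape, dtype=np.float32)
    xyz = np.moveaxis(idx, 0, -1)
    world = target.voxel_to_world(xyz.reshape(-1, 3))
    u = field.sample_world(world)
    mov_vox = image.world_to_voxel(world + u).T.reshape(3, *target.shape)
    order = 3 if interp == "windowed_sinc" else _ORDER[interp]
    data = ndi.map_coordinates(np.asarray(image.data, dtype=np.float32), mov_vox,
                               order=order, mode="constant", cval=0.0,
                               prefilter=(order > 1))
    vsrc = image.valid_mask().astype(np.float32)
    v = ndi.map_coordinates(vsrc, mov_vox, order=0, mode="constant", cval=0.0)
    if isinstance(image, LabelMap):
        return LabelMap(np.rint(data).astype(np.int16), target.affine.copy(), v > 0.5)
    return ImageVolume(data, target.affine.copy(), v > 0.5)


def _sitk_resample(image: ImageVolume, transform, target: ImageVolume) -> np.ndarray:
    """Lanczos windowed-sinc resampling through SimpleITK."""
    import SimpleITK as sitk

    def to_sitk(vol: ImageVolume) -> "sitk.Image":
        A = vol.affine[:3, :3]
        spacing = np.linalg.norm(A, axis=0)
        direction = A / spacing  # columns
        if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-6):
            raise ValueError("windowed-sinc resampling requires an orthogonal grid")
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(np.asarray(vol.data, dtype=np.float32).transpose(2, 1, 0)))
        img.SetSpacing(tuple(spacing))
        img.SetOrigin(tuple(vol.affine[:3, 3]))
        img.SetDirection(tuple(direction.ravel(order="C")))
        return img

    mov = to_sitk(image)
    ref = to_sitk(target)
    if transform is None:
        t = sitk.Transform(3, sitk.sitkIdentity)
    else:
        inv = np.linalg.inv(transform.matrix)  # fixed world -> moving world
        t = sitk.AffineTransform(3)
        t.SetMatrix(tuple(inv[:3, :3].ravel(order="C")))
        t.SetTranslation(tuple(inv[:3, 3]))
    out = sitk.Resample(mov, ref, t, sitk.sitkLanczosWindowedSinc, 0.0,
                        sitk.sitkFloat32)
    return sitk.GetArrayFromImage(out).transpose(2, 1, 0)


# ----------------------------------------------------------------------
# similarity
# ----------------------------------------------------------------------

def nmi(a: ImageVolume, b: ImageVolume, bins: int = 64,
        mask: Optional[np.ndarray] = None,
        edges: Optional[tuple] = None) -> float:
    """Normalized mutual information (H(A)+H(B))/H(A,B); higher = more similar.

    ``b`` must share ``a``'s grid (resample first otherwise); the joint
    histogram is taken over ``mask`` voxels (default: voxels valid in both).
    """
    if not same_grid(a, b):
        b = resample(b, None, a, interp="linear")
    if mask is None:
        mask = a.valid_mask() & b.valid_mask()
    x = np.asarray(a.data, dtype=np.float64)[mask]
    y = np.asarray(b.data, dtype=np.float64)[mask]
    if x.size == 0:
        raise ValueError("empty overlap between images")
    if edges is None:
        ex = np.linspace(x.min(), x.max() + 1e-9, bins + 1)
        ey = np.linspace(y.min(), y.max() + 1e-9, bins + 1)
    else:
        ex, ey = edges
    h, _, _ = np.histogram2d(x, y, bins=(ex, ey))
    p = h / h.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def ent(q):
        q = q[q > 0]
        return -np.sum(q * np.log(q))

    hxy = ent(p.ravel())
    if hxy == 0:
        return 2.0
    return (ent(px) + ent(py)) / hxy


# ----------------------------------------------------------------------
# staged registration
# ----------------------------------------------------------------------

@dataclass
class RegistrationStagePlan:
    """Parameter schedule for the staged affine registration.

    Stages run in order, each freezing all previously optimized parameters:
    rotations (3 dof), translation (3 dof), multi-start global scale (1 dof),
    then per-axis scales + shears (6 dof).
    """

    bins: int = 64
    xatol: float = 1e-4
    fatol: float = 1e-6
    maxiter: int = 400
    scale_seeds: tuple = (0.95, 1.0, 1.05)
    coarse_max_dim: int = 48
    smooth_sigma_vox: float = 1.0


def _coarsen(vol: ImageVolume, max_dim: int, sigma: float) -> ImageVolume:
    """Smooth + stride-decimate for fast similarity evaluation."""
    step = max(1, int(np.ceil(max(vol.shape) / max_dim)))
    data = np.asarray(vol.data, dtype=np.float32)
    if sigma > 0:
        data = ndi.gaussian_filter(data, sigma * step)
    data = data[::step, ::step, ::step]
    A = vol.affine.copy()
    A[:3, :3] *= step
    v = vol.valid_mask()[::step, ::step, ::step]
    return ImageVolume(data, A, v)


def _brain_centroid(vol: ImageVolume, mask: Optional[np.ndarray] = None) -> np.ndarray:
    data = np.asarray(vol.data, dtype=np.float64)
    if mask is None:
        mask = data > 0.1 * data.max()
    idx = np.argwhere(mask)
    if idx.size == 0:
        return vol.center_world()
    return vol.voxel_to_world(idx.mean(axis=0))


class _NMICost:
    """Negative NMI of (fixed, moving warped by params) on coarse grids."""

    def __init__(self, moving: ImageVolume, fixed: ImageVolume,
                 plan: RegistrationStagePlan, center: np.ndarray,
                 mask: Optional[np.ndarray] = None):
        self.movc = _coarsen(moving, plan.coarse_max_dim, plan.smooth_sigma_vox)
        self.fixc = _coarsen(fixed, plan.coarse_max_dim, plan.smooth_sigma_vox)
        self.plan = plan
        self.center = center
        if mask is not None:
            step = max(1, int(np.ceil(max(fixed.shape) / plan.coarse_max_dim)))
            self.mask = mask[::step, ::step, ::step]
        else:
            self.mask = None
        x = np.asarray(self.fixc.data, dtype=np.float64)
        y = np.asarray(self.movc.data, dtype=np.float64)
        self.edges = (
            np.linspace(x.min(), x.max() + 1e-9, plan.bins + 1),
            np.linspace(y.min(), y.max() + 1e-9, plan.bins + 1),
        )

    def nmi_of(self, transform: AffineTransform) -> float:
        warped = resample(self.movc, transform, self.fixc, interp="linear")
        mask = warped.valid_mask() & self.fixc.valid_mask()
        if self.mask is not None:
            mask &= self.mask
        if not mask.any():
            return 0.0
        return nmi(self.fixc, warped, bins=self.plan.bins, mask=mask,
                   edges=self.edges)

    def __call__(self, transform: AffineTransform) -> float:
        return -self.nmi_of(transform)


def _simplex(fun, x0, steps, plan: RegistrationStagePlan):
    x0 = np.asarray(x0, dtype=float)
    sim = np.vstack([x0] + [x0 + np.eye(len(x0))[i] * steps[i] for i in range(len(x0))])
    res = minimize(fun, x0, method="Nelder-Mead",
                   options=dict(xatol=plan.xatol, fatol=plan.fatol,
                                maxiter=plan.maxiter, initial_simplex=sim))
    return res.x, res.fun


def _staged_affine(cost: _NMICost, center: np.ndarray, init_trans: np.ndarray,
                   plan: RegistrationStagePlan,
                   stages: Sequence[str]) -> AffineTransform:
    """Run the requested stages; each stage reverts if it worsens NMI."""
    params = dict(rot=np.zeros(3), trans=np.asarray(init_trans, dtype=float),
                  scale=np.ones(3), shear=np.zeros(3))

    def build():
        return make_affine(rot=params["rot"], trans=params["trans"],
                           scale=params["scale"], shear=params["shear"],
                           center=center)

    best = cost.nmi_of(build())
    flags = {}
    for stage in stages:
        if stage == "rotations":
            def fun(x):
                return cost(make_affine(rot=x, trans=params["trans"],
                                        scale=params["scale"], shear=params["shear"],
                                        center=center))
            x, f = _simplex(fun, params["rot"], [0.03] * 3, plan)
            trial = {**params, "rot": x}
        elif stage == "translation":
            def fun(x):
                return cost(make_affine(rot=params["rot"], trans=x,
                                        scale=params["scale"], shear=params["shear"],
                                        center=center))
            x, f = _simplex(fun, params["trans"], [2.0] * 3, plan)
            trial = {**params, "trans": x}
        elif stage == "global_scale":
            def fun(x):
                return cost(make_affine(rot=params["rot"], trans=params["trans"],
                                        scale=float(x[0]) * params["scale"],
                                        shear=params["shear"], center=center))
            cands = []
            for seed in plan.scale_seeds:
                x, f = _simplex(fun, [seed], [0.02], plan)
                cands.append((f, x))
            f, x = min(cands, key=lambda c: c[0])
            trial = {**params, "scale": float(x[0]) * params["scale"]}
        elif stage == "scales_shears":
            def fun(x):
                return cost(make_affine(rot=params["rot"], trans=params["trans"],
                                        scale=x[:3], shear=x[3:],
                                        center=center))
            x0 = np.concatenate([params["scale"], params["shear"]])
            x, f = _simplex(fun, x0, [0.01] * 6, plan)
            trial = {**params, "scale": x[:3], "shear": x[3:]}
        elif stage == "rigid":
            def fun(x):
                return cost(make_affine(rot=x[:3], trans=x[3:],
                                        scale=params["scale"], shear=params["shear"],
                                        center=center))
            x0 = np.concatenate([params["rot"], params["trans"]])
            x, f = _simplex(fun, x0, [0.03] * 3 + [2.0] * 3, plan)
            trial = {**params, "rot": x[:3], "trans": x[3:]}
        else:  # pragma: no cover
            raise ValueError(f"unknown stage {stage!r}")
        trial_nmi = cost.nmi_of(make_affine(rot=trial["rot"], trans=trial["trans"],
                                            scale=trial["scale"], shear=trial["shear"],
                                            center=center))
        if trial_nmi >= best - 1e-12:
            params = trial
            best = trial_nmi
        else:
            warnings.warn(f"registration stage {stage!r} worsened NMI; reverted")
            flags[f"reverted_{stage}"] = True
    t = build()
    t.flags.update(flags)
    t.flags["nmi"] = best
    return t


def hierarchical_affine(moving: ImageVolume, fixed: ImageVolume,
                        plan: Optional[RegistrationStagePlan] = None,
                        fixed_mask: Optional[np.ndarray] = None,
                        refine: bool = True) -> AffineTransform:
    """Staged affine registration of ``moving`` onto ``fixed`` by simplex over NMI.

    Stages: rotations, translation, multi-start global scale, scales+shears;
    each optimizes only its own parameter subset and is reverted (with a
    warning) if it fails to improve NMI.  Initialization translates the
    moving intensity centroid onto the fixed one.  ``refine`` adds a final
    full-resolution least-squares polish of translation/scale/shear.
    """
    plan = plan or RegistrationStagePlan()
    center = _brain_centroid(fixed, fixed_mask)
    init_trans = center - _brain_centroid(moving)
    cost = _NMICost(moving, fixed, plan, center, fixed_mask)
    out = _staged_affine(cost, center, init_trans, plan,
                         ["rotations", "translation", "global_scale", "scales_shears"])
    if refine:
        fdat = np.asarray(fixed.data)
        region = fixed_mask if fixed_mask is not None else fdat > 0.1 * fdat.max()
        out = _msd_refine(fixed, moving, out, region, center, plan)
    return out


def pairreg_like(baseline: ImageVolume, followup: ImageVolume,
                 brain_mask: np.ndarray, skull_mask: np.ndarray,
                 plan: Optional[RegistrationStagePlan] = None) -> AffineTransform:
    """Skull-constrained intra-subject registration (pairreg-style).

    Stage 1 estimates the 6-dof rigid alignment of the follow-up onto the
    baseline over brain-mask NMI; stage 2 freezes the rigid part and
    estimates global scale, per-axis scales and shears over skull-mask NMI,
    absorbing scanner voxel-size miscalibration.  Returns the composed
    transform (followup world -> baseline world).
    """
    plan = plan or RegistrationStagePlan()
    center = _brain_centroid(baseline, brain_mask)
    init_trans = center - _brain_centroid(followup)

    cost_brain = _NMICost(followup, baseline, plan, center, brain_mask)
    rigid = _staged_affine(cost_brain, center, init_trans, plan, ["rigid"])

    if skull_mask is None or not np.any(skull_mask):
        warnings.warn("empty skull mask: falling back to rigid-only pairreg")
        rigid.flags["rigid_only"] = True
        return rigid

    skull_region = ndi.binary_dilation(skull_mask, iterations=2)
    cost_skull = _NMICost(followup, baseline, plan, center, skull_region)

    def nmi_of(scale, shear):
        t = _compose_scale_on_rigid(rigid, scale, shear, center)
        return cost_skull.nmi_of(t)

    best_nmi = nmi_of(np.ones(3), np.zeros(3))
    # stage 2a: multi-start global scale (1 dof)
    def fun_g(x):
        return -nmi_of(np.full(3, float(x[0])), np.zeros(3))
    cands = []
    for seed in plan.scale_seeds:
        x, f = _simplex(fun_g, [seed], [0.02], plan)
        cands.append((f, float(x[0])))
    _, g = min(cands, key=lambda c: c[0])
    # stage 2b: per-axis scales + shears (6 dof)
    def fun_ss(x):
        return -nmi_of(x[:3], x[3:])
    x, _ = _simplex(fun_ss, np.array([g, g, g, 0, 0, 0]), [0.005] * 6, plan)
    scale, shear = x[:3], x[3:]
    if nmi_of(scale, shear) >= best_nmi - 1e-12:
        out = _compose_scale_on_rigid(rigid, scale, shear, center)
    else:
        warnings.warn("pairreg scale/skew stage worsened skull NMI; reverted")
        out = rigid
        out.flags["reverted_scale_skew"] = True
    out = _msd_refine(baseline, followup, out, skull_region, center, plan)
    out.flags["nmi_brain"] = rigid.flags.get("nmi")
    return out


def _msd_refine(fixed: ImageVolume, moving: ImageVolume, init: AffineTransform,
                region: np.ndarray, center: np.ndarray,
                plan: RegistrationStagePlan) -> AffineTransform:
    """Full-resolution least-squares polish of an affine estimate.

    The coarse NMI stages locate the optimum to ~0.1% in scale; integrating
    Jacobians to a tenth of a percentage point needs better, so the final
    scale/shear/translation are refined by minimizing the mean squared
    intensity difference over the (mildly smoothed, mean-normalized) region.
    """
    sm = 0.5
    fdat = ndi.gaussian_filter(np.asarray(fixed.data, np.float32), sm)
    mdat = ndi.gaussian_filter(np.asarray(moving.data, np.float32), sm)
    fvol = ImageVolume(fdat, fixed.affine.copy())
    mvol = ImageVolume(mdat, moving.affine.copy(), moving.valid)
    fnorm = float(fdat[region].mean())

    def cost(x) -> float:
        delta = make_affine(trans=x[:3], scale=x[3:6], shear=x[6:], center=center)
        t = AffineTransform(delta.matrix @ init.matrix)
        w = resample(mvol, t, fvol, interp="linear")
        m = region & w.valid_mask()
        if not m.any():
            return np.inf
        wn = float(w.data[m].mean())
        if wn <= 0:
            return np.inf
        return float(np.mean((w.data[m] / wn - fdat[m] / fnorm) ** 2))

    x0 = np.concatenate([np.zeros(3), np.ones(3), np.zeros(3)])
    steps = [0.2] * 3 + [0.004] * 3 + [0.002] * 3
    x, f = _simplex(cost, x0, steps, plan)
    if f <= cost(x0):
        delta = make_affine(trans=x[:3], scale=x[3:6], shear=x[6:], center=center)
        out = AffineTransform(delta.matrix @ init.matrix)
        out.flags.update(init.flags)
        out.flags["msd_refined"] = True
        return out
    return init


def _compose_scale_on_rigid(rigid: AffineTransform, scale, shear,
                            center: np.ndarray) -> AffineTransform:
    ss = make_affine(scale=scale, shear=shear, center=center)
    return AffineTransform(ss.matrix @ rigid.matrix)


def symmetry_rotation(image: ImageVolume,
                      plan: Optional[RegistrationStagePlan] = None) -> AffineTransform:
    """Find y- and z-rotations maximizing left-right mirror symmetry.

    The image is rotated by candidate (ry, rz), mirrored across the
    mid-sagittal (x = const) plane through its centroid, and the rotation
    maximizing NMI between the rotated image and its mirror is returned.
    A non-converged optimization returns the identity with a flag.
    """
    plan = plan or RegistrationStagePlan()
    center = _brain_centroid(image)
    coarse = _coarsen(image, plan.coarse_max_dim, plan.smooth_sigma_vox)
    x = np.asarray(coarse.data, dtype=np.float64)
    edges = (np.linspace(x.min(), x.max() + 1e-9, plan.bins + 1),) * 2

    def mirror_mat() -> AffineTransform:
        M = np.eye(4)
        M[0, 0] = -1.0
        M[0, 3] = 2.0 * center[0]
        return M

    Mm = mirror_mat()

    def score(ry: float, rz: float) -> float:
        rot = make_affine(rot=(0.0, ry, rz), center=center)
        rotated = resample(coarse, rot, coarse, interp="linear")
        # mirror the rotated image: pull back through the reflection
        M = np.linalg.inv(coarse.affine) @ Mm @ coarse.affine
        mirr = ndi.affine_transform(np.asarray(rotated.data, np.float32),
                                    M[:3, :3], M[:3, 3], order=1,
                                    mode="constant", cval=0.0, prefilter=False)
        mirr_vol = coarse.like(mirr, valid=None)
        mask = rotated.valid_mask()
        return nmi(rotated, mirr_vol, bins=plan.bins, mask=mask, edges=edges)

    def fun(p):
        return -score(p[0], p[1])

    x0 = np.zeros(2)
    sim = np.vstack([x0, x0 + [0.05, 0], x0 + [0, 0.05]])
    res = minimize(fun, x0, method="Nelder-Mead",
                   options=dict(xatol=plan.xatol, fatol=plan.fatol,
                                maxiter=plan.maxiter, initial_simplex=sim))
    if not res.success and res.fun >= fun(x0):
        t = AffineTransform.identity()
        t.flags["converged"] = False
        return t
    t = make_affine(rot=(0.0, res.x[0], res.x[1]), center=center)
    t.flags["converged"] = True
    return t
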