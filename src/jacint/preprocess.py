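"""Intensity and mask conditioning.

Covers the pre-processing stages around the measurement core: a
Gaussian-mixture tissue segmenter (surrogate for a full MRF-based tool,
sufficient for integration masks), lesion filling with normal-appearing
white matter (NAWM) intensities, longitudinal lesion-mask union, differential
intensity correction against a subject template, field-of-view matching and
a polynomial bias-field surrogate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dfield
from typing import Optional, Sequence

import numpy as np
import scipy.ndimage as ndi

from .image import ImageVolume, LabelMap, Labels, same_grid
from .linreg import AffineTransform, resample

__all__ = [
    "TissueStats",
    "segment_tissues",
    "fill_lesions",
    "union_lesion_masks",
    "differential_intensity_correction",
    "match_fov",
    "simple_bias_correct",
]


@dataclass
class TissueStats:
    """Per-class intensity statistics (CSF, GM, WM) and NAWM mean/SD."""

    means: dict
    sds: dict
    nawm_mean: Optional[float] = None
    nawm_sd: Optional[float] = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "means": {str(k): float(v) for k, v in self.means.items()},
                "sds": {str(k): float(v) for k, v in self.sds.items()},
                "nawm_mean": self.nawm_mean, "nawm_sd": self.nawm_sd,
            }, fh, indent=2)


def segment_tissues(image: ImageVolume, brain_mask: np.ndarray, k: int = 3,
                    lesion_mask: Optional[np.ndarray] = None,
                    max_fit_voxels: int = 200_000, seed: int = 0
                    ) -> tuple[LabelMap, TissueStats]:
    """Three-class Gaussian-mixture EM segmentation of in-mask intensities.

    Classes are relabeled by ascending mean (CSF < GM < WM for T1) and hard
    labels assigned by maximum posterior.  NAWM statistics are computed over
    WM voxels excluding ``lesion_mask``.  Collapsed classes raise with
    diagnostics.
    """
    from sklearn.mixture import GaussianMixture

    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    x = np.asarray(image.data, dtype=np.float64)[brain_mask]
    rng = np.random.default_rng(seed)
    fit_x = x if x.size <= max_fit_voxels else rng.choice(x, max_fit_voxels,
                                                          replace=False)
    scale = fit_x.std() or 1.0
    gmm = GaussianMixture(n_components=k, covariance_type="spherical",
                          reg_covar=1e-6 * scale ** 2, n_init=1,
                          random_state=0, max_iter=200)
    gmm.fit(fit_x[:, None])
    means = gmm.means_.ravel()
    order = np.argsort(means)
    if gmm.weights_[order].min() < 1e-4 or np.min(np.diff(means[order])) < 1e-6 * scale:
        raise RuntimeError(
            f"EM degenerate: means={means[order]}, weights={gmm.weights_[order]}")

    post = gmm.predict(x[:, None])
    relabel = np.empty(k, dtype=np.int16)
    for new, old in enumerate(order):
        relabel[old] = new
    tissue_codes = np.array([Labels.CSF, Labels.GM, Labels.WM])[relabel[post]]

    lab = np.zeros(image.shape, dtype=np.int16)
    lab[brain_mask] = tissue_codes
    labels = LabelMap(lab, image.affine.copy())

    stats_means, stats_sds = {}, {}
    for code in (Labels.CSF, Labels.GM, Labels.WM):
        sel = x[tissue_codes == code]
        stats_means[code] = float(sel.mean()) if sel.size else float("nan")
        stats_sds[code] = float(sel.std(ddof=1)) if sel.size > 1 else 0.0
    stats = TissueStats(stats_means, stats_sds)

    wm = labels.mask(Labels.WM)
    nawm = wm & ~np.asarray(lesion_mask, dtype=bool) if lesion_mask is not None else wm
    sel = np.asarray(image.data, dtype=np.float64)[nawm]
    if sel.size:
        stats.nawm_mean = float(sel.mean())
        stats.nawm_sd = float(sel.std(ddof=1)) if sel.size > 1 else 0.0
    return labels, stats


def fill_lesions(image: ImageVolume, lesion_mask: np.ndarray,
                 stats: TissueStats, seed: int = 0) -> ImageVolume:
    """Replace lesion voxels with i.i.d. draws from Normal(NAWM mean, NAWM SD).

    Sampling (rather than a constant fill) preserves NAWM texture
    statistics; all non-lesion voxels are untouched.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    out = np.asarray(image.data, dtype=np.float32).copy()
    if not lesion_mask.any():
        return image.like(out)
    if stats.nawm_mean is None:
        raise ValueError("no NAWM region available to sample fill intensities from")
    rng = np.random.default_rng(seed)
    out[lesion_mask] = rng.normal(stats.nawm_mean, max(stats.nawm_sd or 0.0, 0.0),
                                  size=int(lesion_mask.sum()))
    return image.like(out)


def union_lesion_masks(masks: Sequence[LabelMap],
                       to_template: Sequence[AffineTransform],
                       template_grid: Optional[ImageVolume] = None
                       ) -> tuple[LabelMap, list[LabelMap]]:
    """Combine per-time-point lesion masks through the subject template.

    Each mask is carried to template space (nearest neighbour) with its
    transform, the voxelwise OR is taken, and the union is projected back to
    every time-point's native grid.  Returns ``(union_in_template,
    back_projections)``.
    """
    if len(masks) != len(to_template):
        raise ValueError("need one transform per mask")
    template_grid = template_grid if template_grid is not None else masks[0]
    union = np.zeros(template_grid.shape, dtype=bool)
    for m, t in zip(masks, to_template):
        r = resample(m, t, template_grid, interp="nearest")
        if r.data.shape != union.shape:
            raise ValueError("grid mismatch after resampling to template")
        union |= r.data > 0
    union_map = LabelMap(union.astype(np.int16) * Labels.LESION,
                         template_grid.affine.copy())
    back = [resample(union_map, t.inverse(), m, interp="nearest") for m, t in
            zip(masks, to_template)]
    return union_map, back


def differential_intensity_correction(image: ImageVolume,
                                      template_image: ImageVolume,
                                      median_kernel_mm: float = 8.0,
                                      brain_mask: Optional[np.ndarray] = None,
                                      clamp: tuple = (0.5, 2.0),
                                      downsample: int = 1) -> ImageVolume:
    """Remove time-point bias as a median-filtered ratio to the template.

    ``bias = median_filter(image / template)`` over the brain (ratio clamped
    to ``clamp`` first); the output is ``image / bias`` inside the brain and
    unchanged outside.  The median makes the estimate robust to focal
    change, so real anatomy survives the correction.  ``downsample`` > 1
    evaluates the (smooth) bias on a decimated grid, cutting the cubic
    filter cost by its third power.
    """
    if not same_grid(image, template_image):
        raise ValueError("image and template must share one grid")
    size = np.maximum(np.rint(median_kernel_mm / image.spacing).astype(int), 0)
    if np.any(size < 1):
        raise ValueError("median kernel is smaller than one voxel")
    data = np.asarray(image.data, dtype=np.float64)
    tmpl = np.asarray(template_image.data, dtype=np.float64)
    if brain_mask is None:
        brain_mask = tmpl > 0.05 * tmpl.max()
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if np.any(tmpl[brain_mask] <= 0):
        raise ValueError("template must be strictly positive inside the brain")
    ratio = np.ones_like(data)
    ratio[brain_mask] = np.clip(data[brain_mask] / tmpl[brain_mask], *clamp)
    d = max(int(downsample), 1)
    if d > 1:
        coarse = ratio[::d, ::d, ::d]
        csize = tuple(np.maximum(np.rint(size / d).astype(int), 1))
        cbias = ndi.median_filter(coarse, size=csize)
        zoom = [s / c for s, c in zip(ratio.shape, cbias.shape)]
        bias = ndi.zoom(cbias, zoom, order=1)
    else:
        bias = ndi.median_filter(ratio, size=tuple(size))
    out = data.copy()
    out[brain_mask] = data[brain_mask] / np.maximum(bias[brain_mask], 1e-6)
    vol = image.like(out.astype(np.float32))
    vol.bias = bias.astype(np.float32)
    return vol


def match_fov(volumes: Sequence[ImageVolume]) -> list[ImageVolume]:
    """Keep only voxels observed at every time-point.

    Voxels invalid in any volume are zeroed and flagged invalid in all of
    them; an empty intersection raises.
    """
    if not volumes:
        return []
    g0 = volumes[0]
    for v in volumes[1:]:
        if not same_grid(g0, v):
            raise ValueError("match_fov requires a common grid")
    common = np.ones(g0.shape, dtype=bool)
    for v in volumes:
        common &= v.valid_mask()
    if not common.any():
        raise ValueError("empty field-of-view intersection")
    out = []
    for v in volumes:
        data = np.asarray(v.data).copy()
        data[~common] = 0
        out.append(type(v)(data, v.affine.copy(), common.copy()))
    return out


def simple_bias_correct(image: ImageVolume, brain_mask: np.ndarray,
                        degree: int = 3, seed: int = 0) -> ImageVolume:
    """Divide out a low-order polynomial estimate of smooth intensity bias.

    A smooth multiplicative non-uniformity surrogate: log-intensities are
    first normalized by their tissue-class mean (a quick 3-class mixture fit)
    so the regression target is the bias alone, a 3rd-degree 3-D polynomial
    is fitted to the residuals by least squares and divided out, and the
    output is rescaled so the brain mean intensity is preserved.  Without
    the class normalization the polynomial would fit the CSF/GM/WM contrast
    itself and imprint spurious gradients at tissue boundaries.
    """
    from sklearn.mixture import GaussianMixture

    brain_mask = np.asarray(brain_mask, dtype=bool)
    data = np.asarray(image.data, dtype=np.float64)
    pos = brain_mask & (data > 0)
    if not pos.any():
        raise ValueError("no positive in-mask intensities to fit")
    # fit only deep-tissue voxels: boundary/partial-volume voxels carry
    # anatomy, and any asymmetry there between time-points would imprint
    # a differential gradient exactly where the atrophy signal lives
    grad = ndi.gaussian_gradient_magnitude(data, 1.0)
    deep = pos & (grad <= max(1.5 * np.median(grad[pos]), 1e-12))
    if deep.sum() < 500:
        deep = pos
    pos = deep
    logint = np.log(data[pos])

    rng = np.random.default_rng(seed)
    fit_x = logint if logint.size <= 100_000 else rng.choice(logint, 100_000,
                                                             replace=False)
    gmm = GaussianMixture(n_components=3, covariance_type="spherical",
                          reg_covar=1e-8 * max(float(fit_x.var()), 1e-12) + 1e-10,
                          random_state=0, max_iter=200)
    gmm.fit(fit_x[:, None])
    cls = gmm.predict(logint[:, None])
    class_mean = gmm.means_.ravel()
    class_sd = np.sqrt(gmm.covariances_.ravel())
    y = logint - class_mean[cls]
    # partial-volume voxels at tissue boundaries sit between class means and
    # would drag the fit toward anatomy; keep only well-explained voxels
    keep = np.abs(y) <= np.maximum(2.5 * class_sd[cls], 0.02)

    idx = np.argwhere(pos).astype(np.float64)
    # normalize coordinates to [-1, 1] for a well-conditioned design matrix
    lo = np.array([0.0, 0.0, 0.0])
    hi = np.asarray(image.shape, dtype=np.float64) - 1.0
    xyz = 2.0 * (idx - lo) / (hi - lo) - 1.0

    powers = [(i, j, k) for i in range(degree + 1) for j in range(degree + 1)
              for k in range(degree + 1) if i + j + k <= degree]
    A = np.stack([xyz[:, 0] ** i * xyz[:, 1] ** j * xyz[:, 2] ** k
                  for i, j, k in powers], axis=1)
    coef, *_ = np.linalg.lstsq(A[keep], y[keep], rcond=None)

    all_idx = np.indices(image.shape, dtype=np.float64)
    zyx = 2.0 * np.moveaxis(all_idx, 0, -1).reshape(-1, 3) / (hi - lo) - 1.0
    Afull = np.stack([zyx[:, 0] ** i * zyx[:, 1] ** j * zyx[:, 2] ** k
                      for i, j, k in powers], axis=1)
    logbias = (Afull @ coef).reshape(image.shape)
    logbias -= logbias[pos].mean()
    out = data / np.exp(logbias)
    mean_in = data[brain_mask].mean()
    mean_out = out[brain_mask].mean()
    if mean_out > 0:
        out *= mean_in / mean_out
    vol = image.like(out.astype(np.float32))
    vol.bias = np.exp(logbias).astype(np.float32)
    return vol
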