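"""Visual-quality metrics (PSNR, tri-orientation SSIM, MSE, NRMSE, head
masking) and contour-consistency metrics (mDTA, 95HD, DSC).

PSNR is defined against the reference's maximum intensity,
``10 log10(max(ref)^2 / MSE)``; SSIM is computed in 2D slice-by-slice and
averaged over the axial, coronal and sagittal orientations; surface distances
are pooled symmetrically, with the mean giving the mean distance-to-agreement
and the 95th percentile the 95% Hausdorff distance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.metrics import structural_similarity
from skimage.morphology import ball

from .volumes import VolumeGrid

__all__ = [
    "QualityReport",
    "ContourMetrics",
    "psnr",
    "ssim_mean3",
    "mse_nrmse",
    "head_mask",
    "surface_distances",
    "contour_metrics",
    "quality_report",
]


@dataclass
class QualityReport:
    psnr: float
    ssim_axial: float
    ssim_coronal: float
    ssim_sagittal: float
    ssim_overall: float
    mse: float
    nrmse: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ContourMetrics:
    mdta_mm: float
    hd95_mm: float
    dsc: float

    def to_dict(self) -> dict:
        return asdict(self)


def _check_same_grid(ref: VolumeGrid, pred: VolumeGrid) -> None:
    if ref.shape != pred.shape:
        raise ValueError(f"grids differ: {ref.shape} vs {pred.shape}")
    if any(abs(a - b) > 1e-6 for a, b in zip(ref.spacing, pred.spacing)):
        raise ValueError(f"spacings differ: {ref.spacing} vs {pred.spacing}")


def _masked(values: np.ndarray, mask) -> np.ndarray:
    if mask is None:
        return values.ravel()
    m = mask.values.astype(bool) if isinstance(mask, VolumeGrid) else np.asarray(mask, bool)
    return values[m]


def psnr(ref: VolumeGrid, pred: VolumeGrid, mask=None) -> float:
    """Peak signal-to-noise ratio in dB; the peak is max(ref) in the mask.

    Identical images have zero MSE and an unbounded PSNR, signalled as +inf.
    """
    _check_same_grid(ref, pred)
    r = _masked(ref.values, mask)
    p = _masked(pred.values, mask)
    mse = float(np.mean((r - p) ** 2))
    peak = float(np.max(r))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def mse_nrmse(ref: VolumeGrid, pred: VolumeGrid, mask=None) -> tuple[float, float]:
    """Mean squared error and RMSE normalised by the reference range."""
    _check_same_grid(ref, pred)
    r = _masked(ref.values, mask)
    p = _masked(pred.values, mask)
    mse = float(np.mean((r - p) ** 2))
    rng = float(np.max(r) - np.min(r))
    if rng == 0:
        raise ValueError("NRMSE undefined for a constant reference")
    return mse, float(np.sqrt(mse) / rng)


_ORIENT_AXIS = {"sagittal": "sagittal", "coronal": "coronal", "axial": "axial"}


def _ssim_along(ref: VolumeGrid, pred: VolumeGrid, axis_label: str,
                mask, data_range: float) -> float:
    """Mean 2D SSIM over slices perpendicular to *axis_label*."""
    ax = ref.axis_index(axis_label)
    r = np.moveaxis(ref.values, ax, 0)
    p = np.moveaxis(pred.values, ax, 0)
    m = None
    if mask is not None:
        mv = mask.values if isinstance(mask, VolumeGrid) else np.asarray(mask)
        m = np.moveaxis(mv.astype(bool), ax, 0)
    vals = []
    for s in range(r.shape[0]):
        if m is not None and not m[s].any():
            continue
        if m is None:
            vals.append(structural_similarity(
                r[s], p[s], gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False, data_range=data_range))
        else:
            _, smap = structural_similarity(
                r[s], p[s], gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False, data_range=data_range, full=True)
            vals.append(smap[m[s]].mean())
    if not vals:
        raise ValueError("no usable slices for SSIM")
    return float(np.mean(vals))


def ssim_mean3(ref: VolumeGrid, pred: VolumeGrid, mask=None) -> dict:
    """2D SSIM per orientation plus the three-way mean.

    Uses the standard constants K1=0.01, K2=0.03 and a Gaussian window with
    sigma 1.5; the data range is the reference's intensity range.
    """
    _check_same_grid(ref, pred)
    if min(ref.shape) < 11:
        raise ValueError("volume too small for the 11-sample SSIM window")
    data_range = float(np.max(ref.values) - np.min(ref.values))
    if data_range == 0:
        raise ValueError("SSIM undefined for a constant reference")
    out = {}
    for label in ("axial", "coronal", "sagittal"):
        out[f"ssim_{label}"] = _ssim_along(ref, pred, label, mask, data_range)
    out["ssim_overall"] = float(
        np.mean([out["ssim_axial"], out["ssim_coronal"], out["ssim_sagittal"]])
    )
    return out


def quality_report(ref: VolumeGrid, pred: VolumeGrid, mask=None) -> QualityReport:
    """Full visual-quality record for one reconstruction."""
    s = ssim_mean3(ref, pred, mask)
    mse, nrmse = mse_nrmse(ref, pred, mask)
    return QualityReport(psnr=psnr(ref, pred, mask), mse=mse, nrmse=nrmse, **s)


# ---------------------------------------------------------------------------
# Head masking


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no foreground found")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def head_mask(vol: VolumeGrid) -> VolumeGrid:
    """Foreground head mask.

    Thresholds at half the Otsu level (dark tissue — skull, CSF, vitreous —
    must stay inside the mask), closes with a 3 mm ball to bridge remaining
    dark shells, keeps the largest connected component and fills holes.
    """
    v = vol.values
    if np.ptp(v) == 0:
        raise ValueError("cannot mask a constant volume")
    fg = v > 0.5 * threshold_otsu(v)
    r_vox = max(1, int(round(3.0 / min(vol.spacing))))
    fg = ndimage.binary_closing(fg, structure=ball(r_vox))
    fg = _largest_component(fg)
    fg = ndimage.binary_fill_holes(fg)
    return vol.with_values(fg.astype(np.uint8))


# ---------------------------------------------------------------------------
# Contour metrics


_CONN6 = ndimage.generate_binary_structure(3, 1)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels under 6-connectivity (mask minus its erosion)."""
    return mask & ~ndimage.binary_erosion(mask, structure=_CONN6,
                                          border_value=0)


def surface_distances(a: VolumeGrid, b: VolumeGrid) -> tuple[np.ndarray, np.ndarray]:
    """Directed surface-distance multisets (mm) between two binary masks.

    Returns ``(d_ab, d_ba)``: from each boundary voxel of *a* the distance to
    the nearest boundary voxel of *b*, and vice versa, using the grid spacing
    as the metric.
    """
    _check_same_grid(a, b)
    ma = a.values.astype(bool)
    mb = b.values.astype(bool)
    if not ma.any() or not mb.any():
        raise ValueError("surface distances need two non-empty masks")
    sa, sb = _boundary(ma), _boundary(mb)
    dt_b = ndimage.distance_transform_edt(~sb, sampling=a.spacing)
    dt_a = ndimage.distance_transform_edt(~sa, sampling=a.spacing)
    return dt_b[sa], dt_a[sb]


def contour_metrics(a: VolumeGrid, b: VolumeGrid) -> ContourMetrics:
    """mDTA (symmetric pooled mean), 95HD (pooled 95th pct) and Dice."""
    d_ab, d_ba = surface_distances(a, b)
    pooled = np.concatenate([d_ab, d_ba])
    ma = a.values.astype(bool)
    mb = b.values.astype(bool)
    dsc = 2.0 * np.logical_and(ma, mb).sum() / (ma.sum() + mb.sum())
    return ContourMetrics(
        mdta_mm=float(pooled.mean()),
        hd95_mm=float(np.percentile(pooled, 95)),
        dsc=float(dsc),
    )
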