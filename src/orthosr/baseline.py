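"""Interpolation-fusion baselines: register, upsample, normalise, average."""

from __future__ import annotations

import numpy as np

from .metrics import head_mask
from .volumes import VolumeGrid, apply_rigid, resample_to_grid, rigid_register

__all__ = ["fuse_interpolate"]


def _is_blank(vol: VolumeGrid) -> bool:
    return not np.any(vol.values)


def fuse_interpolate(X1: VolumeGrid, X2: VolumeGrid, method: str = "linear",
                     register: bool = False, normalize: bool = True,
                     grid: tuple | None = None,
                     target_spacing: float = 1.0) -> VolumeGrid:
    """Fuse two perpendicular stacks by interpolation and averaging.

    Each view is resampled to the isotropic target grid by the named kernel
    (``linear`` or ``lanczos``), optionally after rigidly registering view 2
    onto view 1.  With ``normalize`` the views are z-scored within their head
    masks before averaging and the result is rescaled back to view 1's
    statistics, so differently scaled acquisitions average meaningfully.  A
    fully blank (all-zero, masked) view is excluded from the average.
    """
    blank1, blank2 = _is_blank(X1), _is_blank(X2)
    if blank1 and blank2:
        raise ValueError("both views are blank")
    if register and not (blank1 or blank2):
        T = rigid_register(X2, X1)
        X2 = apply_rigid(X2, T)

    if grid is None:
        ref = X2 if blank1 else X1
        shape = tuple(int(np.floor(e / target_spacing + 1e-6)) + 1
                      for e in ref.extent_mm())
        grid = (shape, (target_spacing,) * 3, ref.origin)
    shape, spacing, origin = grid

    views = []
    for v, blank in ((X1, blank1), (X2, blank2)):
        if blank:
            continue
        views.append(resample_to_grid(v, shape, spacing, origin, method))

    if len(views) == 1:
        return views[0]

    if not normalize:
        fused = np.mean([v.values for v in views], axis=0)
        return VolumeGrid(fused, spacing, origin, views[0].axes)

    ref_mask = head_mask(views[0]).values.astype(bool)
    stats = []
    zscored = []
    for v in views:
        m, s = v.values[ref_mask].mean(), v.values[ref_mask].std()
        s = s if s > 0 else 1.0
        stats.append((m, s))
        zscored.append((v.values - m) / s)
    fused = np.mean(zscored, axis=0)
    m1, s1 = stats[0]
    return VolumeGrid(fused * s1 + m1, spacing, origin, views[0].axes)
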