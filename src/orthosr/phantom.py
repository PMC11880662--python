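"""Procedural T1-like digital head phantoms with ground-truth structure masks.

The phantom stands in for an isotropic ~1 mm T1 head scan: a bright
soft-tissue head ellipsoid wrapped in a scalp/skull shell, dark CSF and
ventricle cavities, and a set of discrete structures that matter for
radiotherapy follow-up — two eyes, a brainstem, two hippocampal arcs and two
thin optic-nerve tubes.  A smooth multiplicative inhomogeneity field and a
little texture noise keep it from being piecewise constant.  Geometry scales
with the requested grid so that smaller desk-scale phantoms remain anatomically
proportioned; per-seed jitter moves structure positions by up to ~5 mm and
radii by up to 10%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import AXIS_LABELS, VolumeGrid

__all__ = ["PhantomSpec", "LABELS", "make_phantom", "make_cohort"]

#: Label ids of the discrete structures in the label map.
LABELS = {
    "shell": 1,
    "brain": 2,
    "eye_left": 3,
    "eye_right": 4,
    "brainstem": 5,
    "hippocampus_left": 6,
    "hippocampus_right": 7,
    "optic_nerve_left": 8,
    "optic_nerve_right": 9,
}

#: Per-structure mean intensity (T1-like relative contrast, arbitrary [0,1]).
INTENSITY = {
    "background": 0.0,
    "scalp": 0.75,
    "skull": 0.12,
    "csf": 0.22,
    "brain": 0.62,
    "ventricle": 0.18,
    "eye": 0.25,
    "brainstem": 0.55,
    "hippocampus": 0.50,
    "optic_nerve": 0.58,
}


@dataclass
class PhantomSpec:
    """Configuration of one phantom draw."""

    seed: int = 0
    size: int = 160              # cubic grid, 1 mm isotropic
    spacing_mm: float = 1.0
    eye_radius_mm: float | None = None   # default scales with size (12 mm at 160)
    optic_radius_mm: float = 1.8         # tube radius; diameter <= 4 mm
    inhomogeneity: float = 0.08          # multiplicative field amplitude
    texture_sigma: float = 0.012         # additive texture noise scale
    jitter_mm: float = 5.0
    jitter_radius_frac: float = 0.10


def _ellipsoid(coords, center, semi):
    d = sum(((coords[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return d <= 1.0


def _capsule(coords, p0, p1, radius):
    """Voxels within *radius* mm of the segment p0-p1."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    L2 = float(d @ d)
    v = [coords[i] - p0[i] for i in range(3)]
    if L2 == 0:
        dist2 = sum(vi**2 for vi in v)
        return dist2 <= radius**2
    t = sum(v[i] * d[i] for i in range(3)) / L2
    t = np.clip(t, 0.0, 1.0)
    dist2 = sum((v[i] - t * d[i]) ** 2 for i in range(3))
    return dist2 <= radius**2


def _arc(coords, center, r_major, r_minor, phi0, phi1, n_seg=8):
    """A torus arc in the x-z plane approximated by capsule segments."""
    mask = np.zeros(np.broadcast_shapes(*(c.shape for c in coords)), dtype=bool)
    phis = np.linspace(phi0, phi1, n_seg + 1)
    pts = [
        (
            center[0] + r_major * np.cos(p),
            center[1],
            center[2] + r_major * np.sin(p),
        )
        for p in phis
    ]
    for a, b in zip(pts[:-1], pts[1:]):
        mask |= _capsule(coords, a, b, r_minor)
    return mask


def make_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, VolumeGrid]:
    """Build one phantom.  Returns ``(volume, label_map)`` on the same grid.

    The volume is deterministic in ``spec.seed``; the label map holds the ids
    of :data:`LABELS` (disjoint, everything inside the scalp shell).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(spec.size)
    sp = float(spec.spacing_mm)
    scale = n * sp / 160.0  # geometry reference frame is a 160 mm head box

    def jit(lo=-spec.jitter_mm, hi=spec.jitter_mm):
        return rng.uniform(lo, hi)

    def jrad(r):
        return r * (1.0 + rng.uniform(-spec.jitter_radius_frac, spec.jitter_radius_frac))

    ax = [np.arange(n) * sp for _ in range(3)]
    coords = np.meshgrid(*ax, indexing="ij", sparse=True)
    c0 = np.array([n * sp / 2.0] * 3)

    # Head: outer scalp ellipsoid, skull below it, CSF, then brain.
    head_semi = np.array([jrad(62.0), jrad(72.0), jrad(66.0)]) * scale
    head_c = c0 + np.array([jit(), jit(), jit()]) * 0.5
    scalp = _ellipsoid(coords, head_c, head_semi)
    skull_out = _ellipsoid(coords, head_c, head_semi - 3.5 * scale)
    skull_in = _ellipsoid(coords, head_c, head_semi - 8.0 * scale)
    brain_semi = head_semi - 12.0 * scale
    brain = _ellipsoid(coords, head_c, brain_semi)

    # Ventricles: two dark cavities beside the midline.
    vent = np.zeros((n,) * 3, dtype=bool)
    for side in (-1, 1):
        vc = head_c + np.array([side * 10.0 * scale + jit() * 0.3,
                                jit() * 0.3, 8.0 * scale + jit() * 0.3])
        vent |= _ellipsoid(coords, vc, np.array([5.0, 18.0, 8.0]) * scale)
    vent &= brain

    # Eyes: anterior spheres.
    eye_r = jrad(spec.eye_radius_mm if spec.eye_radius_mm is not None else 12.0 * scale)
    eyes = {}
    eye_centers = {}
    for side, name in ((-1, "eye_left"), (1, "eye_right")):
        ec = head_c + np.array(
            [side * (28.0 * scale + jit() * 0.4),
             head_semi[1] - eye_r - 6.0 * scale + jit() * 0.3,
             4.0 * scale + jit() * 0.3]
        )
        eyes[name] = _ellipsoid(coords, ec, np.array([eye_r] * 3))
        eye_centers[name] = ec

    # Brainstem: near-vertical cylinder (capsule) below the brain centre.
    bs_r = jrad(8.0 * scale)
    bs_top = head_c + np.array([jit() * 0.3, -8.0 * scale + jit() * 0.3, -6.0 * scale])
    bs_bot = bs_top + np.array([0.0, -4.0 * scale, -34.0 * scale])
    brainstem = _capsule(coords, bs_top, bs_bot, bs_r)

    # Hippocampi: arcs beside the brainstem.
    hip_rmin = jrad(4.0 * scale)
    hips = {}
    for side, name in ((-1, "hippocampus_left"), (1, "hippocampus_right")):
        hc = head_c + np.array([side * (22.0 * scale + jit() * 0.3),
                                -12.0 * scale + jit() * 0.3, -4.0 * scale])
        hips[name] = _arc(coords, hc, jrad(12.0 * scale), hip_rmin,
                          np.pi * 0.15, np.pi * 0.85)

    # Optic nerves: thin tubes from the back of each eye toward the chiasm.
    chiasm = head_c + np.array([0.0, 6.0 * scale, 0.0])
    optic_r = spec.optic_radius_mm * scale
    optics = {}
    for name, eye_name in (("optic_nerve_left", "eye_left"),
                           ("optic_nerve_right", "eye_right")):
        start = eye_centers[eye_name] + np.array([0.0, -eye_r, 0.0])
        optics[name] = _capsule(coords, start, chiasm, optic_r)

    # --- compose intensity -------------------------------------------------
    vol = np.zeros((n,) * 3, dtype=np.float64)
    vol[scalp] = INTENSITY["scalp"]
    vol[skull_out] = INTENSITY["skull"]
    vol[skull_in] = INTENSITY["csf"]
    vol[brain] = INTENSITY["brain"]
    vol[vent] = INTENSITY["ventricle"]
    for name, m in eyes.items():
        vol[m] = INTENSITY["eye"]
    vol[brainstem & skull_in] = INTENSITY["brainstem"]
    for m in hips.values():
        vol[m & brain] = INTENSITY["hippocampus"]
    for m in optics.values():
        vol[m & skull_in] = INTENSITY["optic_nerve"]

    # Smooth multiplicative inhomogeneity + texture noise.
    rough = rng.standard_normal((n,) * 3)
    smooth = ndimage.gaussian_filter(rough, sigma=25.0 / sp, mode="nearest")
    smooth /= max(np.abs(smooth).max(), 1e-12)
    vol *= 1.0 + spec.inhomogeneity * smooth
    tex = ndimage.gaussian_filter(rng.standard_normal((n,) * 3), sigma=1.0)
    vol += spec.texture_sigma * tex * (vol > 0)
    np.clip(vol, 0.0, 1.0, out=vol)

    # --- label map ---------------------------------------------------------
    labels = np.zeros((n,) * 3, dtype=np.int16)
    labels[scalp & ~skull_in] = LABELS["shell"]
    labels[brain] = LABELS["brain"]
    for name in ("eye_left", "eye_right"):
        labels[eyes[name] & scalp] = LABELS[name]
    labels[brainstem & skull_in] = LABELS["brainstem"]
    for name, m in hips.items():
        labels[m & brain] = LABELS[name]
    for name, m in optics.items():
        labels[m & skull_in] = LABELS[name]

    grid = dict(spacing=(sp,) * 3, origin=(0.0, 0.0, 0.0), axes=AXIS_LABELS)
    return VolumeGrid(vol, **grid), VolumeGrid(labels, **grid)


def make_cohort(n: int, base_seed: int = 0, **spec_kwargs):
    """*n* independently jittered phantoms, reproducible from *base_seed*."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = np.random.default_rng(base_seed).integers(0, 2**31 - 1, size=n)
    return [make_phantom(PhantomSpec(seed=int(s), **spec_kwargs)) for s in seeds]
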