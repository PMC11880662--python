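"""Simulate perpendicular thick-slice acquisitions from an isotropic volume.

The forward model of a 2D multi-slice acquisition along one anatomical axis is
(i) a through-plane Gaussian slice profile with standard deviation equal to the
slice thickness ``t`` (mm), followed by (ii) plane sampling at the slice
distance ``d`` (mm), with ``t ~ U(3, 8)`` and ``d ~ U(t, t + 4)``.  Two such
views along perpendicular axes, plus realistic acquisition artifacts
(per-slice motion, inter-view misregistration, Rician noise,
brightness/contrast changes, random blanking of one view) make up one
simulated training pair.  Because the two views live in slightly different
rigid frames, four high-resolution targets are emitted — one per plausible
reference frame — and the trainer scores a prediction against the closest one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation, Slerp

from .volumes import AXIS_LABELS, RigidTransform, VolumeGrid, apply_rigid

__all__ = [
    "AcquisitionParams",
    "ArtifactConfig",
    "SimulatedPair",
    "sample_acquisition_params",
    "blur_along_axis",
    "extract_slices",
    "inject_motion",
    "augment_intensity",
    "add_noise",
    "normalize_window",
    "simulate_pair",
]

THICKNESS_RANGE = (3.0, 8.0)   # mm, slice thickness ~ U(3, 8)
DISTANCE_EXTRA = 4.0           # mm, d ~ U(t, t + 4)


@dataclass
class AcquisitionParams:
    """One random draw of the two-view acquisition geometry."""

    t1: float
    t2: float
    d1: float
    d2: float
    axis1: str
    axis2: str
    offset1: float = 0.0
    offset2: float = 0.0

    def __post_init__(self) -> None:
        for t, d in ((self.t1, self.d1), (self.t2, self.d2)):
            if not (THICKNESS_RANGE[0] <= t <= THICKNESS_RANGE[1]):
                raise ValueError(f"slice thickness {t} outside {THICKNESS_RANGE}")
            if not (t <= d <= t + DISTANCE_EXTRA):
                raise ValueError(f"sampling distance {d} outside [{t}, {t + 4}]")
        if self.axis1 == self.axis2:
            raise ValueError("the two views must use distinct slice axes")
        for off, d in ((self.offset1, self.d1), (self.offset2, self.d2)):
            if not (0.0 <= off < d):
                raise ValueError(f"offset {off} outside [0, {d})")

    def to_dict(self) -> dict:
        return dict(t1=self.t1, t2=self.t2, d1=self.d1, d2=self.d2,
                    axis1=self.axis1, axis2=self.axis2,
                    offset1=self.offset1, offset2=self.offset2)


@dataclass
class ArtifactConfig:
    """Magnitudes of the simulated acquisition artifacts.

    The literature states which artifact families occur but not their sizes;
    these defaults are deliberately conservative and fully config-exposed.
    """

    noise_sigma_frac: float = 0.02       # Rician sigma as fraction of p99
    motion_prob: float = 0.3             # chance a stack receives slice motion
    motion_sigma_mm: float = 1.0         # per-slice in-plane shift SD
    interview_shift_mm: float = 2.0      # inter-view translation ~ U(-s, s)
    interview_rot_deg: float = 2.0       # inter-view rotation ~ U(-r, r)
    brightness_range: tuple[float, float] = (-0.1, 0.1)
    gamma_range: tuple[float, float] = (0.75, 4.0 / 3.0)
    mask_view_prob: float = 0.1

    def __post_init__(self) -> None:
        for p in (self.motion_prob, self.mask_view_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for s in (self.noise_sigma_frac, self.motion_sigma_mm,
                  self.interview_shift_mm, self.interview_rot_deg):
            if s < 0:
                raise ValueError("artifact scales must be >= 0")

    @classmethod
    def none(cls) -> "ArtifactConfig":
        """All artifacts switched off (pure blur + slice sampling)."""
        return cls(noise_sigma_frac=0.0, motion_prob=0.0, motion_sigma_mm=0.0,
                   interview_shift_mm=0.0, interview_rot_deg=0.0,
                   brightness_range=(0.0, 0.0), gamma_range=(1.0, 1.0),
                   mask_view_prob=0.0)


@dataclass
class SimulatedPair:
    """Two simulated LR views plus the four HR targets they came from."""

    X1: VolumeGrid
    X2: VolumeGrid
    targets: list[VolumeGrid]
    params: AcquisitionParams
    masked_view: int | None = None


def sample_acquisition_params(rng: np.random.Generator,
                              axes: tuple[str, str] | None = None
                              ) -> AcquisitionParams:
    """Draw t ~ U(3, 8) and d ~ U(t, t+4) per view, plus axes and offsets."""
    t1, t2 = rng.uniform(*THICKNESS_RANGE, size=2)
    d1 = rng.uniform(t1, t1 + DISTANCE_EXTRA)
    d2 = rng.uniform(t2, t2 + DISTANCE_EXTRA)
    if axes is None:
        axes = tuple(rng.permutation(AXIS_LABELS)[:2])
    off1 = rng.uniform(0.0, d1)
    off2 = rng.uniform(0.0, d2)
    return AcquisitionParams(t1, t2, d1, d2, axes[0], axes[1], off1, off2)


def blur_along_axis(vol: VolumeGrid, axis: str, sigma_mm: float) -> VolumeGrid:
    """1D Gaussian blur along one anatomical axis (slice-profile model).

    ``sigma_mm`` is converted to voxels through that axis's spacing; the kernel
    is truncated at 4 sigma and renormalised to unit sum, so constants are
    exactly preserved.
    """
    if sigma_mm < 0:
        raise ValueError("sigma must be >= 0")
    ax = vol.axis_index(axis)
    if sigma_mm == 0:
        return vol.copy()
    sigma_vox = sigma_mm / vol.spacing[ax]
    out = ndimage.gaussian_filter1d(
        vol.values.astype(np.float64, copy=False), sigma_vox, axis=ax,
        mode="nearest", truncate=4.0,
    )
    return vol.with_values(out)


def extract_slices(vol: VolumeGrid, axis: str, d_mm: float,
                   offset_mm: float = 0.0) -> VolumeGrid:
    """Sample planes at world positions offset, offset+d, ... along *axis*.

    Non-integral positions interpolate linearly between neighbouring planes.
    The output grid keeps the in-plane geometry and has spacing ``d_mm`` along
    the slice axis.
    """
    if d_mm <= 0:
        raise ValueError("slice distance must be > 0")
    if not 0.0 <= offset_mm < d_mm:
        raise ValueError("offset must lie in [0, d)")
    ax = vol.axis_index(axis)
    extent = vol.extent_mm()[ax]
    positions = np.arange(offset_mm, extent + 1e-9, d_mm)
    if len(positions) == 0:
        positions = np.array([offset_mm])
    coords = positions / vol.spacing[ax]
    idx_lo = np.floor(coords).astype(int)
    idx_hi = np.minimum(idx_lo + 1, vol.shape[ax] - 1)
    frac = coords - idx_lo
    v = np.moveaxis(vol.values.astype(np.float64, copy=False), ax, 0)
    out = v[idx_lo] * (1.0 - frac)[:, None, None] + v[idx_hi] * frac[:, None, None]
    out = np.moveaxis(out, 0, ax)
    spacing = list(vol.spacing)
    spacing[ax] = d_mm
    origin = list(vol.origin)
    origin[ax] += offset_mm
    return VolumeGrid(out, tuple(spacing), tuple(origin), vol.axes)


def inject_motion(stack: VolumeGrid, axis: str, rng: np.random.Generator,
                  motion_sigma_mm: float) -> VolumeGrid:
    """Shift every slice independently in-plane by N(0, sigma^2) mm."""
    ax = stack.axis_index(axis)
    if motion_sigma_mm == 0:
        return stack.copy()
    inplane = [i for i in range(3) if i != ax]
    v = np.moveaxis(stack.values.astype(np.float64, copy=True), ax, 0)
    for s in range(v.shape[0]):
        shift_mm = rng.normal(0.0, motion_sigma_mm, size=2)
        shift_vox = [shift_mm[j] / stack.spacing[inplane[j]] for j in range(2)]
        v[s] = ndimage.shift(v[s], shift_vox, order=1, mode="nearest")
    return stack.with_values(np.moveaxis(v, 0, ax))


def augment_intensity(vol: VolumeGrid, rng: np.random.Generator,
                      brightness_range=(-0.1, 0.1),
                      gamma_range=(0.75, 4.0 / 3.0)) -> VolumeGrid:
    """Random brightness/contrast change ``v -> clip(v + b, 0, 1) ** gamma``."""
    v = vol.values
    if v.min() < -1e-9 or v.max() > 1 + 1e-9:
        raise ValueError("intensity augmentation expects values in [0, 1]")
    b = rng.uniform(*brightness_range)
    g = rng.uniform(*gamma_range)
    out = np.clip(v + b, 0.0, 1.0) ** g
    return vol.with_values(out)


def add_noise(vol: VolumeGrid, rng: np.random.Generator,
              noise_sigma_frac: float) -> VolumeGrid:
    """Rician noise: magnitude of (v + n1, n2), sigma scaled to the 99th pct."""
    if noise_sigma_frac == 0:
        return vol.copy()
    sigma = noise_sigma_frac * float(np.percentile(vol.values, 99))
    if sigma <= 0:
        sigma = noise_sigma_frac
    n1 = rng.normal(0.0, sigma, vol.shape)
    n2 = rng.normal(0.0, sigma, vol.shape)
    out = np.hypot(vol.values + n1, n2)
    return vol.with_values(out)


def normalize_window(vol: VolumeGrid, lo_pct: float = 1.0,
                     hi_pct: float = 99.0) -> VolumeGrid:
    """Window intensities to [0, 1] by the (1st, 99th) percentile range."""
    lo, hi = np.percentile(vol.values, [lo_pct, hi_pct])
    if hi <= lo:
        return vol.with_values(np.zeros_like(vol.values, dtype=np.float64))
    out = np.clip((vol.values - lo) / (hi - lo), 0.0, 1.0)
    return vol.with_values(out)


def _random_view_transform(rng: np.random.Generator, cfg: ArtifactConfig,
                           center) -> RigidTransform:
    rot = rng.uniform(-cfg.interview_rot_deg, cfg.interview_rot_deg, size=3)
    tra = rng.uniform(-cfg.interview_shift_mm, cfg.interview_shift_mm, size=3)
    return RigidTransform(tuple(rot), tuple(tra), tuple(center))


def _halfway(T1: RigidTransform, T2: RigidTransform) -> RigidTransform:
    """Geodesic midpoint of two rigid transforms (slerp + mean translation)."""
    rots = Rotation.from_euler("xyz", [T1.rotation, T2.rotation], degrees=True)
    mid = Slerp([0.0, 1.0], rots)(0.5)
    tra = 0.5 * (np.asarray(T1.translation) + np.asarray(T2.translation))
    return RigidTransform(tuple(mid.as_euler("xyz", degrees=True)), tuple(tra),
                          T1.center)


def simulate_pair(hr: VolumeGrid, rng: np.random.Generator,
                  artifacts: ArtifactConfig | None = None,
                  params: AcquisitionParams | None = None,
                  normalized: bool = False) -> SimulatedPair:
    """Fabricate two perpendicular LR stacks and four HR targets from *hr*.

    *hr* must be 1 mm isotropic.  Pipeline per view: rigid inter-view
    perturbation of the HR frame, slice-profile blur with sigma = t, plane
    sampling at distance d (random phase), per-slice motion, Rician noise,
    brightness/gamma augmentation, and optional blanking of one view.  The
    four targets are the HR patch in the identity frame, each view's frame and
    the half-way frame.
    """
    if any(abs(s - 1.0) > 1e-6 for s in hr.spacing):
        raise ValueError(f"expected a 1 mm isotropic HR volume, got {hr.spacing}")
    artifacts = artifacts if artifacts is not None else ArtifactConfig()
    if params is None:
        params = sample_acquisition_params(rng)
    if not normalized:
        hr = normalize_window(hr)

    center = tuple(o + e / 2.0 for o, e in zip(hr.origin, hr.extent_mm()))
    T1 = _random_view_transform(rng, artifacts, center)
    T2 = _random_view_transform(rng, artifacts, center)
    identity = RigidTransform(center=center)

    views = []
    for T, axis, t, d, off in (
        (T1, params.axis1, params.t1, params.d1, params.offset1),
        (T2, params.axis2, params.t2, params.d2, params.offset2),
    ):
        moved = apply_rigid(hr, T) if _is_nontrivial(T) else hr.copy()
        blurred = blur_along_axis(moved, axis, t)
        # keep the offset inside the stack extent for small patches
        off = min(off, max(blurred.extent_mm()[blurred.axis_index(axis)] - 1e-6, 0.0))
        stack = extract_slices(blurred, axis, d, off % d)
        if rng.uniform() < artifacts.motion_prob:
            stack = inject_motion(stack, axis, rng, artifacts.motion_sigma_mm)
        stack = add_noise(stack, rng, artifacts.noise_sigma_frac)
        stack = stack.with_values(np.clip(stack.values, 0.0, 1.0))
        stack = augment_intensity(stack, rng, artifacts.brightness_range,
                                  artifacts.gamma_range)
        views.append(stack)
    X1, X2 = views

    masked_view = None
    if rng.uniform() < artifacts.mask_view_prob:
        masked_view = int(rng.integers(1, 3))
        blank = (X1 if masked_view == 1 else X2)
        blanked = blank.with_values(np.zeros_like(blank.values))
        if masked_view == 1:
            X1 = blanked
        else:
            X2 = blanked

    targets = [hr.copy()]
    for T in (T1, T2, _halfway(T1, T2)):
        targets.append(apply_rigid(hr, T) if _is_nontrivial(T) else hr.copy())
    return SimulatedPair(X1, X2, targets, params, masked_view)


def _is_nontrivial(T: RigidTransform) -> bool:
    return any(abs(a) > 1e-12 for a in T.rotation) or any(
        abs(t) > 1e-12 for t in T.translation
    )
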