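"""Volume data model, NIfTI I/O, resampling and rigid registration.

A :class:`VolumeGrid` is a 3D scalar field on a regular, axis-aligned grid.
World coordinates follow the RAS convention (first axis runs left->right,
second posterior->anterior, third inferior->superior), positions are
voxel-*center* based and every distance is in millimetres.  Each array axis
carries an anatomical label named after the slice orientation whose normal it
is: the left-right axis is ``sagittal``, the posterior-anterior axis is
``coronal`` and the inferior-superior axis is ``axial``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "AXIS_LABELS",
    "VolumeGrid",
    "RigidTransform",
    "read_volume",
    "write_volume",
    "resample",
    "resample_to_grid",
    "apply_rigid",
    "rigid_register",
]

#: Canonical array-axis labels, in RAS order.
AXIS_LABELS = ("sagittal", "coronal", "axial")


@dataclass
class VolumeGrid:
    """A 3D scalar field with per-axis spacing (mm), origin (mm) and labels."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: tuple[str, str, str] = AXIS_LABELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.axes = tuple(self.axes)
        if len(self.spacing) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in self.spacing
        ):
            raise ValueError(f"spacing must be three positive finite mm: {self.spacing}")
        if sorted(self.axes) != sorted(AXIS_LABELS):
            raise ValueError(f"axes must be a permutation of {AXIS_LABELS}: {self.axes}")
        if not np.isfinite(self.values).all():
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def extent_mm(self) -> tuple[float, float, float]:
        """Center-to-center world extent along each axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def axis_index(self, label: str) -> int:
        """Array axis whose slice-normal label is *label*."""
        if label not in self.axes:
            raise ValueError(f"unknown axis {label!r}; have {self.axes}")
        return self.axes.index(label)

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        return replace(self, values=values)

    def copy(self) -> "VolumeGrid":
        return replace(self, values=self.values.copy())


@dataclass
class RigidTransform:
    """6-DOF rigid map ``p -> R(p - c) + c + t`` (angles deg, lengths mm).

    Used as a *resampling* transform: :func:`apply_rigid` evaluates the input
    volume at the mapped position of every output voxel.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix (intrinsic x-y-z Euler angles, degrees)."""
        return Rotation.from_euler("xyz", self.rotation, degrees=True).as_matrix()

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (pts - c) @ self.matrix().T + c + t

    def inverse(self) -> "RigidTransform":
        rot = Rotation.from_euler("xyz", self.rotation, degrees=True).inv()
        angles = rot.as_euler("xyz", degrees=True)
        t_inv = -rot.as_matrix() @ np.asarray(self.translation)
        return RigidTransform(tuple(angles), tuple(t_inv), self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """The transform ``p -> self(other(p))`` (shared center assumed equal)."""
        r_self = Rotation.from_euler("xyz", self.rotation, degrees=True)
        r_other = Rotation.from_euler("xyz", other.rotation, degrees=True)
        r = r_self * r_other
        c = np.asarray(self.center)
        # self(other(p)) = R_s(R_o(p-c)+c+t_o - c)+c+t_s
        t = r_self.as_matrix() @ np.asarray(other.translation) + np.asarray(
            self.translation
        )
        return RigidTransform(
            tuple(r.as_euler("xyz", degrees=True)), tuple(t), self.center
        )


# ---------------------------------------------------------------------------
# NIfTI I/O


_LABEL_TO_WORLD = {"sagittal": 0, "coronal": 1, "axial": 2}


def read_volume(path) -> VolumeGrid:
    """Load a 3D NIfTI-1 volume, reoriented to canonical RAS axis order."""
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: image contains non-finite voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VolumeGrid(data, spacing, origin, AXIS_LABELS)


def write_volume(vol: VolumeGrid, path) -> None:
    """Write a :class:`VolumeGrid` as NIfTI-1, affine encoding the geometry."""
    affine = np.eye(4)
    for i, label in enumerate(vol.axes):
        w = _LABEL_TO_WORLD[label]
        affine[:3, i] = 0.0
        affine[w, i] = vol.spacing[i]
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), affine), str(path))


# ---------------------------------------------------------------------------
# Resampling


def _lanczos_weights(x: np.ndarray, a: int = 3) -> np.ndarray:
    """Lanczos-windowed sinc, support |x| < a."""
    out = np.sinc(x) * np.sinc(x / a)
    out[np.abs(x) >= a] = 0.0
    return out


def _resample_axis_1d(values: np.ndarray, axis: int, coords: np.ndarray,
                      method: str) -> np.ndarray:
    """Sample *values* at fractional index positions *coords* along one axis.

    Out-of-grid positions clamp to the edge value.  Linear and nearest have
    compact support; Lanczos (a=3) kernels are renormalised to unit sum so a
    constant field stays constant near the edges.
    """
    n = values.shape[axis]
    values = np.moveaxis(values, axis, 0)
    if method == "nearest":
        idx = np.clip(np.round(coords).astype(int), 0, n - 1)
        out = values[idx]
    elif method == "linear":
        c = np.clip(coords, 0, n - 1)
        lo = np.floor(c).astype(int)
        hi = np.minimum(lo + 1, n - 1)
        f = (c - lo).reshape((-1,) + (1,) * (values.ndim - 1))
        out = values[lo] * (1.0 - f) + values[hi] * f
    elif method == "lanczos":
        a = 3
        lo = np.floor(coords).astype(int)
        taps = np.arange(-a + 1, a + 1)  # 2a support around the interval
        idx = lo[:, None] + taps[None, :]
        w = _lanczos_weights(coords[:, None] - idx)
        w = w / w.sum(axis=1, keepdims=True)
        idx = np.clip(idx, 0, n - 1)
        flat = values.reshape(n, -1)
        out = np.einsum("ot,otf->of", w, flat[idx]).reshape(
            (len(coords),) + values.shape[1:]
        )
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return np.moveaxis(out, 0, axis)


def resample_to_grid(
    vol: VolumeGrid,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] | None = None,
    method: str = "linear",
) -> VolumeGrid:
    """Separable resampling of *vol* onto an explicit axis-aligned grid."""
    if origin is None:
        origin = vol.origin
    out = vol.values.astype(np.float64, copy=False)
    for ax in range(3):
        centers = origin[ax] + spacing[ax] * np.arange(shape[ax])
        coords = (centers - vol.origin[ax]) / vol.spacing[ax]
        out = _resample_axis_1d(out, ax, coords, method)
    return VolumeGrid(out, tuple(spacing), tuple(origin), vol.axes)


def resample(vol: VolumeGrid, target_spacing, method: str = "linear") -> VolumeGrid:
    """Resample to *target_spacing*, covering the same voxel-center extent."""
    target_spacing = tuple(float(s) for s in np.broadcast_to(target_spacing, 3))
    if any(s <= 0 or not np.isfinite(s) for s in target_spacing):
        raise ValueError(f"target spacing must be positive: {target_spacing}")
    shape = tuple(
        int(np.floor(ext / s + 1e-6)) + 1
        for ext, s in zip(vol.extent_mm(), target_spacing)
    )
    return resample_to_grid(vol, shape, target_spacing, vol.origin, method)


# ---------------------------------------------------------------------------
# Rigid motion


_RIGID_ORDER = {"nearest": 0, "linear": 1}


def apply_rigid(vol: VolumeGrid, T: RigidTransform, method: str = "linear") -> VolumeGrid:
    """Resample *vol* through the rigid map ``T`` on its own grid.

    Output voxel at world position ``p`` takes the input value at ``T(p)``;
    samples falling outside the grid clamp to the nearest edge value.
    """
    if method not in _RIGID_ORDER:
        raise ValueError(f"method must be one of {tuple(_RIGID_ORDER)}")
    S = np.diag(vol.spacing)
    Sinv = np.diag([1.0 / s for s in vol.spacing])
    R = T.matrix()
    c = np.asarray(T.center)
    t = np.asarray(T.translation)
    o = np.asarray(vol.origin)
    # index_in = S^-1 (R (S idx_out + o - c) + c + t - o)
    A = Sinv @ R @ S
    b = Sinv @ (R @ (o - c) + c + t - o)
    out = ndimage.affine_transform(
        vol.values.astype(np.float64, copy=False),
        A,
        offset=b,
        order=_RIGID_ORDER[method],
        mode="nearest",
    )
    return vol.with_values(out)


# ---------------------------------------------------------------------------
# Rigid registration (SimpleITK backend)


def _to_sitk(vol: VolumeGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T, dtype=np.float64))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def rigid_register(moving: VolumeGrid, fixed: VolumeGrid) -> RigidTransform:
    """Estimate the rigid transform aligning *moving* onto *fixed*.

    Returns ``T`` such that ``apply_rigid(moving, T)`` approximates *fixed*
    (the map takes fixed-space points to moving-space points, the usual
    resampling convention).  Similarity is normalised cross-correlation,
    optimised over a 3-level multiresolution pyramid.  Any backend honouring
    this contract may be substituted.
    """
    if np.ptp(moving.values) == 0 or np.ptp(fixed.values) == 0:
        warnings.warn("degenerate (constant) image; returning identity transform")
        return RigidTransform()
    f = _to_sitk(fixed)
    m = _to_sitk(moving)
    init = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=200,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SetInitialTransform(init, inPlace=False)
    final = reg.Execute(f, m)
    euler = sitk.Euler3DTransform(
        sitk.CompositeTransform(final).GetNthTransform(0)
        if isinstance(final, sitk.CompositeTransform)
        else final
    )
    ax, ay, az = euler.GetAngleX(), euler.GetAngleY(), euler.GetAngleZ()
    # ITK Euler3D composes R = Rz Ry Rx, i.e. extrinsic z-y-x == intrinsic x-y-z
    # read right-to-left; convert through the matrix to our convention.
    Rm = np.asarray(euler.GetMatrix()).reshape(3, 3)
    angles = Rotation.from_matrix(Rm).as_euler("xyz", degrees=True)
    return RigidTransform(
        rotation=tuple(angles),
        translation=tuple(euler.GetTranslation()),
        center=tuple(euler.GetCenter()),
    )


def similarity_ncc(a: VolumeGrid, b: VolumeGrid) -> float:
    """Normalised cross-correlation between two same-grid volumes."""
    x = a.values.ravel() - a.values.mean()
    y = b.values.ravel() - b.values.mean()
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom == 0:
        return 0.0
    return float(x @ y / denom)
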