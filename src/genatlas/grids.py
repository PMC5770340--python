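"""Image containers, NIfTI I/O, coordinate conventions and resampling.

Internal convention: continuous 0-based voxel coordinates with voxel centres
at integers.  World (mm) coordinates appear only at the I/O boundary, where
they are read from / written to the NIfTI sform.  Out-of-field sampling
clamps to the nearest edge voxel, so constant fields stay constant under
warping and no artificial background class is injected at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "ImageVolume",
    "LabelMap",
    "read_volume",
    "write_volume",
    "read_labels",
    "interpolate",
    "interpolate_vector",
    "trilinear_with_gradient",
    "push_weighted",
    "identity_map",
    "jacobian_determinant",
]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel lattice with a voxel-to-world affine (mm)."""

    shape: tuple[int, int, int]
    voxel_to_world: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        object.__setattr__(self, "shape", shape)
        aff = self.voxel_to_world
        if aff is None:
            aff = np.eye(4)
        aff = np.asarray(aff, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("voxel_to_world must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) <= 0.0:
            raise ValueError("voxel_to_world is singular")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "voxel_to_world", aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.voxel_to_world[:3, :3] ** 2).sum(axis=0))

    @property
    def world_to_voxel(self) -> np.ndarray:
        return np.linalg.inv(self.voxel_to_world)

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_to_world, other.voxel_to_world, atol=tol
        )


@dataclass
class ImageVolume:
    """Multi-channel image: ``data`` has shape (D, *grid.shape).

    ``observed_mask`` is True where the channel value is an actual
    measurement; NaNs on disk become unobserved voxels in memory.
    """

    grid: VoxelGrid
    data: np.ndarray
    observed_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.atleast_1d(np.asarray(self.data, dtype=float))
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        if self.observed_mask is None:
            self.observed_mask = np.isfinite(self.data)
        else:
            self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
            if self.observed_mask.shape != self.data.shape:
                raise ValueError("observed_mask shape mismatch")
        if not np.isfinite(self.data[self.observed_mask]).all():
            raise ValueError("observed voxels contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class LabelMap:
    """Integer-coded categorical labels; 0 means unlabelled."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-coded")
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0 (0 = unlabelled)")


def _grid_from_nifti(img) -> VoxelGrid:
    aff = img.get_sform() if img.header.get("sform_code", 0) else img.affine
    if aff is None or not np.isfinite(aff).all() or abs(np.linalg.det(np.asarray(aff)[:3, :3])) <= 0:
        aff = img.affine
    shape3 = tuple(img.shape[:3]) + (1,) * (3 - min(3, len(img.shape)))
    return VoxelGrid(shape3[:3], np.asarray(aff, dtype=float))


def read_volume(path) -> ImageVolume:
    """Read a NIfTI-1/2 file into an :class:`ImageVolume`.

    A 4-D file is interpreted as D channels along the last axis.  Non-finite
    voxels are marked unobserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if len(img.shape) > 4:
        raise ValueError(f"volume has {len(img.shape)} dimensions; at most 4 supported")
    data = np.asarray(img.get_fdata(), dtype=float)
    while data.ndim < 3:
        data = data[..., None]
    if data.ndim == 4:
        data = np.moveaxis(data, -1, 0)
    else:
        data = data[None]
    return ImageVolume(_grid_from_nifti(img), data)


def write_volume(path, vol: ImageVolume) -> None:
    """Write an ImageVolume as NIfTI (4-D when D > 1, NaN for unobserved)."""
    data = vol.data.copy()
    data[~vol.observed_mask] = np.nan
    arr = np.moveaxis(data, 0, -1) if vol.n_channels > 1 else data[0]
    img = nib.Nifti1Image(arr, vol.grid.voxel_to_world)
    img.set_sform(vol.grid.voxel_to_world, code=2)
    img.set_qform(vol.grid.voxel_to_world, code=2)
    nib.save(img, str(path))


def read_labels(path) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    while data.ndim < 3:
        data = data[..., None]
    labels = np.rint(data).astype(np.int32)
    return LabelMap(_grid_from_nifti(img), labels)


def write_labels(path, lab: LabelMap) -> None:
    img = nib.Nifti1Image(lab.labels.astype(np.int16), lab.grid.voxel_to_world)
    nib.save(img, str(path))


def identity_map(shape) -> np.ndarray:
    """Identity coordinate field, shape (3, *shape), voxel coordinates."""
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    return np.stack(grids, axis=0)


def interpolate(values: np.ndarray, points: np.ndarray, degree: int = 1) -> np.ndarray:
    """Sample a scalar field at continuous voxel coordinates.

    ``points`` has shape (3, ...).  Degree 0 is nearest neighbour, degree 1
    trilinear; both clamp outside the field of view.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("empty point set")
    if not np.isfinite(points).all():
        raise ValueError("NaN/inf coordinates")
    if degree not in (0, 1):
        raise ValueError("degree must be 0 or 1")
    return ndimage.map_coordinates(
        np.asarray(values, dtype=float), points, order=degree, mode="nearest"
    )


def interpolate_vector(values: np.ndarray, points: np.ndarray, degree: int = 1) -> np.ndarray:
    """Sample a (C, *shape) field component-wise; returns (C, *points.shape[1:])."""
    return np.stack([interpolate(values[c], points, degree) for c in range(values.shape[0])])


def trilinear_with_gradient(values: np.ndarray, points: np.ndarray):
    """Trilinear sample of a scalar field together with its spatial gradient.

    Returns (sampled, grad) where grad has shape (3, *points.shape[1:]) and is
    the exact derivative of the piecewise-linear interpolant (zero beyond the
    clamped boundary).
    """
    values = np.asarray(values, dtype=float)
    pts = np.asarray(points, dtype=float)
    shape = values.shape
    out_shape = pts.shape[1:]
    p = pts.reshape(3, -1)
    # clamp: replicate edge values; derivative vanishes outside
    inside = np.ones(p.shape[1], dtype=bool)
    pc = np.empty_like(p)
    for d in range(3):
        pc[d] = np.clip(p[d], 0.0, shape[d] - 1.0)
        inside &= (p[d] > 0.0) & (p[d] < shape[d] - 1.0)
    i0 = np.minimum(np.floor(pc).astype(int), np.array(shape)[:, None] - 2)
    i0 = np.maximum(i0, 0)
    f = pc - i0
    hi = [shape[d] - 1 for d in range(3)]
    vals = np.zeros(p.shape[1])
    grad = np.zeros((3, p.shape[1]))
    for cx in (0, 1):
        wx = f[0] if cx else 1.0 - f[0]
        dwx = 1.0 if cx else -1.0
        ix = np.minimum(i0[0] + cx, hi[0])
        for cy in (0, 1):
            wy = f[1] if cy else 1.0 - f[1]
            dwy = 1.0 if cy else -1.0
            iy = np.minimum(i0[1] + cy, hi[1])
            for cz in (0, 1):
                wz = f[2] if cz else 1.0 - f[2]
                dwz = 1.0 if cz else -1.0
                iz = np.minimum(i0[2] + cz, hi[2])
                v = values[ix, iy, iz]
                vals += wx * wy * wz * v
                grad[0] += dwx * wy * wz * v
                grad[1] += wx * dwy * wz * v
                grad[2] += wx * wy * dwz * v
    # beyond-edge clamp: values are constant, derivative zero, per axis
    for d in range(3):
        off = (p[d] <= 0.0) | (p[d] >= shape[d] - 1.0)
        if shape[d] == 1:
            grad[d] = 0.0
        else:
            grad[d, off] = 0.0
    return vals.reshape(out_shape), grad.reshape((3,) + out_shape)


def push_weighted(values: np.ndarray, inverse_map: np.ndarray, jac_det: np.ndarray) -> np.ndarray:
    """Volume-preserving pullback of a subject-grid field onto the template grid.

    Evaluates ``det(J) * values(inverse_map)`` at every template voxel, where
    ``inverse_map`` holds subject voxel coordinates of the inverse warp sampled
    on the template lattice and ``jac_det`` its Jacobian determinant there.
    """
    jac_det = np.asarray(jac_det, dtype=float)
    if (jac_det <= 0).any():
        raise ValueError("non-positive Jacobian determinant: folded map")
    return jac_det * interpolate(values, inverse_map, degree=1)


def jacobian_determinant(coord_map: np.ndarray) -> np.ndarray:
    """Determinant of the Jacobian of a sampled coordinate map (3, *shape).

    Central differences in the interior, one-sided at edges; singleton axes
    contribute an identity row.
    """
    shape = coord_map.shape[1:]
    J = np.zeros((3, 3) + shape)
    for comp in range(3):
        for ax in range(3):
            if shape[ax] == 1:
                J[comp, ax] = 1.0 if comp == ax else 0.0
            else:
                J[comp, ax] = np.gradient(coord_map[comp], axis=ax)
    return (
        J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
        - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
        + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0])
    )
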