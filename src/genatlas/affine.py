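"""Nine-parameter affine transforms via the Lie-algebra exponential map.

The linear part is T = expm(sum_m a_m B_m) over nine fixed generators of
ga(3) — three rotations, three log-zooms, three shears — so det T > 0 for
any parameter vector; translations are a separate 3-vector t (mm).  The
affine acts in world coordinates, composing with the subject-grid
diffeomorphism as  xi(y) = T phi(y) + t  before conversion to template
voxel coordinates.  A zero-mean Gaussian prior regularises the parameters:
variance 1 for rotations and translations, 0.001 for zooms and shears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, expm_frechet

from .grids import VoxelGrid

logger = logging.getLogger(__name__)

__all__ = ["AffineTransform", "affine_generators", "exponential_map", "compose_mapping"]


def affine_generators() -> np.ndarray:
    """The nine ga(3) generators: rotations (x,y,z), log-zooms, shears (xy,xz,yz)."""
    B = np.zeros((9, 3, 3))
    # rotations about x, y, z
    B[0, 1, 2], B[0, 2, 1] = -1.0, 1.0
    B[1, 0, 2], B[1, 2, 0] = 1.0, -1.0
    B[2, 0, 1], B[2, 1, 0] = -1.0, 1.0
    # log-zooms
    for i in range(3):
        B[3 + i, i, i] = 1.0
    # shears xy, xz, yz (symmetric generators)
    B[6, 0, 1] = B[6, 1, 0] = 1.0
    B[7, 0, 2] = B[7, 2, 0] = 1.0
    B[8, 1, 2] = B[8, 2, 1] = 1.0
    return B

_GENERATORS = affine_generators()

# Prior variances per parameter: rotations/translations 1, zooms/shears 0.001.
PRIOR_VARIANCE = np.concatenate([np.ones(3), np.full(6, 1e-3), np.ones(3)])


def exponential_map(a: np.ndarray) -> np.ndarray:
    """T = expm(Q(a)) with Q(a) = sum_m a_m B_m; a = 0 gives the identity."""
    a = np.asarray(a, dtype=float)
    if not np.isfinite(a).all():
        raise ValueError("non-finite affine parameters")
    return expm(np.tensordot(a, _GENERATORS, axes=1))


@dataclass
class AffineTransform:
    """Nine exponential-map parameters plus a translation vector (mm)."""

    a: np.ndarray = field(default_factory=lambda: np.zeros(9))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float).reshape(9)
        self.t = np.asarray(self.t, dtype=float).reshape(3)

    @property
    def matrix(self) -> np.ndarray:
        return exponential_map(self.a)

    def as_homogeneous(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.matrix
        M[:3, 3] = self.t
        return M

    def log_prior(self) -> float:
        """Zero-mean Gaussian prior quadratic form (normalising constant dropped)."""
        p = np.concatenate([self.a, self.t])
        return -0.5 * float((p**2 / PRIOR_VARIANCE).sum())

    def copy(self) -> "AffineTransform":
        return AffineTransform(self.a.copy(), self.t.copy())


def compose_mapping(
    affine: AffineTransform,
    phi: np.ndarray,
    subject_grid: VoxelGrid,
    template_grid: VoxelGrid,
) -> np.ndarray:
    """xi = template-voxel coordinates of T phi(y) + t for every subject voxel.

    ``phi`` is the sampled diffeomorphism in subject voxel coordinates,
    shape (3, *subject_grid.shape).  The world-to-voxel conversions are folded
    into a single 3x4 matrix applied outside any loop.
    """
    if phi.shape[1:] != subject_grid.shape:
        raise ValueError("phi is not sampled on the subject grid")
    M = (
        template_grid.world_to_voxel
        @ affine.as_homogeneous()
        @ subject_grid.voxel_to_world
    )
    out = np.einsum("ab,bxyz->axyz", M[:3, :3], phi)
    return out + M[:3, 3][:, None, None, None]


def mapping_jacobian_params(
    affine: AffineTransform,
    phi: np.ndarray,
    subject_grid: VoxelGrid,
    template_grid: VoxelGrid,
) -> np.ndarray:
    """d xi / d(a, t): shape (12, 3, N) over flattened subject voxels.

    Uses the exact Frechet derivative of the matrix exponential for the nine
    exponential-map parameters.
    """
    Q = np.tensordot(affine.a, _GENERATORS, axes=1)
    A_t = template_grid.world_to_voxel[:3, :3]
    world_pts = (
        np.einsum(
            "ab,bn->an",
            subject_grid.voxel_to_world[:3, :3],
            phi.reshape(3, -1),
        )
        + subject_grid.voxel_to_world[:3, 3][:, None]
    )
    N = world_pts.shape[1]
    J = np.empty((12, 3, N))
    for m in range(9):
        _, dT = expm_frechet(Q, _GENERATORS[m])
        J[m] = (A_t @ dT) @ world_pts
    for m in range(3):
        J[9 + m] = A_t[:, m][:, None] * np.ones((1, N))
    return J


def update_affine(
    affine: AffineTransform,
    phi: np.ndarray,
    subject_grid: VoxelGrid,
    template_grid: VoxelGrid,
    matching_fn,
    max_halvings: int = 12,
) -> AffineTransform:
    """One Gauss-Newton step on the affine parameters.

    ``matching_fn(points)`` must return (value, grad, hess) of the matching
    objective (to be maximised) with per-voxel gradient (3, N) and Fisher
    curvature (3, 3, N) with respect to the template-voxel coordinates.
    The prior is included; the total objective never decreases (backtracking).
    """
    xi = compose_mapping(affine, phi, subject_grid, template_grid)
    f0, grad_pts, hess_pts = matching_fn(xi)
    f0 += affine.log_prior()
    Jp = mapping_jacobian_params(affine, phi, subject_grid, template_grid)
    g = np.einsum("pan,an->p", Jp, grad_pts.reshape(3, -1))
    H = np.einsum("pan,abn,qbn->pq", Jp, hess_pts.reshape(3, 3, -1), Jp, optimize=True)
    prior_prec = np.diag(1.0 / PRIOR_VARIANCE)
    p = np.concatenate([affine.a, affine.t])
    g -= prior_prec @ p          # gradient of log-prior
    H += prior_prec
    try:
        step = np.linalg.solve(H + 1e-9 * np.eye(12), g)
    except np.linalg.LinAlgError:
        logger.warning("singular affine system: Levenberg damping added")
        step = np.linalg.solve(H + 1e-2 * np.trace(H) / 12 * np.eye(12), g)
    alpha = 1.0
    for _ in range(max_halvings + 1):
        cand = AffineTransform(p[:9] + alpha * step[:9], p[9:] + alpha * step[9:])
        xi_c = compose_mapping(cand, phi, subject_grid, template_grid)
        f1 = matching_fn(xi_c)[0] + cand.log_prior()
        if f1 >= f0:
            return cand
        alpha *= 0.5
    return affine.copy()
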