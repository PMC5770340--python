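"""Diffeomorphic deformations from initial velocity fields.

A deformation is the endpoint of the flow  d/dt phi(y,t) = u(phi(y,t), t)
on t in [0,1], integrated by geodesic shooting: the initial momentum
m0 = (L^T L) u0 is transported by the coadjoint action of the evolving map
(conservation of momentum) and the velocity at each time step is recovered
by inverting the smoothness operator spectrally.  The operator L^T L
penalises a weighted combination of absolute displacement, membrane energy,
bending energy and linear elasticity, with circulant (periodic) boundary
conditions so that both the energy and the Green's function are diagonal
3x3 problems in the Fourier domain.

The Gauss-Newton velocity update solves (H + L^T L) delta = grad with a
preconditioned conjugate-gradient inner solver, the preconditioner being the
circulant inverse of L^T L plus the mean curvature; a backtracking line
search guarantees the objective never decreases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .grids import identity_map, interpolate_vector, jacobian_determinant

logger = logging.getLogger(__name__)

__all__ = [
    "LuOperator",
    "Diffeomorphism",
    "regularisation_energy",
    "geodesic_shoot",
    "update_velocity",
]

# absolute, membrane, bending, linear-elastic (mu, lambda), voxel units.
# Chosen so that accepted velocity fields stay in the band where the discrete
# geodesic transport is accurate (momentum pairing conserved to < 1%).
DEFAULT_WEIGHTS = (1e-2, 0.3, 64.0, 1.0, 2.0)


class LuOperator:
    """Self-adjoint smoothness operator A = L^T L on vector fields (circulant).

    Fourier symbol per frequency:
        M = (la + lm*s + lb*s^2 + mu*s) I + (mu + lam) g g^H
    with s_d = 2 - 2 cos(w_d) the 1-D Laplacian eigenvalues, s = sum_d s_d and
    g_d = exp(i w_d) - 1 the forward-difference symbol.  With la > 0 the
    operator is positive-definite.
    """

    def __init__(self, shape, weights=DEFAULT_WEIGHTS):
        la, lm, lb, mu, elam = (float(w) for w in weights)
        if min(la, lm, lb, mu, elam) < 0:
            raise ValueError("operator weights must be non-negative")
        if max(la, lm, lb, mu, elam) == 0:
            raise ValueError("at least one operator weight must be positive")
        self.shape = tuple(int(s) for s in shape)
        self.weights = (la, lm, lb, mu, elam)
        omegas = [2 * np.pi * np.fft.fftfreq(n) for n in self.shape]
        W = np.meshgrid(*omegas, indexing="ij")
        s_axes = [2.0 - 2.0 * np.cos(w) for w in W]
        s = sum(s_axes)
        g = np.stack([np.exp(1j * w) - 1.0 for w in W])  # (3, *shape)
        diag = la + lm * s + lb * s**2 + mu * s
        M = (mu + elam) * np.einsum("a...,b...->ab...", g, g.conj())
        for d in range(3):
            M[d, d] += diag
        self._symbol = M                       # (3, 3, *shape) Hermitian
        self._lap_eigs = s                     # sum_d (2 - 2 cos w_d)
        # inverse symbol (Green's function); regularised if la == 0
        Mi = np.moveaxis(M, (0, 1), (-2, -1))
        eye = np.eye(3)
        self._inv_symbol = np.moveaxis(
            np.linalg.inv(Mi + 1e-12 * eye), (-2, -1), (0, 1)
        )

    def _spectral_apply(self, u: np.ndarray, symbol: np.ndarray) -> np.ndarray:
        uh = np.fft.fftn(u, axes=(1, 2, 3))
        vh = np.einsum("ab...,b...->a...", symbol, uh)
        return np.real(np.fft.ifftn(vh, axes=(1, 2, 3)))

    def apply(self, u: np.ndarray) -> np.ndarray:
        """A u  (momentum from velocity)."""
        return self._spectral_apply(u, self._symbol)

    def greens(self, m: np.ndarray) -> np.ndarray:
        """A^-1 m  (velocity from momentum)."""
        return self._spectral_apply(m, self._inv_symbol)

    def greens_shifted(self, m: np.ndarray, shift: float) -> np.ndarray:
        """(A + shift I)^-1 m — used as a PCG preconditioner."""
        Mi = np.moveaxis(self._symbol, (0, 1), (-2, -1)) + shift * np.eye(3)
        inv = np.moveaxis(np.linalg.inv(Mi), (-2, -1), (0, 1))
        return self._spectral_apply(m, inv)

    def apodise(self, u: np.ndarray, kappa: float) -> np.ndarray:
        """Symmetric spectral low-pass exp(-kappa * laplacian-eigenvalue) per mode.

        Used to restrict Gauss-Newton search directions to the band-limited
        subspace where the discrete geodesic transport is accurate.
        """
        if kappa <= 0:
            return u
        uh = np.fft.fftn(u, axes=(1, 2, 3))
        uh *= np.exp(-kappa * self._lap_eigs)[None]
        return np.real(np.fft.ifftn(uh, axes=(1, 2, 3)))

    def sample_gaussian(self, rng: np.random.Generator) -> np.ndarray:
        """Draw u ~ N(0, (L^T L)^-1) spectrally (used by the phantom generator).

        With A = (1/N) F^H diag(M) F for a circulant operator, A^{-1/2} eps is
        ifftn( M^{-1/2} fftn(eps) ) for real white noise eps.
        """
        eps = rng.standard_normal((3,) + self.shape)
        eh = np.fft.fftn(eps, axes=(1, 2, 3))
        Mi = np.moveaxis(self._inv_symbol, (0, 1), (-2, -1))
        Mi = 0.5 * (Mi + np.conj(np.swapaxes(Mi, -1, -2)))
        evals, evecs = np.linalg.eigh(Mi)
        half = evecs @ (
            np.sqrt(np.maximum(evals, 0.0))[..., None]
            * np.swapaxes(np.conj(evecs), -1, -2)
        )
        uh = (half @ np.moveaxis(eh, 0, -1)[..., None])[..., 0]
        return np.real(np.fft.ifftn(np.moveaxis(uh, -1, 0), axes=(1, 2, 3)))


def regularisation_energy(u: np.ndarray, op: LuOperator) -> float:
    """0.5 ||L u||^2 = 0.5 u^T (L^T L) u, computed spectrally."""
    if u.shape[1:] != op.shape:
        raise ValueError("velocity grid does not match operator grid")
    return 0.5 * float(np.vdot(u, op.apply(u)).real)


@dataclass
class Diffeomorphism:
    """Sampled forward/inverse maps with Jacobian determinant fields."""

    forward: np.ndarray       # phi, (3, *shape) voxel coords
    inverse: np.ndarray       # phi^-1
    jac_det_fwd: np.ndarray
    jac_det_inv: np.ndarray
    momentum_pairing: np.ndarray = None  # <m_t, u_t> trace along the geodesic

    @property
    def shape(self):
        return self.forward.shape[1:]

    def inverse_consistency_error(self) -> float:
        """Mean |phi^-1(phi(y)) - y| in voxels."""
        comp = interpolate_vector(self.inverse - identity_map(self.shape), self.forward)
        resid = comp + self.forward - identity_map(self.shape)
        return float(np.sqrt((resid**2).sum(axis=0)).mean())


def _splat(values: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Trilinear scatter (adjoint of interpolation) of a (C, *shape) field.

    Each source voxel deposits its value at the continuous target location
    ``points[:, voxel]`` with trilinear weights; the adjoint form integrates
    rather than samples, which keeps rough momentum densities well-defined.
    """
    C = values.shape[0]
    shape = points.shape[1:]
    out = np.zeros((C,) + shape)
    p = points.reshape(3, -1)
    v = values.reshape(C, -1)
    pc = np.empty_like(p)
    for d in range(3):
        pc[d] = np.clip(p[d], 0.0, shape[d] - 1.0)
    i0 = np.minimum(np.floor(pc).astype(int), np.maximum(np.array(shape)[:, None] - 2, 0))
    f = pc - i0
    flat = out.reshape(C, -1)
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    for cx in (0, 1):
        wx = f[0] if cx else 1.0 - f[0]
        ix = np.minimum(i0[0] + cx, shape[0] - 1)
        for cy in (0, 1):
            wy = f[1] if cy else 1.0 - f[1]
            iy = np.minimum(i0[1] + cy, shape[1] - 1)
            for cz in (0, 1):
                wz = f[2] if cz else 1.0 - f[2]
                iz = np.minimum(i0[2] + cz, shape[2] - 1)
                w = wx * wy * wz
                idx = ix * strides[0] + iy * strides[1] + iz * strides[2]
                for c in range(C):
                    np.add.at(flat[c], idx, w * v[c])
    return out


def geodesic_shoot(u0: np.ndarray, op: LuOperator, steps: int = 8) -> Diffeomorphism:
    """Integrate the flow of u0 to t = 1 under conservation of momentum.

    Returns forward and inverse maps (voxel coordinates) and their Jacobian
    determinants; raises if any determinant is non-positive (too-large
    velocity or too-few steps).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    shape = u0.shape[1:]
    ident = identity_map(shape)
    if not np.any(u0):
        one = np.ones(shape)
        return Diffeomorphism(ident.copy(), ident.copy(), one, one.copy(),
                              momentum_pairing=np.zeros(steps))
    dt = 1.0 / steps
    m0 = op.apply(u0)
    m = m0.copy()
    phi = ident.copy()
    psi_disp = np.zeros_like(u0)          # psi = phi^-1 = id + psi_disp
    pairing = np.empty(steps)
    for step in range(steps):
        u = op.greens(m)
        pairing[step] = float(np.vdot(m, u).real)
        # forward flow, midpoint rule: phi += dt * u(phi + dt/2 u(phi))
        k1 = interpolate_vector(u, phi)
        k2 = interpolate_vector(u, phi + 0.5 * dt * k1)
        phi = phi + dt * k2
        # inverse: psi_{t+dt} = psi_t o (id + dt u)^-1, midpoint backtrace
        b1 = interpolate_vector(u, ident - 0.5 * dt * u)
        back = ident - dt * b1
        psi_disp = interpolate_vector(psi_disp, back) + (back - ident)
        # momentum transport (coadjoint pushforward): splat (Dphi)^-T m0 to phi(y)
        J = _jacobian_matrix(phi)
        Jinv = np.linalg.inv(np.moveaxis(J, (0, 1), (-2, -1)))
        Jinv = np.moveaxis(Jinv, (-2, -1), (0, 1))
        v = np.einsum("ba...,b...->a...", Jinv, m0)
        m = _splat(v, phi)
    jf = jacobian_determinant(phi)
    ji = jacobian_determinant(ident + psi_disp)
    if (jf <= 0).any() or (ji <= 0).any():
        raise FloatingPointError(
            "non-positive Jacobian determinant: velocity too large or too few steps"
        )
    return Diffeomorphism(phi, ident + psi_disp, jf, ji, momentum_pairing=pairing)


def _jacobian_matrix(coord_map: np.ndarray) -> np.ndarray:
    shape = coord_map.shape[1:]
    J = np.zeros((3, 3) + shape)
    for comp in range(3):
        for ax in range(3):
            if shape[ax] == 1:
                J[comp, ax] = 1.0 if comp == ax else 0.0
            else:
                J[comp, ax] = np.gradient(coord_map[comp], axis=ax)
    return J


def _det33(J: np.ndarray) -> np.ndarray:
    return (
        J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
        - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
        + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0])
    )


def update_velocity(
    u0: np.ndarray,
    op: LuOperator,
    objective_fn,
    matching_grad_hess_fn,
    chain_matrix: np.ndarray | None = None,
    steps: int = 8,
    max_cg_iter: int = 30,
    max_halvings: int = 12,
    smooth_kappa: float = 2.0,
):
    """One Gauss-Newton step on the initial velocity field.

    ``objective_fn(u)`` returns the total energy to MINIMISE, i.e.
    -(matching term) + 0.5 u^T A u, re-shooting internally.
    ``matching_grad_hess_fn(u)`` returns the per-voxel gradient (3, *shape)
    and Fisher curvature (3, 3, *shape) of -(matching term) with respect to
    the deformation, evaluated at the current shot deformation; the map from
    a velocity perturbation to a template-coordinate perturbation is the
    constant 3x3 ``chain_matrix`` (identity if None), which is exact to first
    order in u.  The linear Gauss-Newton system is solved by PCG with a
    circulant preconditioner; a backtracking line search enforces descent.

    Returns (new_u, accepted: bool).
    """
    shape = u0.shape[1:]
    R = np.eye(3) if chain_matrix is None else np.asarray(chain_matrix, dtype=float)
    g_pts, H_pts = matching_grad_hess_fn(u0)
    g = np.einsum("ba,b...->a...", R, g_pts) + op.apply(u0)
    H = np.einsum("ca,cd...,db->ab...", R, H_pts, R)
    # Levenberg floor keeps the per-voxel blocks positive-definite
    tr = np.einsum("aa...->...", H)
    damp = 1e-6 * float(tr.mean() + 1.0)
    for d in range(3):
        H[d, d] += damp

    n = u0.size

    def matvec(v):
        vf = v.reshape(u0.shape)
        out = np.einsum("ab...,b...->a...", H, vf) + op.apply(vf)
        return out.reshape(-1)

    shift = float(tr.mean()) / 3.0 + damp

    def precond(v):
        return op.greens_shifted(v.reshape(u0.shape), shift).reshape(-1)

    A = LinearOperator((n, n), matvec=matvec)
    M = LinearOperator((n, n), matvec=precond)
    # band-limit the direction symmetrically (S^1/2 (H+A)^-1 S^1/2 is SPD,
    # so the result is always a descent direction for the smoothed search)
    rhs = op.apodise(g, smooth_kappa)
    step, info = cg(A, rhs.reshape(-1), rtol=1e-4, maxiter=max_cg_iter, M=M)
    if info != 0:
        logger.info("velocity PCG not fully converged (info=%d): damped step", info)
    step = op.apodise(step.reshape(u0.shape), smooth_kappa)

    f0 = objective_fn(u0)
    alpha = 1.0
    for _ in range(max_halvings + 1):
        cand = u0 - alpha * step
        try:
            f1 = objective_fn(cand)
        except FloatingPointError:
            f1 = np.inf
        if f1 <= f0:
            return cand, True
        alpha *= 0.5
    return u0.copy(), False
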