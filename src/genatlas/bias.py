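"""Multiplicative intensity-inhomogeneity (bias) model.

The bias for each channel is the exponential of a low-order separable
DCT-II expansion, so the evaluated field is strictly positive by
construction.  Its effect on a Gaussian component is a diagonal rescaling of
the mean and covariance; the density identity

    N(x | diag(b)^-1 mu, diag(b)^-1 Sigma diag(b)^-1)
        = det(diag(b)) N(b * x | mu, Sigma)

makes bias correction and segmentation share one objective.  The smoothness
prior is a Gaussian penalty on the Laplacian of the log-field, which is
diagonal in the DCT basis (the basis functions are Neumann eigenfunctions of
the discrete Laplacian).  The update is one Gauss-Newton step with a
backtracking line search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grids import VoxelGrid

logger = logging.getLogger(__name__)

__all__ = ["BiasField", "dct_basis", "modulate_gaussian", "update_bias", "bias_objective"]


def dct_basis(n: int, order: int) -> np.ndarray:
    """Orthonormal DCT-II basis matrix, shape (n, order).

    Column m samples the m-th cosine mode at voxel centres; column 0 is the
    constant (DC) mode 1/sqrt(n).
    """
    if order > n:
        raise ValueError(f"basis order {order} exceeds axis length {n}")
    x = np.arange(n)
    B = np.empty((n, order))
    B[:, 0] = 1.0 / np.sqrt(n)
    for m in range(1, order):
        B[:, m] = np.sqrt(2.0 / n) * np.cos(np.pi * m * (2 * x + 1) / (2 * n))
    return B


def _laplacian_eigs(n: int, order: int) -> np.ndarray:
    """Eigenvalues of the (negated) discrete 1-D Laplacian for DCT modes."""
    m = np.arange(order)
    return 2.0 - 2.0 * np.cos(np.pi * m / n)


@dataclass
class BiasField:
    """Per-channel DCT log-bias coefficients on a voxel grid."""

    grid: VoxelGrid
    coeffs: np.ndarray                    # (D, n1, n2, n3) basis orders
    lam: float = 1e2                      # Laplacian-penalty weight

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim == 3:
            self.coeffs = self.coeffs[None]
        if not np.isfinite(self.coeffs).all():
            raise ValueError("non-finite bias coefficients")
        self._basis = [
            dct_basis(self.grid.shape[ax], self.coeffs.shape[1 + ax]) for ax in range(3)
        ]
        e = [_laplacian_eigs(self.grid.shape[ax], self.coeffs.shape[1 + ax]) for ax in range(3)]
        self._penalty_eigs = (
            e[0][:, None, None] + e[1][None, :, None] + e[2][None, None, :]
        ) ** 2

    @classmethod
    def zeros(cls, grid: VoxelGrid, n_channels: int, order: int | tuple = 4,
              lam: float = 1e2) -> "BiasField":
        if np.isscalar(order):
            order = tuple(min(int(order), s) for s in grid.shape)
        return cls(grid, np.zeros((n_channels,) + tuple(order)), lam)

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[0]

    def log_field(self) -> np.ndarray:
        """Log-bias field, shape (D, *grid.shape)."""
        B1, B2, B3 = self._basis
        f = np.einsum("dabc,xa,yb,zc->dxyz", self.coeffs, B1, B2, B3, optimize=True)
        if np.abs(f).max() > 700:
            raise FloatingPointError("bias exponent overflow: runaway update")
        return f

    def field(self) -> np.ndarray:
        """Evaluated bias, strictly positive, shape (D, *grid.shape)."""
        return np.exp(self.log_field())

    def penalty(self) -> float:
        """0.5 * lam * || Laplacian(log-bias) ||^2, diagonal in the DCT basis."""
        return 0.5 * self.lam * float((self._penalty_eigs[None] * self.coeffs**2).sum())

    def recentred(self) -> "BiasField":
        """Copy with the DC coefficient zeroed (mean log-bias pinned to 0).

        Only rescales every channel's field by a constant, so corrected-data
        likelihood ratios between classes are unchanged.
        """
        c = self.coeffs.copy()
        c[:, 0, 0, 0] = 0.0
        return BiasField(self.grid, c, self.lam)

    def copy(self) -> "BiasField":
        return BiasField(self.grid, self.coeffs.copy(), self.lam)


def modulate_gaussian(mu: np.ndarray, Sigma: np.ndarray, b: np.ndarray):
    """Bias-modulated Gaussian parameters (diag(b)^-1 mu, diag(b)^-1 Sigma diag(b)^-1)."""
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if (b <= 0).any():
        raise ValueError("bias must be strictly positive")
    binv = 1.0 / b
    return binv * np.atleast_1d(mu), np.atleast_2d(Sigma) * np.outer(binv, binv)


def bias_objective(
    x: np.ndarray,
    gamma: np.ndarray,
    post,
    bias: BiasField,
    observed: np.ndarray | None = None,
) -> float:
    """Lower-bound terms that depend on the bias coefficients.

    sum_jk gamma_jk [ sum_d log b_jd - 0.5 nu_k (c_j - m_k)^T W_k (c_j - m_k) ]
    minus the Laplacian penalty, with c = b * x the corrected intensities.
    Unobserved channel entries (if given) are excluded.
    """
    b = bias.field().reshape(bias.n_channels, -1).T  # (N, D)
    obs = np.ones_like(b, dtype=bool) if observed is None else observed
    c = np.where(obs, b * x, 0.0)
    logdet = np.where(obs, np.log(b), 0.0).sum(axis=1)
    total = float((gamma.sum(axis=1) * logdet).sum())
    K = post.n_classes
    for k in range(K):
        diff = np.where(obs, c - post.m[k], 0.0)
        quad = post.nu[k] * np.einsum("nd,de,ne->n", diff, post.W[k], diff)
        total -= 0.5 * float((gamma[:, k] * quad).sum())
    return total - bias.penalty()


def bias_gradient_hessian(x, gamma, post, bias: BiasField, observed=None):
    """Gradient and Gauss-Newton Hessian of -bias_objective in coefficient space.

    Returns (g, H) with g flattened over (channel, modes) and H the full
    cross-channel curvature, assembled through the separable basis.
    """
    D = bias.n_channels
    sh = bias.grid.shape
    nm = bias.coeffs.shape[1:]
    b = bias.field()                                  # (D, *sh)
    bf = b.reshape(D, -1).T                           # (N, D)
    obs = np.ones_like(bf, dtype=bool) if observed is None else observed
    c = np.where(obs, bf * x, 0.0)
    K = post.n_classes

    g_field = np.zeros((D, bf.shape[0]))              # d(-obj)/d f_jd
    h_field = np.zeros((D, D, bf.shape[0]))           # GN curvature per voxel
    for k in range(K):
        diff = np.where(obs, c - post.m[k], 0.0)
        Wd = diff @ post.W[k].T                       # (N, D): W_k (c - m_k)
        gk = gamma[:, k]
        for d in range(D):
            g_field[d] += gk * (post.nu[k] * c[:, d] * Wd[:, d] - 1.0) * obs[:, d]
        for d in range(D):
            for e in range(D):
                h_field[d, e] += (
                    gk * post.nu[k] * post.W[k][d, e] * c[:, d] * c[:, e]
                ) * (obs[:, d] & obs[:, e])

    B1, B2, B3 = bias._basis
    gf = g_field.reshape((D,) + sh)
    g = np.einsum("dxyz,xa,yb,zc->dabc", gf, B1, B2, B3, optimize=True)
    g += bias.lam * bias._penalty_eigs[None] * bias.coeffs

    n_coef = int(np.prod(nm))
    H = np.zeros((D * n_coef, D * n_coef))
    hf = h_field.reshape((D, D) + sh)
    for d in range(D):
        for e in range(D):
            t = np.einsum("xyz,xa,xA->aAyz", hf[d, e], B1, B1, optimize=True)
            t = np.einsum("aAyz,yb,yB->aAbBz", t, B2, B2, optimize=True)
            t = np.einsum("aAbBz,zc,zC->abcABC", t, B3, B3, optimize=True)
            H[d * n_coef:(d + 1) * n_coef, e * n_coef:(e + 1) * n_coef] = t.reshape(
                n_coef, n_coef
            )
    pen = (bias.lam * bias._penalty_eigs).ravel()
    for d in range(D):
        idx = np.arange(d * n_coef, (d + 1) * n_coef)
        H[idx, idx] += pen
    return g.reshape(-1), H


def update_bias(
    x: np.ndarray,
    gamma: np.ndarray,
    post,
    bias: BiasField,
    observed: np.ndarray | None = None,
    max_halvings: int = 12,
) -> BiasField:
    """One Gauss-Newton step on the bias coefficients, objective non-decreasing."""
    g, H = bias_gradient_hessian(x, gamma, post, bias, observed)
    ridge = 1e-8 * max(np.trace(H) / max(H.shape[0], 1), 1.0)
    try:
        step = np.linalg.solve(H + ridge * np.eye(H.shape[0]), g)
    except np.linalg.LinAlgError:
        logger.warning("indefinite bias Hessian: Levenberg regularisation added")
        lev = 1e-2 * np.trace(H) / H.shape[0]
        step = np.linalg.solve(H + lev * np.eye(H.shape[0]), g)
    f0 = bias_objective(x, gamma, post, bias, observed)
    alpha = 1.0
    for _ in range(max_halvings + 1):
        cand = BiasField(
            bias.grid, bias.coeffs - alpha * step.reshape(bias.coeffs.shape), bias.lam
        )
        try:
            f1 = bias_objective(x, gamma, post, cand, observed)
        except FloatingPointError:
            f1 = -np.inf
        if f1 >= f0:
            return cand
        alpha *= 0.5
    return bias.copy()
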