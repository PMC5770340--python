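"""Population tissue-probability template.

The template is a K-channel probability field on its own grid, parametrised
by first-degree B-spline (trilinear) coefficients that live on the simplex
at every voxel.  Warped class priors for a subject divide the
weight-rescaled interpolated template by its weighted sum; a Dirichlet prior
regularises the coefficients; the groupwise update pools Jacobian-weighted
pushed responsibilities from every subject and either applies the
closed-form MAP solution (all rescaling weights equal to one) or the
approximate unconstrained solution followed by projection onto the simplex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .grids import VoxelGrid, trilinear_with_gradient

logger = logging.getLogger(__name__)

__all__ = [
    "TissueTemplate",
    "DirichletPrior",
    "warped_class_prior",
    "dirichlet_log_prior",
    "update_template",
    "template_objective",
]

TEMPLATE_FLOOR = 1e-6


@dataclass
class TissueTemplate:
    """K-class probability template; coeffs shape (K, *grid.shape)."""

    grid: VoxelGrid
    coeffs: np.ndarray

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape[1:] != self.grid.shape:
            raise ValueError("template coefficients do not match grid")
        rows = self.coeffs.sum(axis=0)
        if np.abs(rows - 1.0).max() > 1e-9:
            raise ValueError("template rows must sum to 1")
        if (self.coeffs < 0).any():
            raise ValueError("template probabilities must be non-negative")

    @classmethod
    def uniform(cls, grid: VoxelGrid, K: int) -> "TissueTemplate":
        return cls(grid, np.full((K,) + grid.shape, 1.0 / K))

    @classmethod
    def from_probabilities(cls, grid: VoxelGrid, probs: np.ndarray) -> "TissueTemplate":
        p = np.maximum(np.asarray(probs, dtype=float), TEMPLATE_FLOOR)
        return cls(grid, p / p.sum(axis=0, keepdims=True))

    @property
    def n_classes(self) -> int:
        return self.coeffs.shape[0]

    def floored(self) -> np.ndarray:
        return np.maximum(self.coeffs, TEMPLATE_FLOOR)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Interpolated class probabilities at template-voxel points: (K, ...)."""
        out = np.stack(
            [trilinear_with_gradient(self.coeffs[k], points)[0] for k in range(self.n_classes)]
        )
        return out

    def sample_with_gradient(self, points: np.ndarray, centred: bool = False):
        """Interpolated values and spatial gradients at template-voxel points.

        ``centred=False`` returns the exact derivative of the piecewise-linear
        interpolant (one-sided at lattice vertices).  ``centred=True`` returns
        half-voxel central differences, which average the two adjacent cell
        slopes: the standard choice for registration search directions, since
        warped lattices frequently sit exactly on the kinks of the
        interpolant, where the one-sided slope points nowhere useful.
        """
        vals, grads = [], []
        for k in range(self.n_classes):
            v, g = trilinear_with_gradient(self.coeffs[k], points)
            if centred:
                g = np.empty_like(g)
                for d in range(3):
                    off = np.zeros((3,) + (1,) * (points.ndim - 1))
                    off[d] = 0.5
                    g[d] = (
                        trilinear_with_gradient(self.coeffs[k], points + off)[0]
                        - trilinear_with_gradient(self.coeffs[k], points - off)[0]
                    )
            vals.append(v)
            grads.append(g)
        return np.stack(vals), np.stack(grads)

    def copy(self) -> "TissueTemplate":
        return TissueTemplate(self.grid, self.coeffs.copy())


@dataclass
class DirichletPrior:
    """Conjugate prior over each template voxel's probability vector."""

    alpha0: np.ndarray

    def __post_init__(self):
        self.alpha0 = np.atleast_1d(np.asarray(self.alpha0, dtype=float))
        if (self.alpha0 <= 0).any():
            raise ValueError("alpha0 must be positive")

    @classmethod
    def near_flat(cls, K: int, value: float = 1.01) -> "DirichletPrior":
        return cls(np.full(K, value))

    def log_normaliser(self) -> float:
        return float(gammaln(self.alpha0.sum()) - gammaln(self.alpha0).sum())


def warped_class_prior(
    template: TissueTemplate,
    points: np.ndarray,
    weights: np.ndarray | None = None,
    with_gradient: bool = False,
    centred_gradient: bool = False,
):
    """Subject-space class priors  w_k pi_k(xi(y)) / sum_c w_c pi_c(xi(y)).

    ``points`` are template voxel coordinates of the warped subject lattice.
    Returns (K, ...) probabilities (rows on the simplex); with
    ``with_gradient`` also the spatial gradients of the interpolated,
    weighted, floored template (needed by the registration updates).
    """
    K = template.n_classes
    w = np.ones(K) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("mixing weights must be positive")
    if with_gradient:
        vals, grads = template.sample_with_gradient(points, centred=centred_gradient)
    else:
        vals = template.sample(points)
    vals = np.maximum(vals, TEMPLATE_FLOOR)
    wk = w.reshape((K,) + (1,) * (vals.ndim - 1))
    num = wk * vals
    denom = num.sum(axis=0)
    probs = num / denom
    if with_gradient:
        return probs, num, wk[:, None] * grads
    return probs


def dirichlet_log_prior(template: TissueTemplate, prior: DirichletPrior) -> float:
    """sum_j [ log C(alpha0) + sum_k (alpha0_k - 1) log pi_jk ]."""
    pi = template.floored()
    if (template.coeffs < TEMPLATE_FLOOR).any():
        logger.debug(
            "clamped %d template entries at the floor before log",
            int((template.coeffs < TEMPLATE_FLOOR).sum()),
        )
    a = prior.alpha0.reshape((-1,) + (1,) * 3)
    per_voxel = ((a - 1.0) * np.log(pi)).sum(axis=0)
    return float(per_voxel.sum() + template.grid.n_voxels * prior.log_normaliser())


def template_objective(
    pi: np.ndarray,
    pushed: list[np.ndarray],
    weights: list[np.ndarray],
    prior: DirichletPrior,
) -> np.ndarray:
    """Per-voxel pooled matching objective plus Dirichlet term.

    sum_i sum_k N_ijk log( w_ik pi_jk / sum_c w_ic pi_jc ) + sum_k (a0k-1) log pi_jk
    where ``pushed[i]`` holds the det-weighted pushed responsibilities N_ijk.
    """
    pi = np.maximum(pi, TEMPLATE_FLOOR)
    logpi = np.log(pi)
    a = prior.alpha0.reshape((-1,) + (1,) * (pi.ndim - 1))
    out = ((a - 1.0) * logpi).sum(axis=0)
    for Ni, wi in zip(pushed, weights):
        wk = np.asarray(wi).reshape((-1,) + (1,) * (pi.ndim - 1))
        denom = (wk * pi).sum(axis=0)
        out = out + (Ni * (np.log(wk) + logpi - np.log(denom)[None])).sum(axis=0)
    return out


def update_template(
    template: TissueTemplate,
    pushed: list[np.ndarray],
    weights: list[np.ndarray],
    prior: DirichletPrior,
) -> TissueTemplate:
    """Groupwise MAP template update from pushed responsibilities.

    With all rescaling weights equal to one this is the exact closed form
    pi_jk = (N_jk + alpha0_k - 1) / (sum_c (N_jc + alpha0_c) - K); otherwise
    the approximate unconstrained stationary point is computed treating the
    per-voxel weighted normaliser as constant and then projected back onto
    the simplex.  Voxels where the pooled objective would decrease keep their
    previous value.
    """
    K = template.n_classes
    a0 = prior.alpha0
    Ntot = np.zeros((K,) + template.grid.shape)
    for Ni in pushed:
        Ntot += Ni
    all_unit = all(np.all(np.asarray(w) == 1.0) for w in weights)
    if all_unit:
        # exact closed form: pi_jk = (N_jk + a0_k - 1) / (sum_c (N_jc + a0_c) - K)
        num = Ntot + (a0 - 1.0).reshape((-1,) + (1,) * 3)
        denom = (Ntot + a0.reshape((-1,) + (1,) * 3)).sum(axis=0) - K
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = num / denom
        # repair only degenerate voxels so the closed form is untouched elsewhere
        bad = (denom <= 0) | (pi < 0).any(axis=0) | ~np.isfinite(pi).all(axis=0)
        if bad.any():
            logger.info("uniform row substituted at %d voxels", int(bad.sum()))
            pi[:, bad] = 1.0 / K
        return TissueTemplate(template.grid, pi)

    old = template.floored()
    denom_field = np.zeros((K,) + template.grid.shape)
    for Ni, wi in zip(pushed, weights):
        wk = np.asarray(wi).reshape((-1,) + (1,) * 3)
        S = (wk * old).sum(axis=0)               # treated as constant
        mass = Ni.sum(axis=0)                    # sum_k N_ijk
        denom_field += mass[None] * wk / S[None]
    num = np.maximum(Ntot + (a0 - 1.0).reshape((-1,) + (1,) * 3), TEMPLATE_FLOOR)
    # derivative-consistent simplex solution: pi_k = num_k / (D_k + lambda)
    # with the per-voxel Lagrange multiplier solved by Newton iteration
    lam = num.sum(axis=0) - denom_field.mean(axis=0)
    lam = np.maximum(lam, -denom_field.min(axis=0) + 1e-9 * (1.0 + np.abs(lam)))
    for _ in range(50):
        denom = denom_field + lam[None]
        S1 = (num / denom).sum(axis=0)
        S2 = (num / denom**2).sum(axis=0)
        delta = (S1 - 1.0) / np.maximum(S2, 1e-300)
        new_lam = lam + delta
        low = -denom_field.min(axis=0)
        new_lam = np.where(new_lam <= low, 0.5 * (lam + low), new_lam)
        if np.abs(new_lam - lam).max() < 1e-12 * (1.0 + np.abs(lam).max()):
            lam = new_lam
            break
        lam = new_lam
    pi_bar = num / (denom_field + lam[None])
    pi_bar = np.where(np.isfinite(pi_bar), pi_bar, 1.0 / K)
    pi_bar = np.maximum(pi_bar, TEMPLATE_FLOOR)
    pi = pi_bar / pi_bar.sum(axis=0, keepdims=True)

    f_new = template_objective(pi, pushed, weights, prior)
    f_old = template_objective(old, pushed, weights, prior)
    worse = f_new < f_old - 1e-12
    if worse.any():
        logger.debug("template update rejected at %d voxels", int(worse.sum()))
        pi[:, worse] = old[:, worse] / old[:, worse].sum(axis=0, keepdims=True)
    pi = np.maximum(pi, TEMPLATE_FLOOR)
    pi /= pi.sum(axis=0, keepdims=True)
    return TissueTemplate(template.grid, pi)


def smooth_template(template: TissueTemplate, fwhm_voxels: float = 0.0) -> TissueTemplate:
    """Optional mild smoothing of log-coefficients between outer iterations.

    Off (identity) when fwhm is zero; otherwise smooths log-probabilities
    with a Gaussian kernel and renormalises, preserving the simplex.
    """
    if fwhm_voxels <= 0:
        return template
    from scipy.ndimage import gaussian_filter

    sigma = fwhm_voxels / np.sqrt(8.0 * np.log(2.0))
    logp = np.log(template.floored())
    sm = np.stack(
        [gaussian_filter(logp[k], sigma=sigma, mode="nearest") for k in range(template.n_classes)]
    )
    p = np.exp(sm - sm.max(axis=0, keepdims=True))
    p = np.maximum(p, TEMPLATE_FLOOR)
    p /= p.sum(axis=0, keepdims=True)
    return TissueTemplate(template.grid, p)
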