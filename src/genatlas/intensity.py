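"""Variational Bayes Gaussian mixture over channel intensities.

Each subject's intensity distribution is a K-component multivariate Gaussian
mixture whose means and precisions carry conjugate Gaussian-Wishart priors
shared across the population.  The E-step uses the variational expected
log-densities (digamma / log-determinant corrections), the M-step the
standard conjugate updates from responsibility-weighted sufficient
statistics of bias-corrected intensities, and the population prior is
re-estimated by empirical Bayes.  Voxels with missing channels are handled
through a variational posterior over the unobserved intensities, which
amounts to conditional-Gaussian imputation plus a covariance correction in
the second-moment statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import digamma, gammaln, logsumexp

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)
_DENSITY_FLOOR = 1e-300


@dataclass
class GaussWishartPrior:
    """Population-level conjugate prior: per class k, N(m0, (beta0 L)^-1) W(W0, nu0)."""

    m0: np.ndarray      # (K, D)
    beta0: np.ndarray   # (K,)
    W0: np.ndarray      # (K, D, D)
    nu0: np.ndarray     # (K,)

    def __post_init__(self):
        self.m0 = np.atleast_2d(np.asarray(self.m0, dtype=float))
        self.beta0 = np.atleast_1d(np.asarray(self.beta0, dtype=float))
        self.W0 = np.asarray(self.W0, dtype=float)
        if self.W0.ndim == 2:
            self.W0 = self.W0[None]
        self.nu0 = np.atleast_1d(np.asarray(self.nu0, dtype=float))
        K, D = self.m0.shape
        if (self.beta0 <= 0).any():
            raise ValueError("beta0 must be positive")
        if (self.nu0 <= D - 1).any():
            raise ValueError("nu0 must exceed D - 1")
        for k in range(K):
            np.linalg.cholesky(self.W0[k])  # SPD check

    @property
    def n_classes(self) -> int:
        return self.m0.shape[0]

    @property
    def n_channels(self) -> int:
        return self.m0.shape[1]

    def copy(self) -> "GaussWishartPrior":
        return GaussWishartPrior(self.m0.copy(), self.beta0.copy(),
                                 self.W0.copy(), self.nu0.copy())


class MixturePosterior(GaussWishartPrior):
    """Subject-specific variational posterior q(mu, Lambda); same parametrisation."""

    @property
    def m(self):
        return self.m0

    @property
    def beta(self):
        return self.beta0

    @property
    def W(self):
        return self.W0

    @property
    def nu(self):
        return self.nu0

    def expected_precision(self) -> np.ndarray:
        """E[Lambda_k] = nu_k W_k, shape (K, D, D)."""
        return self.nu[:, None, None] * self.W

    def expected_log_det_precision(self) -> np.ndarray:
        K, D = self.m.shape
        out = np.empty(K)
        for k in range(K):
            sign, logdet = np.linalg.slogdet(self.W[k])
            out[k] = (
                digamma(0.5 * (self.nu[k] - np.arange(D))).sum()
                + D * np.log(2.0)
                + logdet
            )
        return out


def expected_log_densities(x: np.ndarray, post: MixturePosterior) -> np.ndarray:
    """E_q[log N(x_j | mu_k, Lambda_k^-1)] for complete rows x (N, D) -> (N, K)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    N, D = x.shape
    K = post.n_classes
    elogdet = post.expected_log_det_precision()
    out = np.empty((N, K))
    for k in range(K):
        diff = x - post.m[k]
        quad = post.nu[k] * np.einsum("nd,de,ne->n", diff, post.W[k], diff)
        out[:, k] = 0.5 * (elogdet[k] - D * LOG2PI - D / post.beta[k] - quad)
    return out


def e_step_unsupervised(
    log_dens: np.ndarray,
    log_prior: np.ndarray,
) -> np.ndarray:
    """Responsibilities from per-voxel expected log-densities and log class priors.

    ``log_dens`` must already include the log det(diag(b)) bias term for
    bias-modulated data.  Computation is entirely in the log domain.
    """
    logr = log_dens + log_prior
    logr -= logsumexp(logr, axis=1, keepdims=True)
    gamma = np.exp(logr)
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma


def sufficient_statistics(x: np.ndarray, gamma: np.ndarray):
    """Responsibility-weighted count, sum and raw scatter for complete data.

    Returns (Nk (K,), s1 (K, D), S2 (K, D, D)) with S2 the weighted sum of
    x x^T (raw second moments, not centred).
    """
    Nk = gamma.sum(axis=0)
    s1 = gamma.T @ x
    S2 = np.einsum("nk,nd,ne->kde", gamma, x, x)
    return Nk, s1, S2


def missing_data_statistics(
    x: np.ndarray,
    observed: np.ndarray,
    gamma: np.ndarray,
    post: MixturePosterior,
):
    """Augmented sufficient statistics when some channels are unobserved.

    For each voxel and class, missing channels are replaced by their
    conditional expectation given the observed ones under the class posterior
    mean parameters (mean m_k, covariance (nu_k W_k)^-1), and the raw second
    moments gain the conditional covariance.  Voxels with no observed channel
    are excluded (counted in the log).  With nothing missing the result equals
    :func:`sufficient_statistics` exactly.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    observed = np.asarray(observed, dtype=bool)
    N, D = x.shape
    K = post.n_classes

    none_obs = ~observed.any(axis=1)
    if none_obs.any():
        logger.info("excluding %d voxels with no observed channel", int(none_obs.sum()))
        keep = ~none_obs
        x, observed, gamma = x[keep], observed[keep], gamma[keep]
        N = x.shape[0]

    if observed.all():
        return sufficient_statistics(np.where(observed, x, 0.0), gamma)

    cov = np.linalg.inv(post.expected_precision())  # (K, D, D)
    Nk = gamma.sum(axis=0)
    s1 = np.zeros((K, D))
    S2 = np.zeros((K, D, D))
    patterns = {}
    for n in range(N):
        patterns.setdefault(tuple(observed[n]), []).append(n)
    for pat, idx in patterns.items():
        idx = np.asarray(idx)
        o = np.asarray(pat)
        m = ~o
        xo = x[np.ix_(idx, np.where(o)[0])]
        for k in range(K):
            g = gamma[idx, k]
            xhat = np.zeros((len(idx), D))
            xhat[:, o] = xo
            corr = np.zeros((D, D))
            if m.any():
                Soo = cov[k][np.ix_(o, o)]
                Smo = cov[k][np.ix_(m, o)]
                Smm = cov[k][np.ix_(m, m)]
                sol = np.linalg.solve(Soo, (xo - post.m[k][o]).T).T
                xhat[:, m] = post.m[k][m] + sol @ Smo.T
                corr[np.ix_(m, m)] = Smm - Smo @ np.linalg.solve(Soo, Smo.T)
            s1[k] += g @ xhat
            S2[k] += np.einsum("n,nd,ne->de", g, xhat, xhat) + g.sum() * corr
    return Nk, s1, S2


def m_step(Nk, s1, S2, prior: GaussWishartPrior) -> MixturePosterior:
    """Conjugate Gaussian-Wishart update from sufficient statistics."""
    K, D = prior.m0.shape
    if not (np.isfinite(Nk).all() and np.isfinite(s1).all() and np.isfinite(S2).all()):
        raise ValueError("non-finite sufficient statistics")
    if (np.asarray(Nk) < -1e-9).any():
        raise ValueError("negative responsibility mass")
    beta = prior.beta0 + Nk
    nu = prior.nu0 + Nk
    m = np.empty((K, D))
    W = np.empty((K, D, D))
    for k in range(K):
        if Nk[k] > 1e-12:
            xbar = s1[k] / Nk[k]
            Sk = S2[k] / Nk[k] - np.outer(xbar, xbar)
        else:
            xbar = prior.m0[k]
            Sk = np.zeros((D, D))
        m[k] = (prior.beta0[k] * prior.m0[k] + Nk[k] * xbar) / beta[k]
        diff = xbar - prior.m0[k]
        Winv = (
            np.linalg.inv(prior.W0[k])
            + Nk[k] * Sk
            + (prior.beta0[k] * Nk[k] / beta[k]) * np.outer(diff, diff)
        )
        Winv = 0.5 * (Winv + Winv.T)
        W[k] = np.linalg.inv(Winv)
        W[k] = 0.5 * (W[k] + W[k].T)
    return MixturePosterior(m, beta, W, nu)


def update_mixing_weights(
    gamma: np.ndarray,
    template_probs: np.ndarray,
    w_init: np.ndarray | None = None,
    n_iter: int = 20,
    tol: float = 1e-10,
) -> np.ndarray:
    """Per-subject positive class rescalings of the warped template priors.

    Maximises sum_j sum_k gamma_jk log( w_k p_jk / sum_c w_c p_jc ) over w > 0
    by a multiplicative fixed-point iteration; the objective is invariant to a
    global rescaling of w, so the result is normalised to mean 1.
    """
    p = np.asarray(template_probs, dtype=float)
    K = p.shape[1]
    G = gamma.sum(axis=0)
    w = np.ones(K) if w_init is None else np.asarray(w_init, dtype=float).copy()
    mass = p.sum(axis=0)
    dead = mass <= 0
    if dead.any():
        logger.warning("classes with zero template mass: weights pinned to 1")
    for _ in range(n_iter):
        denom = p @ w
        s = (p * w) / denom[:, None]
        S = s.sum(axis=0)
        new = np.where(S > 0, w * G / np.maximum(S, 1e-300), w)
        new[dead] = 1.0
        new = np.maximum(new, 1e-12)
        new /= new.mean()
        if np.abs(new - w).max() < tol:
            w = new
            break
        w = new
    return w


def weight_objective(gamma: np.ndarray, template_probs: np.ndarray, w: np.ndarray) -> float:
    """The matching-term share that depends on the mixing weights."""
    p = np.asarray(template_probs, dtype=float)
    num = np.log(np.maximum(p * w, _DENSITY_FLOOR))
    denom = np.log(np.maximum(p @ w, _DENSITY_FLOOR))
    return float((gamma * num).sum() - denom.sum())


def _log_wishart_B(W: np.ndarray, nu: float) -> float:
    D = W.shape[0]
    sign, logdet = np.linalg.slogdet(W)
    return (
        -0.5 * nu * logdet
        - 0.5 * nu * D * np.log(2.0)
        - 0.25 * D * (D - 1) * np.log(np.pi)
        - gammaln(0.5 * (nu - np.arange(D))).sum()
    )


def expected_log_prior_density(post: MixturePosterior, prior: GaussWishartPrior) -> float:
    """sum_k E_q[log p(mu_k, Lambda_k | prior)]; cross term of the lower bound."""
    K, D = prior.m0.shape
    elogdet = post.expected_log_det_precision()
    total = 0.0
    for k in range(K):
        diff = post.m[k] - prior.m0[k]
        equad = D / post.beta[k] + post.nu[k] * diff @ post.W[k] @ diff
        total += 0.5 * (
            D * np.log(prior.beta0[k] / (2 * np.pi))
            + elogdet[k]
            - prior.beta0[k] * equad
        )
        total += (
            _log_wishart_B(prior.W0[k], prior.nu0[k])
            + 0.5 * (prior.nu0[k] - D - 1) * elogdet[k]
            - 0.5 * np.trace(np.linalg.solve(prior.W0[k], post.nu[k] * post.W[k]))
        )
    return float(total)


def entropy_q(post: MixturePosterior) -> float:
    """Entropy of the Gaussian-Wishart variational posterior q(mu, Lambda)."""
    K, D = post.m.shape
    elogdet = post.expected_log_det_precision()
    total = 0.0
    for k in range(K):
        # Gaussian part: H[N(m, (beta Lambda)^-1)] under E[log det Lambda]
        total += 0.5 * (D * (1 + LOG2PI) - D * np.log(post.beta[k]) - elogdet[k])
        # Wishart part
        lB = _log_wishart_B(post.W[k], post.nu[k])
        total += (
            -lB
            - 0.5 * (post.nu[k] - D - 1) * elogdet[k]
            + 0.5 * post.nu[k] * D
        )
    return float(total)


def update_empirical_priors(
    posteriors: list[MixturePosterior],
    prior: GaussWishartPrior,
    n_sweeps: int = 4,
) -> GaussWishartPrior:
    """Empirical-Bayes update of the population Gauss-Wishart hyperparameters.

    Maximises sum_i E_{q_i}[log p(mu_i, Lambda_i | m0, beta0, W0, nu0)] per
    class.  m0, beta0 and W0 have closed forms; nu0 is a 1-D concave search,
    clamped above D - 1 + 1e-3.
    """
    M = len(posteriors)
    if M < 2:
        logger.info("fewer than 2 subjects: prior left unchanged")
        return prior.copy()
    K, D = prior.m0.shape
    new = prior.copy()
    for k in range(K):
        nus = np.array([p.nu[k] for p in posteriors])
        Ws = np.array([p.W[k] for p in posteriors])
        ms = np.array([p.m[k] for p in posteriors])
        betas = np.array([p.beta[k] for p in posteriors])
        elogdets = np.array([p.expected_log_det_precision()[k] for p in posteriors])
        EL = nus[:, None, None] * Ws                       # E[Lambda_i]
        sumEL = EL.sum(axis=0)
        nu0 = max(new.nu0[k], D - 1 + 1e-3)
        for _ in range(n_sweeps):
            # m0: generalised least squares under expected precisions
            m0 = np.linalg.solve(sumEL, np.einsum("ide,ie->d", EL, ms))
            # beta0
            equad = np.array(
                [D / betas[i] + (ms[i] - m0) @ EL[i] @ (ms[i] - m0) for i in range(M)]
            )
            beta0 = M * D / equad.sum()
            # W0 given nu0
            W0 = sumEL / (M * nu0)
            # nu0: 1-D maximisation
            sign, logdetS = np.linalg.slogdet(sumEL / M)

            def neg(nu0_):
                # with W0(nu0) = (sumEL/M)/nu0 plugged in
                logdetW0 = logdetS - D * np.log(nu0_)
                val = M * (
                    -0.5 * nu0_ * D * np.log(2.0)
                    - 0.5 * nu0_ * logdetW0
                    - gammaln(0.5 * (nu0_ - np.arange(D))).sum()
                ) + 0.5 * (nu0_ - D - 1) * elogdets.sum() - 0.5 * M * nu0_ * D
                return -val

            res = minimize_scalar(
                neg, bounds=(D - 1 + 1e-3, 1e6), method="bounded",
                options={"xatol": 1e-6},
            )
            nu0 = float(res.x)
            W0 = sumEL / (M * nu0)
        new.m0[k] = m0
        new.beta0[k] = beta0
        new.W0[k] = 0.5 * (W0 + W0.T)
        new.nu0[k] = nu0
    return new
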