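"""Joint model of a population of MR volumes and its coordinate-ascent fit.

`AtlasModel` holds the data (one multi-channel volume per subject, optional
integer label maps) and the configuration; `fit()` runs the single-objective
coordinate ascent — per subject: variational E-step (routing labelled and
unlabelled voxels), conjugate mixture M-step, Gauss-Newton bias, affine and
initial-velocity updates; per outer iteration: groupwise template update and
empirical-Bayes intensity-prior update — and returns an `AtlasResults`
carrying the template, per-subject states, the evidence lower bound trace
and diagnostics.  Every accepted update must not decrease the lower bound;
a decrease beyond slack raises an error naming the offending update.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import affine as aff
from . import bias as bias_mod
from . import diffeo
from . import intensity as intens
from . import supervision
from . import template as tpl_mod
from .grids import (
    ImageVolume,
    LabelMap,
    VoxelGrid,
    identity_map,
    interpolate_vector,
    jacobian_determinant,
    push_weighted,
    read_labels,
    read_volume,
    write_volume,
)

logger = logging.getLogger(__name__)

__all__ = ["AtlasConfig", "AtlasModel", "AtlasResults", "SubjectState"]

BOUND_SLACK = 1e-6  # relative slack for the monotonicity tripwire


@dataclass
class AtlasConfig:
    """Run configuration; defaults follow the package's standard settings."""

    n_classes: int = 12
    alpha0: float = 1.01
    zeta: float = 0.9
    bias_order: int = 4
    lambda_bias: float = 1e2
    reg_weights: tuple = diffeo.DEFAULT_WEIGHTS
    shoot_steps: int = 8
    affine_warmup: int = 3
    max_outer: int = 30
    tol: float = 1e-4
    seed: int = 0
    label_class_map: dict = field(default_factory=dict)  # label -> list of class idx
    update_bias: bool = True
    update_affine: bool = True
    update_velocity: bool = True
    update_weights: bool = True
    update_template: bool = True
    update_intensity_prior: bool = True
    template_smooth_fwhm: float = 0.0
    hard_labels: bool = False   # zeta = 1 behaviour (one-hot labelled rows)
    velocity_smooth_kappa: float = 2.0  # band-limit of velocity search directions

    @classmethod
    def from_yaml(cls, path) -> "AtlasConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown configuration keys: {sorted(bad)}")
        if "label_class_map" in raw:
            raw["label_class_map"] = {int(k): list(v) for k, v in raw["label_class_map"].items()}
        if "reg_weights" in raw:
            raw["reg_weights"] = tuple(raw["reg_weights"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reg_weights"] = list(self.reg_weights)
        return d


@dataclass
class SubjectState:
    """All per-subject factors of the model."""

    image: ImageVolume
    labels: LabelMap | None
    posterior: intens.MixturePosterior
    weights: np.ndarray
    bias: bias_mod.BiasField
    affine: aff.AffineTransform
    velocity: np.ndarray
    diffeo: diffeo.Diffeomorphism | None = None
    gamma: np.ndarray | None = None       # (N, K)

    @property
    def x_flat(self) -> np.ndarray:
        return self.image.data.reshape(self.image.n_channels, -1).T

    @property
    def observed_flat(self) -> np.ndarray:
        return self.image.observed_mask.reshape(self.image.n_channels, -1).T


def _expected_log_densities_masked(c, obs, post):
    """Expected log-densities honouring missing channels.

    Fully observed rows use the exact variational expectation; partially
    observed rows use the marginal Gaussian over the observed channels at the
    posterior mean parameters with the 1/beta broadening, a variational
    treatment of the unobserved intensities.
    """
    N, D = c.shape
    K = post.n_classes
    if obs.all():
        return intens.expected_log_densities(c, post)
    out = np.zeros((N, K))
    full = obs.all(axis=1)
    if full.any():
        out[full] = intens.expected_log_densities(c[full], post)
    part = ~full
    idx_part = np.where(part)[0]
    cov = np.linalg.inv(post.expected_precision())
    patterns = {}
    for n in idx_part:
        patterns.setdefault(tuple(obs[n]), []).append(n)
    for pat, idx in patterns.items():
        idx = np.asarray(idx)
        o = np.asarray(pat)
        Do = int(o.sum())
        if Do == 0:
            out[idx] = 0.0  # no intensity evidence
            continue
        xo = c[np.ix_(idx, np.where(o)[0])]
        for k in range(K):
            Soo = cov[k][np.ix_(o, o)]
            L = np.linalg.cholesky(Soo)
            diff = xo - post.m[k][o]
            sol = np.linalg.solve(L, diff.T)
            quad = (sol**2).sum(axis=0)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            out[idx, k] = -0.5 * (
                logdet + Do * intens.LOG2PI + Do / post.beta[k] + quad
            )
    return out


def matching_terms(
    template: tpl_mod.TissueTemplate,
    points: np.ndarray,
    weights: np.ndarray,
    gamma_field: np.ndarray,
    want_derivs: bool = True,
    centred_gradient: bool = False,
):
    """Value, per-point gradient and Fisher curvature of the matching term.

    The matching term is sum_j sum_k gamma_jk log prior_jk with prior the
    warped, weight-rescaled template; derivatives are with respect to the
    template-voxel coordinates of each point.  ``gamma_field`` has shape
    (K, *points.shape[1:]).  The Fisher curvature is the expected Hessian of
    the negative matching term (positive semi-definite 3x3 blocks).

    ``centred_gradient`` switches the template spatial gradients from the
    exact interpolant derivative to half-voxel central differences (used for
    registration search directions; warped lattices often sit exactly on the
    interpolant's kinks, where the one-sided slope locks the optimiser).
    """
    K = template.n_classes
    probs, num, grads = tpl_mod.warped_class_prior(
        template, points, weights, with_gradient=True,
        centred_gradient=centred_gradient,
    )
    # gradient of log(max(pi, floor)) vanishes where floored
    raw = num / np.asarray(weights).reshape((K,) + (1,) * (points.ndim - 1))
    floored = raw <= tpl_mod.TEMPLATE_FLOOR
    grads = np.where(floored[:, None], 0.0, grads)
    logprior = np.log(probs)
    value = float((gamma_field * logprior).sum())
    if not want_derivs:
        return value, None, None
    b = grads / num[:, None]                          # (K, 3, ...)
    B = (probs[:, None] * b).sum(axis=0)              # (3, ...)
    grad = (gamma_field[:, None] * b).sum(axis=0) - B  # ascent gradient
    fisher = np.einsum("ka...,kb...->ab...", probs[:, None] * b, b)
    fisher -= np.einsum("a...,b...->ab...", B, B)
    return value, grad, fisher


class AtlasModel:
    """Generative groupwise model over a list of subject volumes."""

    def __init__(
        self,
        volumes: list[ImageVolume],
        labels: list[LabelMap | None] | None = None,
        config: AtlasConfig | None = None,
        template_grid: VoxelGrid | None = None,
        template: tpl_mod.TissueTemplate | None = None,
        intensity_prior: intens.GaussWishartPrior | None = None,
    ):
        if not volumes:
            raise ValueError("at least one subject volume is required")
        self.config = config or AtlasConfig()
        self.volumes = volumes
        self.labels = labels or [None] * len(volumes)
        if len(self.labels) != len(volumes):
            raise ValueError("labels list length must match volumes")
        K = self.config.n_classes
        if template is not None:
            self.template = template.copy()
        else:
            grid = template_grid or self._default_template_grid()
            self.template = tpl_mod.TissueTemplate.uniform(grid, K)
        self.dirichlet = tpl_mod.DirichletPrior.near_flat(K, self.config.alpha0)
        self.intensity_prior = intensity_prior
        self._frozen_template = template is not None
        self._frozen_prior = intensity_prior is not None

    @classmethod
    def from_paths(cls, image_paths, label_paths=None, config=None, **kw) -> "AtlasModel":
        vols = [read_volume(p) for p in image_paths]
        labs = None
        if label_paths:
            labs = [read_labels(p) if p else None for p in label_paths]
        return cls(vols, labs, config, **kw)

    # ------------------------------------------------------------------ setup

    def _default_template_grid(self) -> VoxelGrid:
        shapes = np.array([v.grid.shape for v in self.volumes])
        return VoxelGrid(tuple(int(s) for s in shapes.mean(axis=0).round()),
                         self.volumes[0].grid.voxel_to_world)

    def _initial_prior(self) -> intens.GaussWishartPrior:
        K = self.config.n_classes
        rows = []
        for v in self.volumes:
            x = v.data.reshape(v.n_channels, -1).T
            ok = v.observed_mask.reshape(v.n_channels, -1).T.all(axis=1)
            rows.append(x[ok])
        pooled = np.concatenate(rows, axis=0)
        D = pooled.shape[1]
        gmean = pooled.mean(axis=0)
        gcov = np.cov(pooled.T).reshape(D, D) + 1e-6 * np.eye(D)
        # spread prior means over K quantiles of the pooled channel average
        score = pooled.mean(axis=1)
        qs = np.quantile(score, (np.arange(K) + 0.5) / K)
        m0 = np.empty((K, D))
        for k in range(K):
            m0[k] = gmean + (qs[k] - score.mean()) * np.ones(D)
        nu0 = np.full(K, D + 2.0)
        W0 = np.stack([np.linalg.inv(gcov * K) / nu0[k] for k in range(K)])
        return intens.GaussWishartPrior(m0, np.full(K, 1e-2), W0, nu0)

    def _initial_subject(self, i: int, prior: intens.GaussWishartPrior) -> SubjectState:
        cfg = self.config
        v = self.volumes[i]
        K = cfg.n_classes
        x = v.data.reshape(v.n_channels, -1).T
        obs = v.observed_mask.reshape(v.n_channels, -1).T
        score = np.where(obs, x, np.nan)
        score = np.nanmean(score, axis=1)
        score = np.where(np.isfinite(score), score, np.nanmean(score))
        if self._frozen_template:
            # a fixed template carries the class identities: start from its
            # priors at the initial (identity) pose
            pts = aff.compose_mapping(aff.AffineTransform(),
                                      identity_map(v.grid.shape),
                                      v.grid, self.template.grid)
            probs = tpl_mod.warped_class_prior(self.template, pts)
            gamma0 = probs.reshape(K, -1).T.copy()
        else:
            edges = np.quantile(score, np.linspace(0, 1, K + 1))
            gamma0 = np.full((x.shape[0], K), 1e-3)
            bins = np.clip(np.searchsorted(edges[1:-1], score), 0, K - 1)
            gamma0[np.arange(x.shape[0]), bins] = 1.0
        # manual labels fix the class identities from the start: without this
        # a quantile initialisation can permute classes against the labels,
        # which sharp intensity posteriors then cement
        if self.labels[i] is not None:
            lab = self.labels[i].labels.reshape(-1)
            zeta = 1.0 if cfg.hard_labels else cfg.zeta
            rater = supervision.RaterModel(zeta=max(zeta, 1.0 / K + 1e-9), K=K)
            for l in np.unique(lab[lab > 0]):
                subset = cfg.label_class_map.get(int(l))
                subset = tuple(subset) if subset else None
                gamma0[lab == l] = supervision.label_prior(int(l), rater, subset)
        gamma0 /= gamma0.sum(axis=1, keepdims=True)
        stats = intens.missing_data_statistics(x, obs, gamma0, _posterior_from(prior))
        post = intens.m_step(*stats, prior)
        return SubjectState(
            image=v,
            labels=self.labels[i],
            posterior=post,
            weights=np.ones(K),
            bias=bias_mod.BiasField.zeros(v.grid, v.n_channels, cfg.bias_order, cfg.lambda_bias),
            affine=aff.AffineTransform(),
            velocity=np.zeros((3,) + v.grid.shape),
        )

    # ------------------------------------------------------------- geometry

    def _operator(self, grid: VoxelGrid) -> diffeo.LuOperator:
        return diffeo.LuOperator(grid.shape, self.config.reg_weights)

    def _shoot(self, s: SubjectState) -> diffeo.Diffeomorphism:
        op = self._operator(s.image.grid)
        return diffeo.geodesic_shoot(s.velocity, op, self.config.shoot_steps)

    def _refresh_warp(self, s: SubjectState) -> None:
        s.diffeo = self._shoot(s)

    def _xi_points(self, s: SubjectState, phi: np.ndarray | None = None) -> np.ndarray:
        phi = s.diffeo.forward if phi is None else phi
        return aff.compose_mapping(s.affine, phi, s.image.grid, self.template.grid)

    def _xi_inverse(self, s: SubjectState):
        """Inverse warp sampled on the template grid + its Jacobian determinant."""
        tgrid = self.template.grid
        M = (
            np.linalg.inv(s.affine.as_homogeneous() @ s.image.grid.voxel_to_world)
            @ tgrid.voxel_to_world
        )
        x = identity_map(tgrid.shape)
        z = np.einsum("ab,bxyz->axyz", M[:3, :3], x) + M[:3, 3][:, None, None, None]
        disp = s.diffeo.inverse - identity_map(s.image.grid.shape)
        xi_inv = z + interpolate_vector(disp, z)
        det = jacobian_determinant(xi_inv)
        det = np.maximum(det, 1e-12)
        return xi_inv, det

    # ------------------------------------------------------------- matching

    def _matching_terms(self, s: SubjectState, points: np.ndarray, want_derivs=True,
                        centred_gradient=False):
        gam = s.gamma.T.reshape((self.template.n_classes,) + points.shape[1:])
        return matching_terms(self.template, points, s.weights, gam, want_derivs,
                              centred_gradient=centred_gradient)

    def _matching_fn(self, s: SubjectState):
        def fn(points):
            v, g, H = self._matching_terms(s, points)
            return v, g, H
        return fn

    # ----------------------------------------------------------------- E/M

    def _log_prior_rows(self, s: SubjectState) -> np.ndarray:
        pts = self._xi_points(s)
        probs = tpl_mod.warped_class_prior(self.template, pts, s.weights)
        return np.log(probs.reshape(self.config.n_classes, -1).T)

    def _log_dens_rows(self, s: SubjectState) -> np.ndarray:
        b = s.bias.field().reshape(s.image.n_channels, -1).T
        x = s.x_flat
        obs = s.observed_flat
        c = np.where(obs, b * x, 0.0)
        logdet_b = np.where(obs, np.log(b), 0.0).sum(axis=1)
        return _expected_log_densities_masked(c, obs, s.posterior) + logdet_b[:, None]

    def _label_rows(self, s: SubjectState):
        """(labelled_mask, per-voxel label prior matrix for labelled voxels)."""
        if s.labels is None:
            return None, None
        lab = s.labels.labels.reshape(-1)
        mask = lab > 0
        if not mask.any():
            return None, None
        K = self.config.n_classes
        zeta = 1.0 if self.config.hard_labels else self.config.zeta
        rater = supervision.RaterModel(zeta=zeta, K=K)
        uniq = np.unique(lab[mask])
        table = {}
        for l in uniq:
            subset = self.config.label_class_map.get(int(l))
            subset = tuple(subset) if subset else None
            table[int(l)] = supervision.label_prior(int(l), rater, subset)
        P = np.zeros((int(mask.sum()), K))
        for n, l in enumerate(lab[mask]):
            P[n] = table[int(l)]
        return mask, P

    def e_step(self, s: SubjectState) -> np.ndarray:
        log_dens = self._log_dens_rows(s)
        log_prior = self._log_prior_rows(s)
        gamma = intens.e_step_unsupervised(log_dens, log_prior)
        mask, P = self._label_rows(s)
        if mask is not None:
            gamma[mask] = supervision.e_step_semisupervised(
                log_dens[mask], log_prior[mask], np.maximum(P, 0.0)
            )
        return gamma

    def m_step(self, s: SubjectState, prior: intens.GaussWishartPrior) -> None:
        b = s.bias.field().reshape(s.image.n_channels, -1).T
        c = np.where(s.observed_flat, b * s.x_flat, 0.0)
        stats = intens.missing_data_statistics(c, s.observed_flat, s.gamma, s.posterior)
        s.posterior = intens.m_step(*stats, prior)

    # ---------------------------------------------------------------- bound

    def lower_bound(self, subjects: list[SubjectState]) -> float:
        """Evidence lower bound; raises naming any non-finite term."""
        terms = {}
        total = 0.0
        for i, s in enumerate(subjects):
            if s.diffeo is None:
                self._refresh_warp(s)
            if s.gamma is None:
                s.gamma = self.e_step(s)
            log_dens = self._log_dens_rows(s)
            log_prior = self._log_prior_rows(s)
            g = s.gamma
            with np.errstate(divide="ignore", invalid="ignore"):
                ent = -np.where(g > 0, g * np.log(g), 0.0).sum()
            terms[f"data_{i}"] = float((g * log_dens).sum())
            terms[f"latent_prior_{i}"] = float((g * log_prior).sum())
            terms[f"latent_entropy_{i}"] = float(ent)
            mask, P = self._label_rows(s)
            if mask is not None:
                with np.errstate(divide="ignore", invalid="ignore"):
                    lp = np.log(P)
                    gm = g[mask]
                    prod = np.where(gm > 0, gm * lp, 0.0)
                terms[f"rater_{i}"] = float(prod.sum())
            terms[f"gw_cross_{i}"] = intens.expected_log_prior_density(
                s.posterior, self.prior_
            )
            terms[f"gw_entropy_{i}"] = intens.entropy_q(s.posterior)
            terms[f"bias_prior_{i}"] = -s.bias.penalty()
            terms[f"affine_prior_{i}"] = s.affine.log_prior()
            op = self._operator(s.image.grid)
            terms[f"velocity_prior_{i}"] = -diffeo.regularisation_energy(s.velocity, op)
        terms["dirichlet"] = tpl_mod.dirichlet_log_prior(self.template, self.dirichlet)
        for name, val in terms.items():
            if not np.isfinite(val):
                raise FloatingPointError(f"non-finite lower-bound term: {name}")
            total += val
        return total

    # ------------------------------------------------------------------ fit

    def fit(self, max_outer: int | None = None, verbose: bool = False) -> "AtlasResults":
        cfg = self.config
        max_outer = cfg.max_outer if max_outer is None else max_outer
        self.prior_ = self.intensity_prior or self._initial_prior()
        subjects = [self._initial_subject(i, self.prior_) for i in range(len(self.volumes))]
        for s in subjects:
            self._refresh_warp(s)
            s.gamma = self.e_step(s)
        bound = self.lower_bound(subjects)
        trace = [bound]
        checks: list[tuple[str, float]] = []

        def check(name: str) -> float:
            nonlocal bound
            new = self.lower_bound(subjects)
            slack = BOUND_SLACK * (1.0 + abs(bound))
            if new < bound - slack:
                raise RuntimeError(
                    f"lower bound decreased after update '{name}': {bound:.6f} -> {new:.6f}"
                )
            checks.append((name, new))
            bound = new
            return new

        for outer in range(max_outer):
            for i, s in enumerate(subjects):
                self._refresh_warp(s)
                s.gamma = self.e_step(s)
                check(f"e_step[{i}]")
                self.m_step(s, self.prior_)
                check(f"m_step[{i}]")
                if cfg.update_weights:
                    self._update_weights(s)
                    check(f"weights[{i}]")
                if cfg.update_bias:
                    b = s.bias
                    s.bias = bias_mod.update_bias(
                        s.x_flat, s.gamma, s.posterior, b, s.observed_flat
                    )
                    check(f"bias[{i}]")
                if cfg.update_affine:
                    s.affine = aff.update_affine(
                        s.affine, s.diffeo.forward, s.image.grid, self.template.grid,
                        lambda pts: self._matching_terms(s, pts,
                                                         centred_gradient=True),
                    )
                    check(f"affine[{i}]")
                if cfg.update_velocity and outer >= cfg.affine_warmup:
                    self._update_velocity(s)
                    check(f"velocity[{i}]")
            if cfg.update_template and not self._frozen_template:
                self._update_template(subjects)
                check("template")
            if cfg.update_intensity_prior and not self._frozen_prior:
                new_prior = intens.update_empirical_priors(
                    [s.posterior for s in subjects], self.prior_
                )
                self.prior_ = new_prior
                check("intensity_prior")
            trace.append(bound)
            if verbose:
                logger.info("outer %d: bound %.4f", outer, bound)
            if len(trace) > 1 and outer >= cfg.affine_warmup:
                gain = (trace[-1] - trace[-2]) / (1.0 + abs(trace[-2]))
                if gain < cfg.tol * 1e-2:
                    break
        return AtlasResults(self, subjects, self.template, self.prior_,
                            np.asarray(trace), checks)

    # ------------------------------------------------------------- updates

    def _update_weights(self, s: SubjectState) -> None:
        pts = self._xi_points(s)
        probs = np.maximum(self.template.sample(pts), tpl_mod.TEMPLATE_FLOOR)
        p = probs.reshape(self.config.n_classes, -1).T
        p = p / p.sum(axis=1, keepdims=True)
        old = s.weights
        new = intens.update_mixing_weights(s.gamma, p, w_init=old)
        if intens.weight_objective(s.gamma, p, new) >= intens.weight_objective(
            s.gamma, p, old
        ):
            s.weights = new

    def _update_velocity(self, s: SubjectState) -> None:
        op = self._operator(s.image.grid)
        R = (
            self.template.grid.world_to_voxel
            @ s.affine.as_homogeneous()
            @ s.image.grid.voxel_to_world
        )[:3, :3]

        def objective(u):
            d = diffeo.geodesic_shoot(u, op, self.config.shoot_steps)
            pts = self._xi_points(s, d.forward)
            v, _, _ = self._matching_terms(s, pts, want_derivs=False)
            return -v + diffeo.regularisation_energy(u, op)

        def grad_hess(u):
            pts = self._xi_points(s)
            _, g, H = self._matching_terms(s, pts, centred_gradient=True)
            return -g, H

        new_u, accepted = diffeo.update_velocity(
            s.velocity, op, objective, grad_hess, chain_matrix=R,
            steps=self.config.shoot_steps,
            smooth_kappa=self.config.velocity_smooth_kappa,
        )
        if accepted:
            s.velocity = new_u
            self._refresh_warp(s)

    def _update_template(self, subjects: list[SubjectState]) -> None:
        pushed, weights = [], []
        for s in subjects:
            xi_inv, det = self._xi_inverse(s)
            K = self.config.n_classes
            gam = s.gamma.T.reshape((K,) + s.image.grid.shape)
            Ni = np.stack([push_weighted(gam[k], xi_inv, det) for k in range(K)])
            pushed.append(np.maximum(Ni, 0.0))
            weights.append(s.weights)
        new = tpl_mod.update_template(self.template, pushed, weights, self.dirichlet)
        if self.config.template_smooth_fwhm > 0:
            new = tpl_mod.smooth_template(new, self.config.template_smooth_fwhm)
        # The det-weighted pushed objective is the continuum change of
        # variables, not the exact discrete adjoint, so guard the true bound
        # with a backtracking blend toward the previous template.
        old = self.template
        old_gammas = [s.gamma for s in subjects]
        f0 = self.lower_bound(subjects)
        alpha = 1.0
        for _ in range(6):
            cand = (1.0 - alpha) * old.coeffs + alpha * new.coeffs
            cand = np.maximum(cand, tpl_mod.TEMPLATE_FLOOR)
            cand /= cand.sum(axis=0, keepdims=True)
            self.template = tpl_mod.TissueTemplate(old.grid, cand)
            for s in subjects:
                s.gamma = self.e_step(s)
            if self.lower_bound(subjects) >= f0:
                return
            alpha *= 0.5
        self.template = old
        for s, g in zip(subjects, old_gammas):
            s.gamma = g

    # ------------------------------------------------------------- serving

    def apply(self, volume: ImageVolume, labels: LabelMap | None = None,
              max_outer: int = 8) -> "AtlasResults":
        """Segment / normalise an unseen volume against the fitted template."""
        if not hasattr(self, "prior_"):
            raise RuntimeError("fit() the population first (or pass a template+prior)")
        sub = AtlasModel(
            [volume], [labels], self.config, template=self.template,
            intensity_prior=self.prior_,
        )
        return sub.fit(max_outer=max_outer)


def _posterior_from(prior: intens.GaussWishartPrior) -> intens.MixturePosterior:
    return intens.MixturePosterior(prior.m0.copy(), prior.beta0.copy(),
                                   prior.W0.copy(), prior.nu0.copy())


class AtlasResults:
    """Fit results: template, per-subject states, bound trace, diagnostics."""

    def __init__(self, model: AtlasModel, subjects, template, prior, bound_trace, checks):
        self.model = model
        self.subjects: list[SubjectState] = subjects
        self.template: tpl_mod.TissueTemplate = template
        self.intensity_prior: intens.GaussWishartPrior = prior
        self.bound_trace = bound_trace
        self.update_checks = checks

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def responsibilities(self, i: int) -> np.ndarray:
        """(K, *shape) posterior class probabilities for subject i."""
        s = self.subjects[i]
        K = self.model.config.n_classes
        return s.gamma.T.reshape((K,) + s.image.grid.shape)

    def segmentation(self, i: int, threshold: float = 0.5) -> np.ndarray:
        """Hard labels (1..K; 0 where no class clears the threshold)."""
        g = self.responsibilities(i)
        arg = g.argmax(axis=0) + 1
        arg[g.max(axis=0) < threshold] = 0
        return arg

    def bias_field(self, i: int) -> np.ndarray:
        return self.subjects[i].bias.field()

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Generative groupwise atlas fit",
            "=" * 46,
            f"subjects:            {self.n_subjects}",
            f"classes (K):         {cfg.n_classes}",
            f"channels (D):        {self.subjects[0].image.n_channels}",
            f"template grid:       {self.template.grid.shape}",
            f"outer iterations:    {len(self.bound_trace) - 1}",
            f"final lower bound:   {self.bound_trace[-1]:.4f}",
            f"bound gain:          {self.bound_trace[-1] - self.bound_trace[0]:.4f}",
            f"monotone updates:    {len(self.update_checks)}",
        ]
        for i, s in enumerate(self.subjects):
            w = np.array2string(s.weights, precision=3)
            lines.append(f"  subject {i}: |t| = {np.linalg.norm(s.affine.t):.3f} mm, "
                         f"weights {w}")
        return "\n".join(lines)

    def save_outputs(self, outdir, config_echo: dict | None = None) -> None:
        """Write template, per-subject maps and a run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tgrid = self.template.grid
        write_volume(outdir / "template.nii.gz",
                     ImageVolume(tgrid, self.template.coeffs))
        for i, s in enumerate(self.subjects):
            write_volume(outdir / f"sub{i:02d}_prob.nii.gz",
                         ImageVolume(s.image.grid, self.responsibilities(i)))
            write_volume(outdir / f"sub{i:02d}_bias.nii.gz",
                         ImageVolume(s.image.grid, s.bias.field()))
            np.savetxt(outdir / f"sub{i:02d}_affine.txt", s.affine.as_homogeneous())
            if s.diffeo is not None:
                from .grids import identity_map as _idmap

                disp = s.diffeo.forward - _idmap(s.image.grid.shape)
                write_volume(outdir / f"sub{i:02d}_def.nii.gz",
                             ImageVolume(s.image.grid, disp))
                write_volume(outdir / f"sub{i:02d}_velocity.nii.gz",
                             ImageVolume(s.image.grid, s.velocity))
                write_volume(outdir / f"sub{i:02d}_jacdet.nii.gz",
                             ImageVolume(s.image.grid, s.diffeo.jac_det_fwd[None]))
        np.savetxt(outdir / "bound_trace.csv", self.bound_trace, delimiter=",")
        manifest = {
            "config": config_echo or self.model.config.to_dict(),
            "seed": self.model.config.seed,
            "n_subjects": self.n_subjects,
            "final_bound": float(self.bound_trace[-1]),
            "bound_trace": [float(v) for v in self.bound_trace],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
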