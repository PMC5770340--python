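"""Supervised and semisupervised E-steps from manual labels.

A manual label is treated as the noisy output of a rater with sensitivity
zeta: the labelled class receives prior mass zeta and the remaining mass is
spread uniformly over the other classes.  At zeta = 1 labels are hard
(one-hot responsibilities); at zeta = 1/K the label carries no information
and the semisupervised E-step reduces to the unsupervised one.  One training
label may map to several mixture classes (e.g. a single gray-matter label
feeding two gray-matter components): the zeta mass is then shared across the
subset, with the split resolved by the current class likelihoods through the
usual Bayes product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["RaterModel", "label_prior", "e_step_labelled", "e_step_semisupervised"]


@dataclass(frozen=True)
class RaterModel:
    """Rater sensitivity model; zeta in (1/K, 1]."""

    zeta: float = 0.9
    K: int = 2

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.K > 1 and not (1.0 / self.K <= self.zeta <= 1.0):
            raise ValueError(f"zeta must lie in [1/K, 1], got {self.zeta}")
        if self.K > 1 and self.zeta == 1.0 / self.K:
            warnings.warn("zeta = 1/K: rater carries no information", stacklevel=2)


def label_prior(
    label: int,
    rater: RaterModel,
    class_subset: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Prior class probabilities given a manual label.

    Sensitivity mass zeta sits on the labelled class (or is split over the
    mapped class subset), with (1 - zeta)/(K - 1) on every other class; the
    vector sums to 1.
    """
    K = rater.K
    if K == 1:
        return np.ones(1)
    subset = (label - 1,) if class_subset is None else tuple(class_subset)
    if not all(0 <= c < K for c in subset):
        raise ValueError(f"label-class subset {subset} out of range for K={K}")
    n_in, n_out = len(subset), K - len(subset)
    if n_out == 0:
        return np.full(K, 1.0 / K)
    out = np.full(K, (1.0 - rater.zeta) / n_out)
    for c in subset:
        out[c] = rater.zeta / n_in
    return out


def e_step_labelled(label: int, K: int) -> np.ndarray:
    """Hard-label responsibility row: one-hot at the labelled class."""
    if not 1 <= label <= K:
        raise ValueError(f"label {label} outside 1..{K}; 0 must use the unsupervised path")
    row = np.zeros(K)
    row[label - 1] = 1.0
    return row


def e_step_semisupervised(
    log_dens: np.ndarray,
    log_class_prior: np.ndarray,
    label_prior_row: np.ndarray,
) -> np.ndarray:
    """Bayes-rule combination of intensity evidence, spatial prior and label prior.

    gamma_k proportional to p(x|k) p(k) p(k|l), computed in the log domain.
    Accepts single rows or (N, K) batches.
    """
    with np.errstate(divide="ignore"):
        logr = log_dens + log_class_prior + np.log(label_prior_row)
    logr = np.atleast_2d(logr)
    logr -= logsumexp(logr, axis=-1, keepdims=True)
    gamma = np.exp(logr)
    gamma /= gamma.sum(axis=-1, keepdims=True)
    return gamma[0] if np.ndim(log_dens) == 1 else gamma
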