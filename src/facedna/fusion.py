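"""Score-level fusion of per-feature matching scores.

An all-versus-all sweep of the validation set yields one n-feature score
vector per (face, probe) pair: genuine when the face and probe belong to
the same individual, imposter otherwise.  A naive-Bayes fuser with
per-feature class-conditional Gaussians is fitted on these labeled
vectors; its posterior probability of "genuine" is the overall matching
score.  Fixed combination rules (sum, min, max, product) are provided as
baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenuineImposterSet",
    "NaiveBayesFuser",
    "build_genuine_imposter",
    "train_fuser",
    "fuse",
    "rule_fuser",
]

_CLIP = 1e-6
_VAR_FLOOR = 1e-6


@dataclass
class GenuineImposterSet:
    """Labeled score vectors from an all-vs-all validation sweep."""

    vectors: np.ndarray  # (n_val^2, d)
    genuine: np.ndarray  # bool
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.vectors.shape[1]


def build_genuine_imposter(
    validation_scores: np.ndarray, feature_names: list[str] | None = None
) -> GenuineImposterSet:
    """Flatten an (n_val faces x n_val probes x d) score tensor.

    The pair (i, j) is genuine iff i == j, giving exactly n_val genuine
    and n_val * (n_val - 1) imposter vectors.
    """
    T = np.asarray(validation_scores, float)
    if T.ndim != 3 or T.shape[0] != T.shape[1]:
        raise ValueError("validation scores must be (n_val, n_val, d)")
    n = T.shape[0]
    vectors = T.reshape(n * n, T.shape[2])
    genuine = (np.arange(n)[:, None] == np.arange(n)[None, :]).reshape(-1)
    return GenuineImposterSet(
        vectors=vectors, genuine=genuine,
        feature_names=list(feature_names or []),
    )


@dataclass
class NaiveBayesFuser:
    """Gaussian naive-Bayes discriminator of genuine vs imposter vectors."""

    mean: np.ndarray  # (2, d): row 0 imposter, row 1 genuine
    var: np.ndarray  # (2, d), floored
    log_prior: np.ndarray  # (2,)
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.mean.shape[1]

    def posterior_genuine(self, vectors: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(vectors, float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"vector has {X.shape[1]} features, model expects {self.n_features}"
            )
        X = np.clip(X, _CLIP, 1.0 - _CLIP)
        ll = np.empty((X.shape[0], 2))
        for k in (0, 1):
            ll[:, k] = self.log_prior[k] - 0.5 * np.sum(
                np.log(2 * np.pi * self.var[k])
                + (X - self.mean[k]) ** 2 / self.var[k],
                axis=1,
            )
        m = ll.max(axis=1, keepdims=True)
        w = np.exp(ll - m)
        return w[:, 1] / w.sum(axis=1)


def train_fuser(
    gi: GenuineImposterSet, prior_mode: str = "empirical", min_genuine: int = 10
) -> NaiveBayesFuser:
    """Fit per-feature class-conditional Gaussians with chosen priors.

    ``prior_mode``: ``empirical`` (heavily imposter-skewed, as the
    all-vs-all sweep is) or ``uniform``.  Fewer than ``min_genuine``
    genuine examples make the fuser untrainable (lower the bound only for
    hand-constructed toys).  Zero variances are floored and logged; scores
    are clipped away from 0 and 1 before fitting.  Variances use the
    unbiased (ddof = 1) estimator.
    """
    if not (gi.genuine.any() and (~gi.genuine).any()):
        raise ValueError("need both genuine and imposter examples")
    if gi.genuine.sum() < min_genuine:
        raise ValueError(f"need at least {min_genuine} genuine examples")
    X = np.clip(gi.vectors, _CLIP, 1.0 - _CLIP)
    mean = np.empty((2, gi.n_features))
    var = np.empty((2, gi.n_features))
    for k, mask in enumerate([~gi.genuine, gi.genuine]):
        mean[k] = X[mask].mean(axis=0)
        var[k] = X[mask].var(axis=0, ddof=1) if mask.sum() > 1 else 0.0
    floored = var < _VAR_FLOOR
    if floored.any():
        logger.info("train_fuser: floored %d zero variances", floored.sum())
    var = np.maximum(var, _VAR_FLOOR)
    if prior_mode == "empirical":
        p1 = gi.genuine.mean()
        prior = np.array([1.0 - p1, p1])
    elif prior_mode == "uniform":
        prior = np.array([0.5, 0.5])
    else:
        raise ValueError(f"unknown prior_mode {prior_mode!r}")
    return NaiveBayesFuser(
        mean=mean, var=var, log_prior=np.log(prior),
        feature_names=list(gi.feature_names),
    )


def fuse(model: NaiveBayesFuser, vectors: np.ndarray) -> np.ndarray:
    """Overall matching score: posterior P(genuine | score vector)."""
    return model.posterior_genuine(vectors)


def rule_fuser(vectors: np.ndarray, rule: str = "sum") -> np.ndarray:
    """Fixed-rule baselines: sum (mean), min, max or product of scores."""
    X = np.atleast_2d(np.asarray(vectors, float))
    if rule == "sum":
        return X.mean(axis=1)
    if rule == "min":
        return X.min(axis=1)
    if rule == "max":
        return X.max(axis=1)
    if rule == "product":
        return np.exp(np.sum(np.log(np.clip(X, _CLIP, 1.0)), axis=1))
    raise ValueError(f"unknown rule {rule!r}")
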