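"""Gaussian mixture intensity model for CT radiodensities.

Voxel intensities y_i (HU) are modelled as draws from a mixture of K
Gaussian clusters, cluster k having mean mu_k, variance sigma2_k and
mixing coefficient gamma_k (gamma sums to one).  Each cluster belongs to
one tissue class; by default one cluster per class.  Spatial information
enters only through per-voxel per-cluster prior weights (see
:mod:`ctbrainseg.priors`) — the mixture itself is purely an intensity
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

log = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-3  # HU^2; prevents cluster collapse onto one intensity


class MixtureError(ValueError):
    pass


@dataclass
class MixtureParams:
    """Parameters of the Gaussian intensity mixture.

    ``class_of_cluster[k]`` maps cluster k to a tissue-class index (into
    the atlas class order); several clusters may share one class.
    """

    mu: np.ndarray
    sigma2: np.ndarray
    gamma: np.ndarray
    class_of_cluster: np.ndarray = field(default=None)

    def __post_init__(self):
        self.mu = np.atleast_1d(np.asarray(self.mu, float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, float))
        K = self.mu.size
        if K < 1 or self.sigma2.size != K or self.gamma.size != K:
            raise MixtureError("mu, sigma2, gamma must have equal length K >= 1")
        if np.any(self.sigma2 <= 0):
            raise MixtureError("variances must be strictly positive")
        if np.any(self.gamma < 0) or abs(self.gamma.sum() - 1.0) > 1e-9:
            raise MixtureError("mixing coefficients must be >= 0 and sum to 1")
        if self.class_of_cluster is None:
            self.class_of_cluster = np.arange(K)
        self.class_of_cluster = np.asarray(self.class_of_cluster, int)
        if self.class_of_cluster.size != K:
            raise MixtureError("class_of_cluster must have length K")

    @property
    def n_clusters(self) -> int:
        return self.mu.size


def class_likelihood(y, k: int, params: MixtureParams):
    """Gaussian density of intensity ``y`` under cluster ``k``."""
    mu, s2 = params.mu[k], params.sigma2[k]
    y = np.asarray(y, float)
    return np.exp(-((y - mu) ** 2) / (2.0 * s2)) / np.sqrt(2.0 * np.pi * s2)


def _log_likelihoods(y: np.ndarray, params: MixtureParams) -> np.ndarray:
    """log N(y_i; mu_k, sigma2_k) for all voxels and clusters, shape (I, K)."""
    y = np.asarray(y, float).reshape(-1, 1)
    mu = params.mu.reshape(1, -1)
    s2 = params.sigma2.reshape(1, -1)
    return -0.5 * (np.log(2.0 * np.pi * s2) + (y - mu) ** 2 / s2)


def marginal_likelihood(y, params: MixtureParams, prior_k) -> np.ndarray:
    """Total density of observing ``y``: sum_k prior_k[k] * N(y; mu_k, s2_k)."""
    prior_k = np.asarray(prior_k, float)
    if np.any(prior_k < 0) or abs(prior_k.sum() - 1.0) > 1e-9:
        raise MixtureError("prior weights must be nonnegative and sum to 1")
    ll = _log_likelihoods(np.atleast_1d(y), params)
    out = np.exp(ll) @ prior_k
    return out if np.ndim(y) else float(out[0])


def responsibilities(y, params: MixtureParams, priors) -> np.ndarray:
    """Posterior cluster probabilities per voxel, shape (I, K).

    ``priors`` is an (I, K) row-normalized prior-weight matrix (a single
    row is broadcast).  Rows whose numerators all underflow to zero fall
    back to their prior weights.
    """
    y = np.atleast_1d(np.asarray(y, float))
    priors = np.asarray(priors, float)
    if priors.ndim == 1:
        priors = np.broadcast_to(priors, (y.size, priors.size))
    with np.errstate(divide="ignore"):
        log_num = np.log(priors) + _log_likelihoods(y, params)
    norm = logsumexp(log_num, axis=1, keepdims=True)
    bad = ~np.isfinite(norm[:, 0])
    norm[bad] = 0.0
    post = np.exp(log_num - norm)
    if bad.any():
        log.warning("responsibilities: %d voxel(s) with all-zero numerators; "
                    "falling back to priors", int(bad.sum()))
        post[bad] = priors[bad]
    return post


def neg_log_likelihood(y, params: MixtureParams, priors) -> float:
    """Mixture cost E = -sum_i log sum_k priors[i,k] N(y_i; mu_k, s2_k).

    Computed in the log domain with per-voxel max-shift (logsumexp); a
    non-finite result raises with the index of the offending voxel.
    """
    y = np.atleast_1d(np.asarray(y, float))
    priors = np.asarray(priors, float)
    if priors.ndim == 1:
        priors = np.broadcast_to(priors, (y.size, priors.size))
    with np.errstate(divide="ignore"):
        terms = logsumexp(np.log(priors) + _log_likelihoods(y, params), axis=1)
    if not np.all(np.isfinite(terms)):
        i = int(np.argmin(np.isfinite(terms)))
        raise FloatingPointError(
            f"neg_log_likelihood non-finite at voxel {i}: y={y[i]}, "
            f"priors={priors[i]}"
        )
    return float(-np.sum(terms))
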