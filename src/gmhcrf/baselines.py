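"""Comparison models: generative Gaussian(-mixture) HMM and the
diagonal moment-feature chain model.

The HMM scorer is implemented as a scaled probability-domain forward
pass with scipy densities — deliberately a separate code path from the
log-space recursions in :mod:`gmhcrf.model_core`, because it serves as
the equivalence oracle for the probability-to-potential mapping
(prior = log b, transition = log C, emissions copied).

The diagonal variant replaces each state's mixture density with a
per-dimension linear + quadratic potential; with weights completed from
(mu, sigma^2) it reproduces the diagonal Gaussian log-density exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from .exceptions import InputError, ModelValidityError
from .model_core import (
    ClassParams,
    FeatureSequence,
    GaussianComponent,
    GMHCRFModel,
    StateMixture,
    chain_log_forward,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianHMM",
    "DiagonalHCRF",
    "hmm_log_likelihood",
    "hcrf_from_hmm",
    "diagonal_hcrf_score",
    "diagonal_weights_from_gaussian",
    "diagonal_hcrf_from_gaussians",
    "fit_diagonal",
]


@dataclass
class GaussianHMM:
    """Generative HMM: stochastic initial/transition, mixture emissions."""

    initial: np.ndarray
    transition: np.ndarray
    emissions: List[StateMixture]

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float).ravel()
        self.transition = np.asarray(self.transition, dtype=float)
        Q = self.initial.shape[0]
        if self.transition.shape != (Q, Q) or len(self.emissions) != Q:
            raise InputError("HMM shapes inconsistent with Q")
        if np.any(self.initial < 0) or abs(self.initial.sum() - 1.0) > 1e-12:
            raise ModelValidityError("initial distribution is not stochastic")
        rows = self.transition.sum(axis=1)
        if np.any(self.transition < 0) or np.any(np.abs(rows - 1.0) > 1e-12):
            raise ModelValidityError("transition matrix rows are not stochastic")

    @property
    def Q(self) -> int:
        return self.initial.shape[0]

    @property
    def D(self) -> int:
        return self.emissions[0].D


def _mixture_log_density_matrix(hmm: GaussianHMM, frames: np.ndarray) -> np.ndarray:
    """T x Q log mixture densities via scipy.stats (independent route)."""
    T = frames.shape[0]
    out = np.empty((T, hmm.Q))
    for q, mix in enumerate(hmm.emissions):
        comp_ld = np.stack(
            [
                multivariate_normal(mean=c.mean, cov=c.covariance).logpdf(frames)
                for c in mix.components
            ]
        ).reshape(mix.M, T)
        with np.errstate(divide="ignore"):
            lw = np.log(mix.weights)
        out[:, q] = logsumexp(lw[:, None] + comp_ld, axis=0)
    return out


def hmm_log_likelihood(hmm: GaussianHMM, seq: FeatureSequence) -> float:
    """log p(U) by the classic scaled (probability-domain) forward pass."""
    if seq.D != hmm.D:
        raise InputError(f"sequence dimension {seq.D} != HMM dimension {hmm.D}")
    ld = _mixture_log_density_matrix(hmm, seq.frames)
    shifts = ld.max(axis=1)
    em = np.exp(ld - shifts[:, None])
    alpha = hmm.initial * em[0]
    loglik = shifts[0]
    c = alpha.sum()
    if c == 0.0:
        return -np.inf
    loglik += np.log(c)
    alpha = alpha / c
    for t in range(1, seq.T):
        alpha = (alpha @ hmm.transition) * em[t]
        c = alpha.sum()
        if c == 0.0:
            return -np.inf
        loglik += np.log(c) + shifts[t]
        alpha = alpha / c
    return float(loglik)


def hcrf_from_hmm(hmm: GaussianHMM) -> ClassParams:
    """Probabilities -> potentials: prior = log b, transition = log C.

    Zero probabilities map to -inf potentials (allowed by ClassParams).
    The mapped block's forward log-score equals the HMM log-likelihood.
    """
    with np.errstate(divide="ignore"):
        prior = np.log(hmm.initial)
        transition = np.log(hmm.transition)
    emissions = [
        StateMixture(
            mix.weights.copy(),
            [GaussianComponent(c.mean.copy(), c.covariance.copy()) for c in mix.components],
        )
        for mix in hmm.emissions
    ]
    return ClassParams(prior, transition, emissions)


# ---------------------------------------------------------------------------
# Diagonal moment-feature variant
# ---------------------------------------------------------------------------


@dataclass
class DiagonalHCRF:
    """Per-class chain potentials with per-dimension moment features.

    Per-frame state potential:
        occurrence[l] + sum_d (m1[l, d] * u_d + m2[l, d] * u_d^2).
    A proper Gaussian correspondence requires m2 < 0; violations are
    allowed but logged.
    """

    labels: list
    prior: List[np.ndarray]  # per class, Q
    transition: List[np.ndarray]  # per class, Q x Q
    occurrence: List[np.ndarray]  # per class, Q
    m1: List[np.ndarray]  # per class, Q x D
    m2: List[np.ndarray]  # per class, Q x D

    def __post_init__(self) -> None:
        n = len(self.labels)
        for part in (self.prior, self.transition, self.occurrence, self.m1, self.m2):
            if len(part) != n:
                raise InputError("per-class parameter lists must match the label set")
        for lab, m2 in zip(self.labels, self.m2):
            if np.any(np.asarray(m2) >= 0):
                logger.warning(
                    "class %r: some quadratic weights are >= 0; the potential "
                    "does not correspond to a proper Gaussian",
                    lab,
                )


def _diag_log_potentials(
    occ: np.ndarray, m1: np.ndarray, m2: np.ndarray, frames: np.ndarray
) -> np.ndarray:
    """T x Q per-frame potentials occ + U m1^T + U^2 m2^T."""
    return occ[None, :] + frames @ np.asarray(m1).T + (frames**2) @ np.asarray(m2).T


def diagonal_hcrf_score(model: DiagonalHCRF, seq: FeatureSequence) -> np.ndarray:
    """Per-class log scores, aligned with ``model.labels``."""
    out = np.empty(len(model.labels))
    for j in range(len(model.labels)):
        log_pot = _diag_log_potentials(
            model.occurrence[j], model.m1[j], model.m2[j], seq.frames
        )
        _, out[j] = chain_log_forward(model.prior[j], model.transition[j], log_pot)
    return out


def diagonal_weights_from_gaussian(
    means: np.ndarray, variances: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complete (occurrence, m1, m2) from per-state diagonal Gaussians.

    occurrence[l] = -1/2 sum_d (log(2 pi s2) + mu^2 / s2),
    m1 = mu / s2,  m2 = -1 / (2 s2);
    the per-frame potential then equals log N(u; mu, diag(s2)) exactly.
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    variances = np.atleast_2d(np.asarray(variances, dtype=float))
    if np.any(variances <= 0):
        raise ModelValidityError("variances must be positive")
    occ = -0.5 * np.sum(np.log(2.0 * np.pi * variances) + means**2 / variances, axis=1)
    m1 = means / variances
    m2 = -0.5 / variances
    return occ, m1, m2


def diagonal_hcrf_from_gaussians(
    labels: list,
    priors: List[np.ndarray],
    transitions: List[np.ndarray],
    means: List[np.ndarray],
    variances: List[np.ndarray],
) -> DiagonalHCRF:
    """Build the moment-feature model equivalent to per-state diagonal
    Gaussian emissions (single component per state)."""
    occ_l, m1_l, m2_l = [], [], []
    for mu, s2 in zip(means, variances):
        occ, m1, m2 = diagonal_weights_from_gaussian(mu, s2)
        occ_l.append(occ)
        m1_l.append(m1)
        m2_l.append(m2)
    return DiagonalHCRF(list(labels), list(priors), list(transitions), occ_l, m1_l, m2_l)


def fit_diagonal(dataset, config, counter=None):
    """Train the diagonal-covariance constrained variant.

    Same training loop as :func:`gmhcrf.training.fit`, with covariances
    restricted to their diagonal (the per-dimension independence
    assumption the full model removes).  Returns (model, history) where
    the model is a diagonal-covariance ``GMHCRFModel``.
    """
    from .training import fit

    return fit(dataset, replace(config, covariance="diag"), counter=counter)
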