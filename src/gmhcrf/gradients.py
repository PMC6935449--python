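"""Analytic gradients of the conditional log-posterior.

Gradients of the per-class log score are expected sufficient statistics
under the hidden-state posterior: state marginals drive the prior and
transition gradients, and mixture responsibilities weighted by state
marginals drive the weight/mean/covariance gradients.  Everything is
computed from ONE cached forward and ONE cached backward pass per
(sequence, class) — the caching contract is instrumented via
``CallCounter`` and asserted in the test suite against a deliberately
naive reference that re-runs forward/backward per parameter family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_solve
from scipy.special import logsumexp

from .exceptions import InputError, InternalConsistencyError
from .model_core import (
    ClassParams,
    FBCache,
    FeatureSequence,
    GMHCRFModel,
    _lse,
    chain_log_backward,
    chain_log_forward,
    log_component_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CallCounter",
    "GradientBlock",
    "build_cache",
    "responsibilities",
    "state_marginals",
    "grad_log_score",
    "grad_log_score_naive",
    "grad_conditional_nll",
]


@dataclass
class CallCounter:
    """Counts forward/backward executions and gradient accumulation work."""

    n_forward: int = 0
    n_backward: int = 0
    n_accum_ops: int = 0

    def reset(self) -> None:
        self.n_forward = 0
        self.n_backward = 0
        self.n_accum_ops = 0


@dataclass
class GradientBlock:
    """Per-class gradient in the model's natural (constrained) coordinates."""

    d_prior: np.ndarray  # Q
    d_transition: np.ndarray  # Q x Q
    d_weights: np.ndarray  # Q x M
    d_means: np.ndarray  # Q x M x D
    d_covariances: np.ndarray  # Q x M x D x D

    def scaled(self, c: float) -> "GradientBlock":
        return GradientBlock(
            c * self.d_prior,
            c * self.d_transition,
            c * self.d_weights,
            c * self.d_means,
            c * self.d_covariances,
        )

    def add_(self, other: "GradientBlock", c: float = 1.0) -> None:
        self.d_prior += c * other.d_prior
        self.d_transition += c * other.d_transition
        self.d_weights += c * other.d_weights
        self.d_means += c * other.d_means
        self.d_covariances += c * other.d_covariances

    @staticmethod
    def zeros(Q: int, M: int, D: int) -> "GradientBlock":
        return GradientBlock(
            np.zeros(Q),
            np.zeros((Q, Q)),
            np.zeros((Q, M)),
            np.zeros((Q, M, D)),
            np.zeros((Q, M, D, D)),
        )


def _resp_from_log_comp(log_comp: np.ndarray) -> np.ndarray:
    """Responsibilities r_{t,l,m} via a per-(t,l) softmax over m.

    Rows where every component underflows to -inf fall back to uniform
    1/M with a logged warning, so line searches survive bad iterates.
    """
    M = log_comp.shape[2]
    mx = np.max(log_comp, axis=2, keepdims=True)
    bad = ~np.isfinite(mx[..., 0])
    safe_mx = np.where(np.isfinite(mx), mx, 0.0)
    w = np.exp(log_comp - safe_mx)
    w_sum = w.sum(axis=2, keepdims=True)
    resp = w / w_sum
    if np.any(bad):
        logger.warning(
            "mixture responsibilities underflowed at %d (frame, state) cells; "
            "falling back to uniform 1/M",
            int(bad.sum()),
        )
        resp[bad] = 1.0 / M
    return resp


def build_cache(
    params: ClassParams, seq: FeatureSequence, counter: Optional[CallCounter] = None
) -> FBCache:
    """One forward pass + one backward pass, cached with responsibilities."""
    log_comp = log_component_matrix(params, seq)
    log_emis = _lse(log_comp, axis=2)
    log_alpha, log_score = chain_log_forward(params.prior, params.transition, log_emis)
    if counter is not None:
        counter.n_forward += 1
    log_beta = chain_log_backward(params.transition, log_emis)
    if counter is not None:
        counter.n_backward += 1
    resp = _resp_from_log_comp(log_comp)
    return FBCache(
        params=params,
        log_alpha=log_alpha,
        log_beta=log_beta,
        log_emis=log_emis,
        log_comp=log_comp,
        resp=resp,
        log_score=log_score,
    )


def responsibilities(params: ClassParams, seq: FeatureSequence) -> np.ndarray:
    """T x Q x M posterior component memberships, computed in log space."""
    return _resp_from_log_comp(log_component_matrix(params, seq))


def _check_cache(cache: FBCache, tol: float = 1e-6) -> None:
    lhs = _lse(cache.log_alpha[-1], axis=0)
    rhs = _lse(cache.params.prior + cache.log_emis[0] + cache.log_beta[0], axis=0)
    if abs(lhs - rhs) > tol * max(1.0, abs(lhs)):
        raise InternalConsistencyError(
            f"forward/backward score identity violated: {lhs} vs {rhs}"
        )


def state_marginals(cache: FBCache) -> tuple:
    """(T x Q single marginals, (T-1) x Q x Q pairwise marginals).

    gamma[t, l]    = p(l_t = l | U, v)
    xi[t, l, l']   = p(l_t = l, l_{t+1} = l' | U, v)
    """
    _check_cache(cache)
    la, lb, le = cache.log_alpha, cache.log_beta, cache.log_emis
    ls = cache.log_score
    # log marginals are <= 0 exactly; clamp the tiny positive excess that
    # float cancellation produces at extreme interim parameters
    gamma = np.exp(np.minimum(la + lb - ls, 0.0))
    T = la.shape[0]
    if T > 1:
        log_xi = (
            la[:-1, :, None]
            + cache.params.transition[None, :, :]
            + (le[1:] + lb[1:])[:, None, :]
            - ls
        )
        xi = np.exp(np.minimum(log_xi, 0.0))
    else:
        Q = la.shape[1]
        xi = np.zeros((0, Q, Q))
    return gamma, xi


def grad_log_score(
    params: ClassParams,
    seq: FeatureSequence,
    cache: FBCache,
    counter: Optional[CallCounter] = None,
) -> GradientBlock:
    """d log Score / d(natural parameters), from cached alpha/beta only."""
    Q, M, D = params.Q, params.M, params.D
    T = seq.T
    gamma, xi = state_marginals(cache)
    g = GradientBlock.zeros(Q, M, D)
    g.d_prior = gamma[0].copy()
    g.d_transition = xi.sum(axis=0)
    # per-frame weight on component (t, l, m): gamma_{t,l} * r_{t,l,m}
    w = gamma[:, :, None] * cache.resp
    with np.errstate(divide="ignore", invalid="ignore"):
        g.d_weights = np.where(
            params_weights(params) > 0,
            w.sum(axis=0) / params_weights(params),
            0.0,
        )
    for q, mix in enumerate(params.emissions):
        for m, comp in enumerate(mix.components):
            wt = w[:, q, m]
            diff = seq.frames - comp.mean  # T x D
            y = diff @ comp.precision  # Sigma^-1 (u - mu), rows
            g.d_means[q, m] = wt @ y
            s = float(wt.sum())
            A = (wt[:, None] * y).T @ y  # sum_t wt * y y^T
            g.d_covariances[q, m] = 0.5 * (A - s * comp.precision)
    if counter is not None:
        # linear-in-T accumulation cost at fixed (Q, M, D)
        counter.n_accum_ops += T * Q * M * (1 + D + D * D) + max(T - 1, 0) * Q * Q
    return g


def params_weights(params: ClassParams) -> np.ndarray:
    """Q x M matrix of mixture weights."""
    return np.stack([m.weights for m in params.emissions])


def grad_log_score_naive(
    params: ClassParams,
    seq: FeatureSequence,
    counter: Optional[CallCounter] = None,
) -> GradientBlock:
    """Reference implementation that re-runs forward/backward once per
    parameter family (prior, transition, weights, means, covariances), the
    way implementations without result caching do.  Used only to assert the
    caching contract on counters; returns the same GradientBlock."""
    families = ("prior", "transition", "weights", "means", "covariances")
    out = None
    for name in families:
        cache = build_cache(params, seq, counter)
        g = grad_log_score(params, seq, cache)
        if out is None:
            out = GradientBlock.zeros(params.Q, params.M, params.D)
        setattr(out, "d_" + name, getattr(g, "d_" + name))
    return out


def grad_conditional_nll(
    model: GMHCRFModel,
    batch: list,
    l2: float = 0.0,
    packing=None,
    counter: Optional[CallCounter] = None,
    theta: Optional[np.ndarray] = None,
) -> tuple:
    """(objective, flat gradient) of the regularized conditional NLL.

    objective = -sum_i log post(v_i | U_i) + (l2/2) ||theta||^2 over the
    unconstrained packed coordinates (``theta`` defaults to the packed
    model).  Exactly one forward and one backward execution per
    (sequence, class) per call.
    """
    from .packing import Packing, natural_to_flat, pack

    if packing is None:
        Q, M, D = model.dims
        packing = Packing.build(model.labels, Q, M, D)
    Q, M, D = model.dims
    nat = [GradientBlock.zeros(Q, M, D) for _ in model.labels]
    obj = 0.0
    for seq in batch:
        if seq.label is None:
            raise InputError(f"sequence {seq.seq_id!r} is unlabeled")
        if seq.label not in model.labels:
            raise InputError(
                f"sequence {seq.seq_id!r} has label {seq.label!r} outside the "
                f"model's label set"
            )
        vi = model.labels.index(seq.label)
        caches = [build_cache(c, seq, counter) for c in model.classes]
        ls = np.array([c.log_score for c in caches])
        lz = logsumexp(ls)
        post = np.exp(ls - lz)
        obj -= float(ls[vi] - lz)
        for j, (cp, cache) in enumerate(zip(model.classes, caches)):
            coeff = post[j] - (1.0 if j == vi else 0.0)
            if coeff == 0.0:
                continue
            nat[j].add_(grad_log_score(cp, seq, cache, counter), coeff)
    flat = natural_to_flat(packing, model, nat)
    if l2:
        if theta is None:
            theta = pack(model, packing)
        obj += 0.5 * l2 * float(theta @ theta)
        flat += l2 * theta
    return obj, flat
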