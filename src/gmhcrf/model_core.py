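"""Domain types and log-space scoring for the full-covariance mixture HCRF.

A model holds one parameter block per class label: a vector of prior
potentials over hidden states, a matrix of transition potentials, and a
full-covariance Gaussian mixture per hidden state.  The unnormalized log
score of a (sequence, class) pair sums, over all hidden-state paths, the
prior potential of the first state, transition potentials for steps
2..T, and per-frame log mixture densities; class posteriors normalize
the per-class scores with a global logsumexp.  All arithmetic is carried
out in the log domain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import logsumexp

from .exceptions import InputError, ModelValidityError

_LOG_2PI = float(np.log(2.0 * np.pi))


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    """logsumexp via a single pairwise ufunc reduction; scipy's wrapper has
    too much call overhead for the tiny arrays inside the chain recursions."""
    return np.logaddexp.reduce(a, axis=axis)

__all__ = [
    "FeatureSequence",
    "GaussianComponent",
    "StateMixture",
    "ClassParams",
    "GMHCRFModel",
    "FBCache",
    "log_gaussian_density",
    "log_mixture_density",
    "log_component_matrix",
    "log_emission_matrix",
    "chain_log_forward",
    "chain_log_backward",
    "forward",
    "backward",
    "brute_force_log_score",
    "class_posterior",
    "predict",
]


@dataclass
class FeatureSequence:
    """One observation sequence: a T x D matrix of real feature vectors."""

    seq_id: str
    frames: np.ndarray
    label: Optional[str] = None
    group_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2:
            raise InputError(
                f"sequence {self.seq_id!r}: frames must be 2-D (T x D), "
                f"got shape {self.frames.shape}"
            )
        T, D = self.frames.shape
        if T < 1 or D < 1:
            raise InputError(
                f"sequence {self.seq_id!r}: need T >= 1 and D >= 1, got T={T}, D={D}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise InputError(f"sequence {self.seq_id!r}: non-finite frame entries")

    @property
    def T(self) -> int:
        return self.frames.shape[0]

    @property
    def D(self) -> int:
        return self.frames.shape[1]


@dataclass
class GaussianComponent:
    """A single full-covariance Gaussian, with a cached Cholesky factor."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.covariance = np.asarray(self.covariance, dtype=float)
        D = self.mean.shape[0]
        if self.covariance.shape != (D, D):
            raise InputError(
                f"covariance shape {self.covariance.shape} does not match mean "
                f"dimension {D}"
            )
        if not np.all(np.isfinite(self.mean)) or not np.all(
            np.isfinite(self.covariance)
        ):
            raise ModelValidityError("non-finite Gaussian parameters")
        asym = np.max(np.abs(self.covariance - self.covariance.T)) if D else 0.0
        scale = max(1.0, float(np.max(np.abs(self.covariance))))
        if asym > 1e-12 * scale:
            raise ModelValidityError(
                f"covariance not symmetric (max asymmetry {asym:.3e})"
            )
        try:
            # lower-triangular factor; raises LinAlgError when not SPD
            self._chol = cholesky(self.covariance, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
            raise ModelValidityError(f"covariance not positive definite: {exc}")
        except Exception as exc:
            raise ModelValidityError(f"covariance not positive definite: {exc}")
        self._log_det = 2.0 * float(np.sum(np.log(np.diag(self._chol))))

    @property
    def D(self) -> int:
        return self.mean.shape[0]

    @property
    def chol_lower(self) -> np.ndarray:
        return self._chol

    def log_density_many(self, frames: np.ndarray) -> np.ndarray:
        """Log density at every row of ``frames`` (T x D) -> (T,)."""
        frames = np.asarray(frames, dtype=float)
        if frames.shape[1] != self.D:
            raise InputError(
                f"frame dimension {frames.shape[1]} != Gaussian dimension {self.D}"
            )
        z = solve_triangular(
            self._chol, (frames - self.mean).T, lower=True, check_finite=False
        )
        maha = np.einsum("ij,ij->j", z, z)
        return -0.5 * (self.D * _LOG_2PI + self._log_det + maha)

    @property
    def precision(self) -> np.ndarray:
        """Sigma^{-1}, lazily computed from the Cholesky factor and cached
        (used by gradient accumulation, not by density evaluation)."""
        P = getattr(self, "_prec", None)
        if P is None:
            Linv = solve_triangular(
                self._chol, np.eye(self.D), lower=True, check_finite=False
            )
            P = Linv.T @ Linv
            self._prec = P
        return P


def log_gaussian_density(u: np.ndarray, comp: GaussianComponent) -> float:
    """log N(u; mean, covariance), via triangular solves (no explicit inverse)."""
    u = np.asarray(u, dtype=float).ravel()
    if u.shape[0] != comp.D:
        raise InputError(f"vector dimension {u.shape[0]} != Gaussian dimension {comp.D}")
    return float(comp.log_density_many(u[None, :])[0])


@dataclass
class StateMixture:
    """Gaussian mixture attached to one hidden state."""

    weights: np.ndarray
    components: list

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        M = self.weights.shape[0]
        if M < 1 or len(self.components) != M:
            raise InputError(
                f"need one component per weight, got {len(self.components)} "
                f"components for {M} weights"
            )
        if np.any(self.weights < 0) or abs(float(self.weights.sum()) - 1.0) > 1e-12:
            raise ModelValidityError(
                f"mixture weights must be a probability vector, got {self.weights}"
            )
        Ds = {c.D for c in self.components}
        if len(Ds) != 1:
            raise InputError(f"components disagree on dimension: {sorted(Ds)}")

    @property
    def M(self) -> int:
        return self.weights.shape[0]

    @property
    def D(self) -> int:
        return self.components[0].D

    @property
    def log_weights(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.weights)


def log_mixture_density(u: np.ndarray, mix: StateMixture) -> float:
    """logsumexp_m [log w_m + log N(u; mu_m, Sigma_m)]; zero weights drop out."""
    terms = mix.log_weights + np.array(
        [log_gaussian_density(u, c) for c in mix.components]
    )
    return float(logsumexp(terms))


@dataclass
class ClassParams:
    """One class's potential block.

    ``prior`` and ``transition`` are unnormalized log-potentials: any real
    value (or -inf, arising from zero probabilities under the HMM mapping)
    is legal; +inf and NaN are not.
    """

    prior: np.ndarray
    transition: np.ndarray
    emissions: list

    def __post_init__(self) -> None:
        self.prior = np.asarray(self.prior, dtype=float).ravel()
        self.transition = np.asarray(self.transition, dtype=float)
        Q = self.prior.shape[0]
        if Q < 1:
            raise InputError("need Q >= 1 hidden states")
        if self.transition.shape != (Q, Q):
            raise InputError(
                f"transition shape {self.transition.shape}, expected ({Q}, {Q})"
            )
        for arr, name in ((self.prior, "prior"), (self.transition, "transition")):
            if np.any(np.isnan(arr)) or np.any(arr == np.inf):
                raise ModelValidityError(f"{name} potentials contain NaN or +inf")
        if len(self.emissions) != Q:
            raise InputError(
                f"need one StateMixture per state, got {len(self.emissions)} for Q={Q}"
            )
        if len({m.M for m in self.emissions}) != 1 or len(
            {m.D for m in self.emissions}
        ) != 1:
            raise InputError("all state mixtures must share the same (M, D)")

    @property
    def Q(self) -> int:
        return self.prior.shape[0]

    @property
    def M(self) -> int:
        return self.emissions[0].M

    @property
    def D(self) -> int:
        return self.emissions[0].D


@dataclass
class GMHCRFModel:
    """Ordered label set plus one ClassParams block per label."""

    labels: list
    classes: list

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.classes) or not self.labels:
            raise InputError("need one ClassParams per label (and at least one label)")
        if len(set(self.labels)) != len(self.labels):
            raise InputError("labels must be unique")
        dims = {(c.Q, c.M, c.D) for c in self.classes}
        if len(dims) != 1:
            raise InputError(f"class blocks disagree on (Q, M, D): {sorted(dims)}")

    @property
    def dims(self) -> tuple:
        c = self.classes[0]
        return (c.Q, c.M, c.D)

    def class_params(self, label) -> ClassParams:
        return self.classes[self.labels.index(label)]


@dataclass
class FBCache:
    """Cached forward/backward results for one (sequence, class) pair."""

    params: ClassParams
    log_alpha: np.ndarray  # T x Q
    log_beta: np.ndarray  # T x Q
    log_emis: np.ndarray  # T x Q   log mixture densities
    log_comp: np.ndarray  # T x Q x M   log w_m + log N_m
    resp: np.ndarray  # T x Q x M  mixture responsibilities
    log_score: float


# ---------------------------------------------------------------------------
# Emission matrices
# ---------------------------------------------------------------------------


def log_component_matrix(params: ClassParams, seq: FeatureSequence) -> np.ndarray:
    """T x Q x M matrix of log w_{l,m} + log N(u_t; mu_{l,m}, Sigma_{l,m})."""
    if seq.D != params.D:
        raise InputError(f"sequence dimension {seq.D} != model dimension {params.D}")
    T, Q, M = seq.T, params.Q, params.M
    out = np.empty((T, Q, M))
    for q, mix in enumerate(params.emissions):
        lw = mix.log_weights
        for m, comp in enumerate(mix.components):
            out[:, q, m] = lw[m] + comp.log_density_many(seq.frames)
    return out


def log_emission_matrix(params: ClassParams, seq: FeatureSequence) -> np.ndarray:
    """T x Q matrix of per-frame log mixture densities."""
    return _lse(log_component_matrix(params, seq), axis=2)


# ---------------------------------------------------------------------------
# Chain dynamic programs (shared by the mixture model and the diagonal
# moment-feature variant, which differ only in the per-frame potential)
# ---------------------------------------------------------------------------


def chain_log_forward(
    prior: np.ndarray, transition: np.ndarray, log_pot: np.ndarray
) -> tuple:
    """Forward recursion over per-frame state potentials.

    log_alpha[0] = prior + log_pot[0];
    log_alpha[t] = logsumexp_l'(log_alpha[t-1, l'] + transition[l', l]) + log_pot[t].
    Returns (log_alpha, log_score) with log_score = logsumexp(log_alpha[-1]).
    """
    T, Q = log_pot.shape
    log_alpha = np.empty((T, Q))
    log_alpha[0] = prior + log_pot[0]
    for t in range(1, T):
        log_alpha[t] = _lse(log_alpha[t - 1][:, None] + transition, axis=0) + log_pot[t]
    return log_alpha, float(_lse(log_alpha[-1], axis=0))


def chain_log_backward(transition: np.ndarray, log_pot: np.ndarray) -> np.ndarray:
    """Backward recursion: log_beta[T-1] = 0;
    log_beta[t] = logsumexp_l'(transition[l, l'] + log_pot[t+1, l'] + log_beta[t+1, l']).
    """
    T, Q = log_pot.shape
    log_beta = np.zeros((T, Q))
    for t in range(T - 2, -1, -1):
        log_beta[t] = _lse(
            transition + (log_pot[t + 1] + log_beta[t + 1])[None, :], axis=1
        )
    return log_beta


def forward(params: ClassParams, seq: FeatureSequence) -> tuple:
    """(log_alpha, log_score) for one class block on one sequence."""
    log_pot = log_emission_matrix(params, seq)
    return chain_log_forward(params.prior, params.transition, log_pot)


def backward(params: ClassParams, seq: FeatureSequence) -> np.ndarray:
    """log_beta for one class block on one sequence."""
    log_pot = log_emission_matrix(params, seq)
    return chain_log_backward(params.transition, log_pot)


def brute_force_log_score(params: ClassParams, seq: FeatureSequence) -> float:
    """Reference oracle: logsumexp over all Q^T hidden-state paths.

    Guarded at Q^T <= 10^6; never used on real workloads.
    """
    Q, T = params.Q, seq.T
    if Q**T > 10**6:
        raise InputError(f"brute force refused: Q^T = {Q}^{T} exceeds 10^6")
    log_pot = log_emission_matrix(params, seq)
    terms = []
    for path in itertools.product(range(Q), repeat=T):
        s = params.prior[path[0]] + log_pot[0, path[0]]
        for t in range(1, T):
            s += params.transition[path[t - 1], path[t]] + log_pot[t, path[t]]
        terms.append(s)
    return float(logsumexp(terms))


# ---------------------------------------------------------------------------
# Posterior and prediction
# ---------------------------------------------------------------------------


def log_class_scores(model: GMHCRFModel, seq: FeatureSequence) -> np.ndarray:
    """Per-class unnormalized log scores, aligned with ``model.labels``."""
    return np.array([forward(c, seq)[1] for c in model.classes])


def class_posterior(model: GMHCRFModel, seq: FeatureSequence) -> np.ndarray:
    """Posterior over class labels; sums to 1 (computed in log space)."""
    ls = log_class_scores(model, seq)
    return np.exp(ls - logsumexp(ls))


def predict(model: GMHCRFModel, seq: FeatureSequence):
    """Argmax-posterior label; ties broken by lowest label index."""
    ls = log_class_scores(model, seq)
    return model.labels[int(np.argmax(ls))]
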