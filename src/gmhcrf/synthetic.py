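"""Seeded GMM-HMM simulator and named dataset presets.

Each class is a generative Gaussian-mixture HMM; sequences are sampled
ancestrally (state chain, then mixture component, then Gaussian draw).
Because the generator's true parameters are known, a Bayes-reference
classifier (per-class likelihood ratio under the true HMMs) gives an
accuracy ceiling for any fitted model on the same data.

Presets (all numbers exact; also listed in the README):

``separable`` — 3 classes, D=2, Q=2, M=1, T=30.
    Shared initial (0.6, 0.4) and transition [[0.9, 0.1], [0.2, 0.8]].
    State means: class c0 (0,0) and (0,4); c1 (6,0) and (6,4);
    c2 (12,0) and (12,4).  All covariances identity.  Class mean gap 6
    with unit sigma, so the Bayes classifier is near-perfect.

``correlated`` — 2 classes, D=2, Q=2, M=1, T=30.
    Shared initial (0.5, 0.5) and transition [[0.85, 0.15], [0.15, 0.85]].
    State means: c0 (0,0) and (4,4); c1 (0.2, 0) and (4.2, 4).
    Covariances have unit variances with correlation +0.9 (c0) versus
    -0.9 (c1).  The state clusters are 4 sigma apart and shared between
    the classes, so hidden states are pinned to cluster locations and
    almost the entire class signal lives in the correlation sign;
    forcing diagonal covariances destroys it.

``hard`` — 3 classes, D=2, Q=2, M=2, T=30.
    Shared initial (0.5, 0.5) and transition [[0.8, 0.2], [0.2, 0.8]];
    equal component weights (0.5, 0.5); all covariances 1.5 * I.
    Bimodal state means (per class, state, component):
        c0: s0 {(0,0), (2,2)},  s1 {(0,3), (2,5)}
        c1: s0 {(1,0), (3,2)},  s1 {(1,3), (3,5)}
        c2: s0 {(0,1), (2,3)},  s1 {(0,4), (2,6)}
    Classes overlap heavily; accuracy well below 100% by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .baselines import GaussianHMM, hmm_log_likelihood
from .exceptions import InputError
from .model_core import FeatureSequence, GaussianComponent, StateMixture

__all__ = [
    "SyntheticSpec",
    "simulate_sequence",
    "simulate_dataset",
    "default_specs",
    "bayes_log_scores",
    "bayes_predict",
    "diagonalized_spec",
]


@dataclass
class SyntheticSpec:
    """Generative parameters: one GaussianHMM per class plus sampling plan."""

    classes: Dict[str, GaussianHMM]
    T: Union[int, Tuple[int, int]]  # fixed length or inclusive (lo, hi) range
    n_sequences: int  # per class
    seed: int = 0
    n_groups: int = 5  # pseudo-subjects, assigned round-robin

    def __post_init__(self) -> None:
        if not self.classes:
            raise InputError("spec needs at least one class")
        Ds = {h.D for h in self.classes.values()}
        if len(Ds) != 1:
            raise InputError("all classes must share D")
        if self.n_sequences < 1 or self.n_groups < 1:
            raise InputError("need n_sequences >= 1 and n_groups >= 1")

    @property
    def D(self) -> int:
        return next(iter(self.classes.values())).D

    @property
    def labels(self) -> list:
        return list(self.classes.keys())


def _draw_T(T, rng: np.random.Generator) -> int:
    if isinstance(T, int):
        return T
    lo, hi = T
    return int(rng.integers(lo, hi + 1))


def simulate_sequence(
    hmm: GaussianHMM,
    T: int,
    rng: np.random.Generator,
    seq_id: str = "seq",
    label: Optional[str] = None,
    group_id: Optional[str] = None,
) -> FeatureSequence:
    """Ancestral sampling: state chain, then component, then Gaussian draw."""
    if T < 1:
        raise InputError("need T >= 1")
    frames = np.empty((T, hmm.D))
    state = int(rng.choice(hmm.Q, p=hmm.initial))
    for t in range(T):
        if t > 0:
            state = int(rng.choice(hmm.Q, p=hmm.transition[state]))
        mix = hmm.emissions[state]
        m = int(rng.choice(mix.M, p=mix.weights))
        comp = mix.components[m]
        frames[t] = rng.multivariate_normal(comp.mean, comp.covariance)
    return FeatureSequence(seq_id=seq_id, frames=frames, label=label, group_id=group_id)


def simulate_dataset(spec: SyntheticSpec, seed: Optional[int] = None) -> List[FeatureSequence]:
    """n_sequences per class with labels and round-robin pseudo-subject groups."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    out: List[FeatureSequence] = []
    i = 0
    for lab, hmm in spec.classes.items():
        for j in range(spec.n_sequences):
            T = _draw_T(spec.T, rng)
            out.append(
                simulate_sequence(
                    hmm,
                    T,
                    rng,
                    seq_id=f"{lab}_{j:04d}",
                    label=lab,
                    group_id=f"g{i % spec.n_groups}",
                )
            )
            i += 1
    return out


# ---------------------------------------------------------------------------
# Bayes-reference classifier
# ---------------------------------------------------------------------------


def bayes_log_scores(spec: SyntheticSpec, seq: FeatureSequence) -> np.ndarray:
    """Per-class log-likelihoods under the TRUE generative parameters
    (uniform class prior)."""
    return np.array([hmm_log_likelihood(h, seq) for h in spec.classes.values()])


def bayes_predict(spec: SyntheticSpec, seq: FeatureSequence):
    return spec.labels[int(np.argmax(bayes_log_scores(spec, seq)))]


def diagonalized_spec(spec: SyntheticSpec) -> SyntheticSpec:
    """Copy of the spec with every covariance forced to its diagonal."""
    classes = {}
    for lab, h in spec.classes.items():
        emissions = [
            StateMixture(
                mix.weights.copy(),
                [
                    GaussianComponent(c.mean.copy(), np.diag(np.diag(c.covariance)))
                    for c in mix.components
                ],
            )
            for mix in h.emissions
        ]
        classes[lab] = GaussianHMM(h.initial.copy(), h.transition.copy(), emissions)
    return SyntheticSpec(
        classes, spec.T, spec.n_sequences, seed=spec.seed, n_groups=spec.n_groups
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def _cov(var: float, corr: float = 0.0) -> np.ndarray:
    return np.array([[var, corr * var], [corr * var, var]])


def _hmm(initial, transition, state_means, covs, weights=None) -> GaussianHMM:
    """state_means: per state, list of component means; covs parallel."""
    emissions = []
    for means_q, covs_q in zip(state_means, covs):
        M = len(means_q)
        w = np.full(M, 1.0 / M) if weights is None else np.asarray(weights, dtype=float)
        emissions.append(
            StateMixture(
                w,
                [GaussianComponent(np.asarray(mu, dtype=float), cv) for mu, cv in zip(means_q, covs_q)],
            )
        )
    return GaussianHMM(np.asarray(initial, dtype=float), np.asarray(transition, dtype=float), emissions)


def default_specs(
    n_sequences: int = 30, T: Union[int, Tuple[int, int]] = 30, seed: int = 0
) -> Dict[str, SyntheticSpec]:
    """The three named presets (numbers documented in the module docstring)."""
    I2 = np.eye(2)
    sep_classes = {}
    for k, x0 in zip(("c0", "c1", "c2"), (0.0, 6.0, 12.0)):
        sep_classes[k] = _hmm(
            (0.6, 0.4),
            [[0.9, 0.1], [0.2, 0.8]],
            [[(x0, 0.0)], [(x0, 4.0)]],
            [[I2], [I2]],
        )
    separable = SyntheticSpec(sep_classes, T, n_sequences, seed=seed)

    corr_classes = {
        "c0": _hmm(
            (0.5, 0.5),
            [[0.85, 0.15], [0.15, 0.85]],
            [[(0.0, 0.0)], [(4.0, 4.0)]],
            [[_cov(1.0, 0.9)], [_cov(1.0, 0.9)]],
        ),
        "c1": _hmm(
            (0.5, 0.5),
            [[0.85, 0.15], [0.15, 0.85]],
            [[(0.2, 0.0)], [(4.2, 4.0)]],
            [[_cov(1.0, -0.9)], [_cov(1.0, -0.9)]],
        ),
    }
    correlated = SyntheticSpec(corr_classes, T, n_sequences, seed=seed)

    C15 = 1.5 * np.eye(2)
    hard_means = {
        "c0": [[(0.0, 0.0), (2.0, 2.0)], [(0.0, 3.0), (2.0, 5.0)]],
        "c1": [[(1.0, 0.0), (3.0, 2.0)], [(1.0, 3.0), (3.0, 5.0)]],
        "c2": [[(0.0, 1.0), (2.0, 3.0)], [(0.0, 4.0), (2.0, 6.0)]],
    }
    hard_classes = {
        k: _hmm(
            (0.5, 0.5),
            [[0.8, 0.2], [0.2, 0.8]],
            means,
            [[C15, C15], [C15, C15]],
        )
        for k, means in hard_means.items()
    }
    hard = SyntheticSpec(hard_classes, T, n_sequences, seed=seed)

    return {"separable": separable, "correlated": correlated, "hard": hard}
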