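"""Finite-difference verification of the analytic gradients.

Draws random small models and sequences, compares the analytic gradient
of the conditional NLL against central differences over the flat
unconstrained vector, and reports the worst coordinate.  Backs the
``gradcheck`` CLI subcommand and the acceptance suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .gradients import grad_conditional_nll
from .model_core import (
    ClassParams,
    FeatureSequence,
    GaussianComponent,
    GMHCRFModel,
    StateMixture,
)
from .packing import Packing, pack, unpack

__all__ = ["random_model", "random_sequence", "fd_gradient", "run_gradcheck", "GradCheckResult"]


def random_spd(rng: np.random.Generator, D: int) -> np.ndarray:
    A = rng.normal(size=(D, D))
    return A @ A.T + D * np.eye(D)


def random_model(
    rng: np.random.Generator,
    n_classes: int = 2,
    Q: int = 2,
    M: int = 2,
    D: int = 2,
) -> GMHCRFModel:
    """Random valid model with O(1)-scale potentials."""
    labels = [f"v{i}" for i in range(n_classes)]
    classes = []
    for _ in labels:
        emissions = []
        for _q in range(Q):
            w = rng.dirichlet(np.ones(M) * 5.0)
            comps = [
                GaussianComponent(rng.normal(scale=2.0, size=D), random_spd(rng, D))
                for _m in range(M)
            ]
            emissions.append(StateMixture(w, comps))
        classes.append(
            ClassParams(
                rng.normal(scale=0.5, size=Q),
                rng.normal(scale=0.5, size=(Q, Q)),
                emissions,
            )
        )
    return GMHCRFModel(labels, classes)


def random_sequence(
    rng: np.random.Generator, T: int, D: int, label: Optional[str] = None
) -> FeatureSequence:
    return FeatureSequence(
        seq_id="r", frames=rng.normal(scale=2.0, size=(T, D)), label=label
    )


def fd_gradient(
    theta: np.ndarray, packing: Packing, batch: list, l2: float, step: float = 1e-5
) -> np.ndarray:
    """Central finite differences of the conditional NLL over the flat vector."""
    g = np.empty_like(theta)
    for i in range(theta.size):
        tp = theta.copy()
        tp[i] += step
        fp, _ = grad_conditional_nll(unpack(tp, packing), batch, l2, packing, theta=tp)
        tm = theta.copy()
        tm[i] -= step
        fm, _ = grad_conditional_nll(unpack(tm, packing), batch, l2, packing, theta=tm)
        g[i] = (fp - fm) / (2.0 * step)
    return g


@dataclass
class GradCheckResult:
    ok: bool
    worst_rel_err: float
    worst_coord: int
    worst_trial: int
    n_trials: int


def run_gradcheck(
    seed: int = 0,
    trials: int = 20,
    tol: float = 1e-4,
    abs_floor: float = 1e-6,
    l2: float = 0.1,
    covariance: str = "full",
) -> GradCheckResult:
    """Compare analytic vs central-difference gradients on random instances."""
    rng = np.random.default_rng(seed)
    worst = (0.0, -1, -1)
    for trial in range(trials):
        n_classes = int(rng.integers(2, 4))
        Q = int(rng.integers(1, 4))
        M = int(rng.integers(1, 3))
        D = int(rng.integers(1, 4))
        T = int(rng.integers(1, 9))
        model = random_model(rng, n_classes, Q, M, D)
        if covariance == "diag":
            model = _diagonalize(model)
        packing = Packing.build(model.labels, Q, M, D, covariance=covariance)
        label = model.labels[int(rng.integers(n_classes))]
        batch = [random_sequence(rng, T, D, label=label)]
        theta = pack(model, packing)
        _, g = grad_conditional_nll(model, batch, l2, packing, theta=theta)
        g_fd = fd_gradient(theta, packing, batch, l2)
        denom = np.maximum(np.abs(g_fd), abs_floor / tol)
        rel = np.abs(g - g_fd) / denom
        i = int(np.argmax(rel))
        if rel[i] > worst[0]:
            worst = (float(rel[i]), i, trial)
    return GradCheckResult(
        ok=worst[0] <= tol,
        worst_rel_err=worst[0],
        worst_coord=worst[1],
        worst_trial=worst[2],
        n_trials=trials,
    )


def _diagonalize(model: GMHCRFModel) -> GMHCRFModel:
    classes = []
    for cp in model.classes:
        emissions = [
            StateMixture(
                mix.weights.copy(),
                [
                    GaussianComponent(c.mean.copy(), np.diag(np.diag(c.covariance)))
                    for c in mix.components
                ],
            )
            for mix in cp.emissions
        ]
        classes.append(ClassParams(cp.prior.copy(), cp.transition.copy(), emissions))
    return GMHCRFModel(list(model.labels), classes)
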