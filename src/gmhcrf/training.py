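"""Initialization and L-BFGS training of the conditional likelihood.

The constrained model is mapped to one flat unconstrained vector (see
:mod:`gmhcrf.packing`) and the regularized conditional negative
log-likelihood is minimized with scipy's limited-memory BFGS.  Prior and
transition potentials initialize to zero; emission mixtures initialize
from a seeded k-means clustering of the per-class frame pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize
from sklearn.cluster import KMeans

from .exceptions import InputError
from .gradients import CallCounter, grad_conditional_nll
from .model_core import (
    ClassParams,
    FeatureSequence,
    GaussianComponent,
    GMHCRFModel,
    StateMixture,
)
from .packing import Packing, pack, unpack

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "initialize", "fit", "pack", "unpack", "Packing"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of one training run."""

    Q: int = 2
    M: int = 1
    l2: float = 0.01
    lbfgs_memory: int = 10
    grad_tol: float = 1e-5
    max_iter: int = 200
    seed: int = 0
    init: str = "kmeans"  # "kmeans" | "random"
    covariance: str = "full"  # "full" | "diag"

    def __post_init__(self) -> None:
        if self.Q < 1 or self.M < 1:
            raise InputError("need Q >= 1 and M >= 1")
        if self.l2 < 0 or self.max_iter < 0:
            raise InputError("need l2 >= 0 and max_iter >= 0")
        if self.init not in ("kmeans", "random"):
            raise InputError(f"unknown init {self.init!r}")
        if self.covariance not in ("full", "diag"):
            raise InputError(f"unknown covariance mode {self.covariance!r}")


def dataset_labels(dataset: List[FeatureSequence]) -> list:
    """Sorted unique labels of a labeled dataset."""
    labels = sorted({s.label for s in dataset if s.label is not None})
    if not labels:
        raise InputError("dataset has no labeled sequences")
    return labels


def _cluster_covariance(
    points: np.ndarray, pooled_scatter: np.ndarray, ridge: float, diag: bool
) -> np.ndarray:
    D = points.shape[1]
    if points.shape[0] > D:
        S = np.cov(points, rowvar=False, bias=True)
        S = np.atleast_2d(S)
    else:
        S = pooled_scatter.copy()
    S = S + ridge * np.eye(D)
    if diag:
        S = np.diag(np.diag(S))
    # guard against residual non-PD from degenerate clusters
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        S = pooled_scatter + ridge * np.eye(D)
        if diag:
            S = np.diag(np.diag(S))
    return S


def initialize(dataset: List[FeatureSequence], config: TrainConfig) -> GMHCRFModel:
    """Seeded per-class initialization; prior/transition potentials are zero."""
    labels = dataset_labels(dataset)
    Q, M = config.Q, config.M
    D = dataset[0].D
    diag = config.covariance == "diag"
    rng = np.random.default_rng(config.seed)
    classes = []
    for lab in labels:
        frames = np.concatenate(
            [s.frames for s in dataset if s.label == lab], axis=0
        )
        if frames.shape[0] < Q * M:
            raise InputError(
                f"class {lab!r} has {frames.shape[0]} frames, fewer than Q*M = {Q * M}"
            )
        pooled = np.atleast_2d(np.cov(frames, rowvar=False, bias=True))
        ridge = max(1e-6 * float(np.trace(pooled)) / D, 1e-6)
        if config.init == "kmeans" and Q * M > 1:
            km = KMeans(n_clusters=Q * M, n_init=10, random_state=config.seed)
            assign = km.fit_predict(frames)
            centers = km.cluster_centers_
        else:
            idx = rng.choice(frames.shape[0], size=Q * M, replace=False)
            centers = frames[idx]
            assign = np.argmin(
                ((frames[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
            )
        emissions = []
        for q in range(Q):
            comps = []
            for m in range(M):
                j = q * M + m
                pts = frames[assign == j]
                cov = _cluster_covariance(pts, pooled, ridge, diag)
                comps.append(GaussianComponent(centers[j].copy(), cov))
            emissions.append(StateMixture(np.full(M, 1.0 / M), comps))
        classes.append(ClassParams(np.zeros(Q), np.zeros((Q, Q)), emissions))
    return GMHCRFModel(labels, classes)


def fit(
    dataset: List[FeatureSequence],
    config: TrainConfig,
    counter: Optional[CallCounter] = None,
) -> Tuple[GMHCRFModel, List[float]]:
    """Minimize the regularized conditional NLL with L-BFGS.

    Returns the best-objective model seen and the accepted-iterate
    objective history (initial value first).
    """
    model0 = initialize(dataset, config)
    Q, M, D = model0.dims
    packing = Packing.build(model0.labels, Q, M, D, covariance=config.covariance)
    theta0 = pack(model0, packing)

    state = {"best_f": np.inf, "best_theta": theta0.copy(), "last_f": np.inf}

    def objective(theta: np.ndarray):
        model = unpack(theta, packing)
        f, g = grad_conditional_nll(
            model, dataset, l2=config.l2, packing=packing, counter=counter, theta=theta
        )
        state["last_f"] = f
        if f < state["best_f"]:
            state["best_f"] = f
            state["best_theta"] = np.array(theta, copy=True)
        return f, g

    f0, _ = objective(theta0)
    if not np.isfinite(f0):
        raise InputError(
            "objective non-finite at initialization; increase the ridge/l2 "
            "or check the data scale"
        )
    history = [f0]
    if config.max_iter == 0:
        return model0, history

    def callback(theta_k: np.ndarray) -> None:
        history.append(state["last_f"])
        logger.info(
            "iter=%d objective=%.6f", len(history) - 1, state["last_f"]
        )

    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={
            "maxiter": config.max_iter,
            "maxcor": config.lbfgs_memory,
            "gtol": config.grad_tol,
            "ftol": 1e-12,
        },
    )
    # status 1 is the iteration cap (normal termination here); status 2 is an
    # abnormal stop such as a failed line search
    if not res.success and res.status != 1:
        logger.warning(
            "L-BFGS stopped abnormally (%s); returning best iterate", res.message
        )
    best = unpack(state["best_theta"], packing)
    return best, history
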