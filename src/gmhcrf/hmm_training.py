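"""Optional generative HMM baseline trainer (requires hmmlearn).

Fits one maximum-likelihood Gaussian(-mixture) HMM per class and maps it
to potential form via :func:`gmhcrf.baselines.hcrf_from_hmm`, so the
result is scored, serialized, and evaluated like any other model.
"""

from __future__ import annotations

import numpy as np

from .exceptions import GMHCRFError, InputError
from .model_core import GMHCRFModel
from .baselines import GaussianHMM, hcrf_from_hmm
from .model_core import GaussianComponent, StateMixture
from .training import TrainConfig, dataset_labels

__all__ = ["fit_hmm_model"]

# zero transition probabilities map to -inf potentials; floor them instead so
# the potential block stays finite for unseen transitions
_PROB_FLOOR = 1e-10


def _floor_stochastic(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), _PROB_FLOOR, None)
    return p / p.sum(axis=-1, keepdims=True)


def fit_hmm_model(dataset, config: TrainConfig) -> GMHCRFModel:
    """Per-class ML HMM training (EM), returned as a potential-form model."""
    try:
        from hmmlearn import hmm as _hmm
    except ImportError as exc:  # pragma: no cover
        raise GMHCRFError(
            "the 'hmm' model kind requires hmmlearn (pip install gmhcrf[hmm])"
        ) from exc

    labels = dataset_labels(dataset)
    classes = []
    for lab in labels:
        seqs = [s for s in dataset if s.label == lab]
        X = np.concatenate([s.frames for s in seqs], axis=0)
        lengths = [s.T for s in seqs]
        if config.M == 1:
            est = _hmm.GaussianHMM(
                n_components=config.Q,
                covariance_type="full",
                n_iter=100,
                random_state=config.seed,
                min_covar=1e-6,
            )
            est.fit(X, lengths)
            emissions = [
                StateMixture(
                    np.array([1.0]),
                    [GaussianComponent(est.means_[q], _symmetrize(est.covars_[q]))],
                )
                for q in range(config.Q)
            ]
        else:
            est = _hmm.GMMHMM(
                n_components=config.Q,
                n_mix=config.M,
                covariance_type="full",
                n_iter=100,
                random_state=config.seed,
            )
            est.fit(X, lengths)
            emissions = []
            for q in range(config.Q):
                w = _floor_stochastic(est.weights_[q])
                comps = [
                    GaussianComponent(est.means_[q, m], _symmetrize(est.covars_[q, m]))
                    for m in range(config.M)
                ]
                emissions.append(StateMixture(w, comps))
        hmm_model = GaussianHMM(
            _floor_stochastic(est.startprob_),
            _floor_stochastic(est.transmat_),
            emissions,
        )
        classes.append(hcrf_from_hmm(hmm_model))
    return GMHCRFModel(labels, classes)


def _symmetrize(S: np.ndarray) -> np.ndarray:
    return 0.5 * (S + S.T)
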