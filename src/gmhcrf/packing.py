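"""Bijection between model parameters and one flat unconstrained vector.

Families and transforms, per class block:

* prior, transition, means — identity (already unconstrained potentials).
* mixture weights — centred log / softmax pair, so any finite logit
  vector unpacks to a simplex point and zeros unpack to uniform weights.
* covariances — lower-triangular Cholesky factor with log-diagonal, so
  any finite vector unpacks to an SPD matrix and zeros unpack to the
  identity.  A ``diag`` covariance mode keeps only the log-diagonal
  coordinates (the diagonal-covariance constrained variant).

``natural_to_flat`` pushes gradients taken in natural coordinates
(through ``gradients.GradientBlock``) to the flat coordinates by the
chain rule of these transforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .exceptions import InputError
from .model_core import ClassParams, GaussianComponent, GMHCRFModel, StateMixture

# keep exp() of the Cholesky log-diagonal inside float64 comfort zone
_LOGDIAG_CLIP = 30.0

__all__ = ["Packing", "pack", "unpack", "natural_to_flat"]


@dataclass(frozen=True)
class LayoutRecord:
    label: object
    family: str
    shape: Tuple[int, ...]
    offset: int
    size: int


@dataclass(frozen=True)
class Packing:
    """Layout of the flat parameter vector for fixed (labels, Q, M, D)."""

    labels: tuple
    Q: int
    M: int
    D: int
    covariance: str  # "full" | "diag"
    layout: tuple
    size: int

    @staticmethod
    def build(labels, Q: int, M: int, D: int, covariance: str = "full") -> "Packing":
        if covariance not in ("full", "diag"):
            raise InputError(f"unknown covariance mode {covariance!r}")
        n_chol = D + D * (D - 1) // 2 if covariance == "full" else D
        records: List[LayoutRecord] = []
        off = 0
        for lab in labels:
            for family, shape in (
                ("prior", (Q,)),
                ("transition", (Q, Q)),
                ("weights", (Q, M)),
                ("means", (Q, M, D)),
                ("covariances", (Q, M, n_chol)),
            ):
                size = int(np.prod(shape))
                records.append(LayoutRecord(lab, family, shape, off, size))
                off += size
        return Packing(tuple(labels), Q, M, D, covariance, tuple(records), off)

    def slices(self, label) -> dict:
        return {
            r.family: (slice(r.offset, r.offset + r.size), r.shape)
            for r in self.layout
            if r.label == label
        }


def _tril_indices(D: int):
    # diagonal first, then strict lower part, row-major
    rows, cols = np.tril_indices(D, k=-1)
    return rows, cols


def _chol_to_coords(L: np.ndarray, covariance: str) -> np.ndarray:
    D = L.shape[0]
    logdiag = np.log(np.diag(L))
    if covariance == "diag":
        return logdiag
    rows, cols = _tril_indices(D)
    return np.concatenate([logdiag, L[rows, cols]])


def _coords_to_chol(v: np.ndarray, D: int, covariance: str) -> np.ndarray:
    L = np.zeros((D, D))
    logdiag = np.clip(v[:D], -_LOGDIAG_CLIP, _LOGDIAG_CLIP)
    np.fill_diagonal(L, np.exp(logdiag))
    if covariance == "full":
        rows, cols = _tril_indices(D)
        L[rows, cols] = v[D:]
    return L


def pack(model: GMHCRFModel, packing: Packing) -> np.ndarray:
    """Model -> flat vector (inverse of :func:`unpack` on valid models)."""
    Q, M, D = model.dims
    if (Q, M, D) != (packing.Q, packing.M, packing.D) or tuple(
        model.labels
    ) != packing.labels:
        raise InputError("packing layout does not match model dimensions/labels")
    theta = np.empty(packing.size)
    for lab, cp in zip(model.labels, model.classes):
        sl = packing.slices(lab)
        theta[sl["prior"][0]] = cp.prior
        theta[sl["transition"][0]] = cp.transition.ravel()
        wlog = np.empty((Q, M))
        mean_blk = np.empty((Q, M, D))
        chol_blk = np.empty(sl["covariances"][1])
        for q, mix in enumerate(cp.emissions):
            lw = np.log(np.clip(mix.weights, 1e-300, None))
            wlog[q] = lw - lw.mean()
            for m, comp in enumerate(mix.components):
                mean_blk[q, m] = comp.mean
                chol_blk[q, m] = _chol_to_coords(comp.chol_lower, packing.covariance)
        theta[sl["weights"][0]] = wlog.ravel()
        theta[sl["means"][0]] = mean_blk.ravel()
        theta[sl["covariances"][0]] = chol_blk.ravel()
    return theta


def unpack(theta: np.ndarray, packing: Packing) -> GMHCRFModel:
    """Flat vector -> valid model (simplex weights, SPD covariances)."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (packing.size,):
        raise InputError(
            f"flat vector has shape {theta.shape}, layout expects ({packing.size},)"
        )
    Q, M, D = packing.Q, packing.M, packing.D
    classes = []
    for lab in packing.labels:
        sl = packing.slices(lab)
        prior = theta[sl["prior"][0]].copy()
        transition = theta[sl["transition"][0]].reshape(Q, Q).copy()
        wlog = theta[sl["weights"][0]].reshape(Q, M)
        means = theta[sl["means"][0]].reshape(Q, M, D)
        chol = theta[sl["covariances"][0]].reshape(sl["covariances"][1])
        emissions = []
        for q in range(Q):
            z = wlog[q] - wlog[q].max()
            w = np.exp(z)
            w /= w.sum()
            comps = []
            for m in range(M):
                L = _coords_to_chol(chol[q, m], D, packing.covariance)
                comps.append(GaussianComponent(means[q, m].copy(), L @ L.T))
            emissions.append(StateMixture(w, comps))
        classes.append(ClassParams(prior, transition, emissions))
    return GMHCRFModel(list(packing.labels), classes)


def natural_to_flat(packing: Packing, model: GMHCRFModel, nat_blocks: list) -> np.ndarray:
    """Chain rule from natural-coordinate gradients to the flat vector.

    ``nat_blocks`` is one ``GradientBlock`` per class, aligned with
    ``model.labels``; d_covariances entries are symmetrized before the
    Cholesky chain rule.
    """
    Q, M, D = packing.Q, packing.M, packing.D
    flat = np.zeros(packing.size)
    for lab, cp, g in zip(model.labels, model.classes, nat_blocks):
        sl = packing.slices(lab)
        flat[sl["prior"][0]] = g.d_prior
        flat[sl["transition"][0]] = g.d_transition.ravel()
        wgrad = np.empty((Q, M))
        chol_grad = np.empty(sl["covariances"][1])
        for q, mix in enumerate(cp.emissions):
            w = mix.weights
            gw = g.d_weights[q]
            # softmax-logits Jacobian
            wgrad[q] = w * (gw - float(w @ gw))
            for m, comp in enumerate(mix.components):
                G = g.d_covariances[q, m]
                Gs = 0.5 * (G + G.T)
                L = comp.chol_lower
                dL = 2.0 * (Gs @ L)
                dL = np.tril(dL)
                # log-diagonal parameterization: dF/ds_i = dF/dL_ii * L_ii
                diag_grad = np.diag(dL) * np.diag(L)
                if packing.covariance == "diag":
                    chol_grad[q, m] = diag_grad
                else:
                    rows, cols = _tril_indices(D)
                    chol_grad[q, m] = np.concatenate([diag_grad, dL[rows, cols]])
        flat[sl["weights"][0]] = wgrad.ravel()
        flat[sl["means"][0]] = g.d_means.ravel()
        flat[sl["covariances"][0]] = chol_grad.ravel()
    return flat
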