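"""Readers/writers: sequence CSV tables and model JSON documents.

CSV contract (UTF-8, comma-separated, mandatory header):
    seq_id, group_id, label, t, f0 .. f{D-1}
with 0-based contiguous ``t`` per sequence; ``group_id``/``label`` may be
empty.  Model JSON is schema-versioned and round-trips losslessly (floats
are serialized at full shortest-round-trip precision).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .exceptions import InputError, ModelValidityError
from .model_core import (
    ClassParams,
    FeatureSequence,
    GaussianComponent,
    GMHCRFModel,
    StateMixture,
)

MODEL_FORMAT_VERSION = 1

__all__ = [
    "DatasetTable",
    "read_sequences",
    "write_sequences",
    "read_model",
    "write_model",
]


@dataclass
class DatasetTable:
    """Parsed sequence table with inferred dimension and label set."""

    sequences: List[FeatureSequence]
    D: int
    labels: list  # sorted distinct non-empty labels


def _feature_columns(columns) -> List[str]:
    feats = [c for c in columns if c.startswith("f") and c[1:].isdigit()]
    feats.sort(key=lambda c: int(c[1:]))
    expected = [f"f{i}" for i in range(len(feats))]
    if not feats or feats != expected:
        raise InputError(
            f"feature columns must be f0..f{{D-1}} with no gaps, found {feats}"
        )
    return feats


def read_sequences(path) -> DatasetTable:
    """Parse and validate a sequence CSV; errors cite 1-based file lines."""
    df = pd.read_csv(path, dtype={"seq_id": str, "group_id": str, "label": str})
    required = ["seq_id", "group_id", "label", "t"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    feats = _feature_columns(df.columns)
    # line number of a dataframe row: +2 for header and 1-based indexing
    sequences = []
    for seq_id, g in df.groupby("seq_id", sort=True):
        lines = (g.index + 2).tolist()
        t_vals = g["t"].tolist()
        if sorted(t_vals) != list(range(len(t_vals))):
            dup = g[g["t"].duplicated()]
            if not dup.empty:
                raise InputError(
                    f"{path}: duplicated (seq_id, t) at line {int(dup.index[0]) + 2} "
                    f"(seq_id={seq_id!r})"
                )
            raise InputError(
                f"{path}: sequence {seq_id!r} (first line {lines[0]}) has "
                f"non-contiguous t values {sorted(t_vals)[:5]}..."
            )
        labels = {v for v in g["label"] if isinstance(v, str) and v != ""}
        if len(labels) > 1:
            raise InputError(
                f"{path}: sequence {seq_id!r} (first line {lines[0]}) has "
                f"conflicting labels {sorted(labels)}"
            )
        groups = {v for v in g["group_id"] if isinstance(v, str) and v != ""}
        if len(groups) > 1:
            raise InputError(
                f"{path}: sequence {seq_id!r} (first line {lines[0]}) has "
                f"conflicting group ids {sorted(groups)}"
            )
        g = g.sort_values("t")
        frames = g[feats].to_numpy(dtype=float)
        if not np.all(np.isfinite(frames)):
            bad = int(g.index[~np.isfinite(frames).all(axis=1)][0]) + 2
            raise InputError(f"{path}: non-finite feature value at line {bad}")
        sequences.append(
            FeatureSequence(
                seq_id=str(seq_id),
                frames=frames,
                label=next(iter(labels)) if labels else None,
                group_id=next(iter(groups)) if groups else None,
            )
        )
    if not sequences:
        raise InputError(f"{path}: no sequences found")
    label_set = sorted({s.label for s in sequences if s.label is not None})
    return DatasetTable(sequences=sequences, D=len(feats), labels=label_set)


def write_sequences(sequences: List[FeatureSequence], path) -> None:
    if not sequences:
        raise InputError("refusing to write an empty dataset")
    D = sequences[0].D
    rows = []
    for s in sequences:
        if s.D != D:
            raise InputError("sequences disagree on dimension D")
        for t in range(s.T):
            rows.append(
                [s.seq_id, s.group_id or "", s.label or "", t, *s.frames[t].tolist()]
            )
    cols = ["seq_id", "group_id", "label", "t"] + [f"f{i}" for i in range(D)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model JSON
# ---------------------------------------------------------------------------


def write_model(model: GMHCRFModel, path) -> None:
    Q, M, D = model.dims
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "labels": list(model.labels),
        "Q": Q,
        "M": M,
        "D": D,
        "classes": {},
    }
    for lab, cp in zip(model.labels, model.classes):
        doc["classes"][str(lab)] = {
            "prior": cp.prior.tolist(),
            "transition": cp.transition.tolist(),
            "states": [
                {
                    "weights": mix.weights.tolist(),
                    "means": [c.mean.tolist() for c in mix.components],
                    "covariances": [c.covariance.tolist() for c in mix.components],
                }
                for mix in cp.emissions
            ],
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_model(path) -> GMHCRFModel:
    """Load and fully re-validate a model JSON (SPD, simplex, shapes)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise InputError(
            f"{path}: unknown format_version {version!r} "
            f"(this reader understands {MODEL_FORMAT_VERSION})"
        )
    try:
        labels = list(doc["labels"])
        Q, M, D = int(doc["Q"]), int(doc["M"]), int(doc["D"])
        classes = []
        for lab in labels:
            blk = doc["classes"][str(lab)]
            emissions = []
            for st in blk["states"]:
                comps = [
                    GaussianComponent(np.array(mu), np.array(cv))
                    for mu, cv in zip(st["means"], st["covariances"])
                ]
                emissions.append(StateMixture(np.array(st["weights"]), comps))
            classes.append(
                ClassParams(np.array(blk["prior"]), np.array(blk["transition"]), emissions)
            )
        model = GMHCRFModel(labels, classes)
    except KeyError as exc:
        raise InputError(f"{path}: malformed model document (missing {exc})")
    if model.dims != (Q, M, D):
        raise ModelValidityError(
            f"{path}: declared dims {(Q, M, D)} do not match stored parameters "
            f"{model.dims}"
        )
    return model
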