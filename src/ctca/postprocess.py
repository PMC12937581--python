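"""Normalization and interpretation of fitted loadings.

A fitted CP model carries a per-factor scale ambiguity: any loading
column can be rescaled if another column of the same factor is rescaled
inversely. :func:`normalize_model` resolves this into a canonical form
(unit-L2 columns, scale absorbed into explicit per-modality factor
weights). For display, loadings are conventionally rescaled per factor
to their maximum so the strongest element is 1, and joint
sender-receiver loadings are the outer product of the two shared cell
loading vectors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tensors import DomainError, FactorModel


class DegenerateFactorError(ValueError):
    """A factor has an all-zero loading column."""


def normalize_model(model: FactorModel) -> FactorModel:
    """Rescale every loading column to unit L2 norm.

    The products of the removed norms are absorbed into weights_a
    (contexts * lr_a * senders * receivers) and weights_b (contexts *
    lr_b * senders * receivers), so both reconstructions are unchanged.
    """
    new = model.copy()
    norms = {}
    for name in ("contexts", "lr_a", "lr_b", "senders", "receivers"):
        mat = getattr(new, name)
        n = np.linalg.norm(mat, axis=0)
        dead = np.flatnonzero(n == 0)
        if dead.size:
            raise DegenerateFactorError(
                f"all-zero {name} column for factor {int(dead[0]) + 1}"
            )
        setattr(new, name, mat / n)
        norms[name] = n
    shared = norms["contexts"] * norms["senders"] * norms["receivers"]
    new.weights_a = model.weights_a * shared * norms["lr_a"]
    new.weights_b = model.weights_b * shared * norms["lr_b"]
    return new


def display_normalize(loadings: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Divide each factor column by its maximum, mapping loadings to [0, 1].

    All-zero columns are left zero with a warning.
    """
    values = np.asarray(loadings, dtype=float)
    if np.any(values < 0):
        raise DomainError("loadings must be non-negative")
    maxima = values.max(axis=0)
    dead = maxima == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} all-zero factor column(s) left unscaled",
            RuntimeWarning,
        )
    scaled = np.divide(values, np.where(dead, 1.0, maxima))
    if isinstance(loadings, pd.DataFrame):
        return pd.DataFrame(scaled, index=loadings.index, columns=loadings.columns)
    return scaled


def joint_cellpair_loadings(
    model: FactorModel,
    sender_labels: list[str] | None = None,
    receiver_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Outer product of sender and receiver loadings per factor.

    Row (sender k, receiver l) of column r is senders[k, r] *
    receivers[l, r]; rows are ordered sender-major and indexed by a
    (sender, receiver) MultiIndex (positional when labels are omitted).
    """
    s, r = model.senders, model.receivers
    joint = np.einsum("kr,lr->klr", s, r).reshape(s.shape[0] * r.shape[0], model.rank)
    index = pd.MultiIndex.from_product(
        [
            sender_labels if sender_labels is not None else range(s.shape[0]),
            receiver_labels if receiver_labels is not None else range(r.shape[0]),
        ],
        names=["sender", "receiver"],
    )
    return pd.DataFrame(
        joint, index=index, columns=[f"factor_{i + 1}" for i in range(model.rank)]
    )


def top_elements(
    loadings: pd.DataFrame, fraction: float = 0.75
) -> dict[str, list[str]]:
    """Labels whose display-normalized loading is >= fraction, per factor.

    Input must already be display-normalized (column maxima of 1 for
    nonzero columns). Labels are sorted by descending loading; an
    element may appear under several factors.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    out: dict[str, list[str]] = {}
    for col in loadings.columns:
        series = loadings[col]
        hits = series[series >= fraction].sort_values(ascending=False)
        out[str(col)] = [str(i) for i in hits.index]
    return out
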