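"""Core containers for coupled 4D communication tensors and factor models.

A communication tensor holds non-negative scores organized as
(context, ligand-receptor pair, sender cell type, receiver cell type).
Two such tensors — e.g. one for protein-mediated and one for
metabolite-mediated signaling — are *coupled* when they share the
context, sender and receiver axes while each keeps its own private
ligand-receptor axis.  A :class:`FactorModel` is the CP-style
decomposition of such a pair into R rank-1 factors with shared
context/sender/receiver loadings and modality-specific LR loadings.

Missing entries are represented by a binary mask (1 = observed,
0 = missing); masked entries of ``values`` are stored as 0 and the mask
is the single source of truth for missingness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import khatri_rao as _kr2


class CouplingError(ValueError):
    """Shared axes of the two tensors do not match."""


class DomainError(ValueError):
    """Values violate the non-negativity domain of the model."""


class ParameterError(ValueError):
    """An invalid parameter combination was supplied."""


def _check_labels(labels: Sequence[str], n: int, axis: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(
            f"{axis} labels have length {len(labels)}, expected {n}"
        )
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate labels on {axis} axis")
    return labels


@dataclass
class CommTensor:
    """One modality's 4D non-negative score tensor with an observation mask.

    Parameters
    ----------
    values
        Array of shape (C, P, S, T): contexts x LR pairs x senders x
        receivers. Observed entries must be non-negative. Entries at
        masked positions are zeroed on construction.
    mask
        Binary array of the same shape; 1 marks an observed entry.
    context_labels, lr_labels, sender_labels, receiver_labels
        Ordered axis labels, unique within each axis.
    modality
        Free-text tag, conventionally ``"protein"`` or ``"metabolite"``.
    """

    values: np.ndarray
    mask: np.ndarray
    context_labels: list[str]
    lr_labels: list[str]
    sender_labels: list[str]
    receiver_labels: list[str]
    modality: str = "protein"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 4:
            raise ValueError(f"values must be 4D, got {values.ndim}D")
        mask = np.asarray(self.mask, dtype=float)
        if mask.shape != values.shape:
            raise ValueError(
                f"mask shape {mask.shape} != values shape {values.shape}"
            )
        if not np.isin(mask, (0.0, 1.0)).all():
            raise ValueError("mask entries must be 0 or 1")
        observed = mask == 1.0
        if np.any(values[observed] < 0):
            raise DomainError("observed tensor entries must be non-negative")
        if not np.isfinite(values[observed]).all():
            raise DomainError("observed tensor entries must be finite")
        c, p, s, t = values.shape
        self.context_labels = _check_labels(self.context_labels, c, "context")
        self.lr_labels = _check_labels(self.lr_labels, p, "lr")
        self.sender_labels = _check_labels(self.sender_labels, s, "sender")
        self.receiver_labels = _check_labels(self.receiver_labels, t, "receiver")
        # mask is authoritative: zero out anything at a masked position
        self.values = np.where(observed, values, 0.0)
        self.mask = observed.astype(float)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape


@dataclass
class CoupledPair:
    """Two communication tensors coupled along context/sender/receiver.

    Construct through :func:`validate_coupled_pair` to get informative
    errors; direct construction also validates.
    """

    tensor_a: CommTensor
    tensor_b: CommTensor

    def __post_init__(self) -> None:
        a, b = self.tensor_a, self.tensor_b
        for axis, la, lb in (
            ("context", a.context_labels, b.context_labels),
            ("sender", a.sender_labels, b.sender_labels),
            ("receiver", a.receiver_labels, b.receiver_labels),
        ):
            if la != lb:
                offender = next(
                    (
                        (i, x, y)
                        for i, (x, y) in enumerate(zip(la, lb))
                        if x != y
                    ),
                    None,
                )
                if offender is None:
                    detail = f"lengths differ ({len(la)} vs {len(lb)})"
                else:
                    i, x, y = offender
                    detail = f"position {i}: {x!r} vs {y!r}"
                raise CouplingError(
                    f"shared {axis} labels differ between tensors ({detail})"
                )


def validate_coupled_pair(tensor_a: CommTensor, tensor_b: CommTensor) -> CoupledPair:
    """Couple two tensors, checking shared-axis label identity.

    The context, sender and receiver label lists must match exactly in
    content *and order*; no silent reordering is performed. The private
    LR axes may differ freely.
    """
    return CoupledPair(tensor_a, tensor_b)


@dataclass
class FactorModel:
    """CP factor model with shared and private loading matrices.

    Columns index the R factors. ``contexts`` (C x R), ``senders``
    (S x R) and ``receivers`` (T x R) are shared between modalities;
    ``lr_a`` (P x R) and ``lr_b`` (P' x R) are private. ``weights_a``
    and ``weights_b`` carry per-factor, per-modality magnitudes after
    normalization; an un-normalized model has all-ones weights.
    """

    rank: int
    contexts: np.ndarray
    lr_a: np.ndarray
    lr_b: np.ndarray
    senders: np.ndarray
    receivers: np.ndarray
    weights_a: np.ndarray = None  # type: ignore[assignment]
    weights_b: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be a positive integer")
        for name in ("contexts", "lr_a", "lr_b", "senders", "receivers"):
            mat = np.asarray(getattr(self, name), dtype=float)
            if mat.ndim != 2 or mat.shape[1] != self.rank:
                raise ValueError(
                    f"{name} must be 2D with {self.rank} columns, got {mat.shape}"
                )
            if np.any(mat < 0):
                raise DomainError(f"{name} loadings must be non-negative")
            setattr(self, name, mat)
        for name in ("weights_a", "weights_b"):
            w = getattr(self, name)
            w = np.ones(self.rank) if w is None else np.asarray(w, dtype=float)
            if w.shape != (self.rank,):
                raise ValueError(f"{name} must have length {self.rank}")
            if np.any(w < 0):
                raise DomainError(f"{name} must be non-negative")
            setattr(self, name, w)

    def factors(self, modality: str) -> list[np.ndarray]:
        """Loading matrices in axis order for one modality."""
        lr = _pick_modality(modality, self.lr_a, self.lr_b)
        return [self.contexts, lr, self.senders, self.receivers]

    def weights(self, modality: str) -> np.ndarray:
        return _pick_modality(modality, self.weights_a, self.weights_b)

    def copy(self) -> "FactorModel":
        return FactorModel(
            rank=self.rank,
            contexts=self.contexts.copy(),
            lr_a=self.lr_a.copy(),
            lr_b=self.lr_b.copy(),
            senders=self.senders.copy(),
            receivers=self.receivers.copy(),
            weights_a=self.weights_a.copy(),
            weights_b=self.weights_b.copy(),
        )

    def permute(self, order: Sequence[int]) -> "FactorModel":
        """Reorder factors; the model is invariant under this."""
        order = list(order)
        return FactorModel(
            rank=self.rank,
            contexts=self.contexts[:, order],
            lr_a=self.lr_a[:, order],
            lr_b=self.lr_b[:, order],
            senders=self.senders[:, order],
            receivers=self.receivers[:, order],
            weights_a=self.weights_a[order],
            weights_b=self.weights_b[order],
        )


def _pick_modality(modality: str, a, b):
    if modality in ("a", "protein"):
        return a
    if modality in ("b", "metabolite"):
        return b
    raise ParameterError(f"unknown modality tag {modality!r} (use 'a' or 'b')")


@dataclass(frozen=True)
class Alphas:
    """Convex balancing weights on the two tensors' error terms.

    The weights must be in [0, 1] and sum to one (the default 0.5/0.5
    weights the modalities equally).
    """

    alpha_a: float = 0.5
    alpha_b: float = 0.5

    def __post_init__(self) -> None:
        a, b = float(self.alpha_a), float(self.alpha_b)
        if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
            raise ParameterError("alphas must lie in [0, 1]")
        if abs(a + b - 1.0) > 1e-12:
            raise ParameterError(
                f"balancing weights must sum to one, got {a} + {b} = {a + b}"
            )
        object.__setattr__(self, "alpha_a", a)
        object.__setattr__(self, "alpha_b", b)

    @classmethod
    def from_alpha_a(cls, alpha_a: float) -> "Alphas":
        return cls(alpha_a, 1.0 - alpha_a)


# ---------------------------------------------------------------------------
# tensor algebra helpers (fixed conventions)
# ---------------------------------------------------------------------------

def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding: remaining modes by increasing index, earliest fastest."""
    return np.reshape(
        np.moveaxis(tensor, mode, 0), (tensor.shape[mode], -1), order="F"
    )


def khatri_rao(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Column-wise Kronecker product over matrices in increasing mode order.

    The product is accumulated in reverse index order so that the first
    matrix's row index varies fastest — the convention matching
    :func:`unfold`.
    """
    mats = list(matrices)
    out = mats[-1]
    for mat in reversed(mats[:-1]):
        out = _kr2(out, mat)
    return out


def reconstruct(model: FactorModel, modality: str) -> np.ndarray:
    """Evaluate the CP model as a dense 4D tensor for one modality.

    Entry (i, j, k, l) is the weighted sum over factors of
    ``contexts[i,r] * lr[j,r] * senders[k,r] * receivers[l,r]``.
    """
    ctx, lr, snd, rcv = model.factors(modality)
    w = model.weights(modality)
    return np.einsum("ir,jr,kr,lr,r->ijkl", ctx, lr, snd, rcv, w, optimize=True)


def coupled_objective(
    model: FactorModel, pair: CoupledPair, alphas: Alphas = Alphas()
) -> float:
    """Masked, alpha-weighted squared Frobenius error of a coupled fit.

    Returns ``alpha_a * ||M * (X_a - Xhat_a)||_F^2
    + alpha_b * ||M' * (X_b - Xhat_b)||_F^2`` where masked entries
    contribute exactly zero.
    """
    total = 0.0
    for alpha, tensor, modality in (
        (alphas.alpha_a, pair.tensor_a, "a"),
        (alphas.alpha_b, pair.tensor_b, "b"),
    ):
        resid = tensor.mask * (tensor.values - reconstruct(model, modality))
        total += alpha * float(np.sum(resid * resid))
    return total


def relative_error(model: FactorModel, pair: CoupledPair) -> tuple[float, float]:
    """Per-modality normalized fit diagnostic ||M*(X-Xhat)||_F / ||M*X||_F."""
    out = []
    for tensor, modality in ((pair.tensor_a, "a"), (pair.tensor_b, "b")):
        denom = float(np.linalg.norm(tensor.mask * tensor.values))
        if denom == 0.0:
            raise DomainError(
                f"relative error undefined: observed entries of modality "
                f"{modality!r} are all zero"
            )
        resid = tensor.mask * (tensor.values - reconstruct(model, modality))
        out.append(float(np.linalg.norm(resid)) / denom)
    return out[0], out[1]
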