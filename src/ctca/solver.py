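"""Masked non-negative coupled alternating least squares.

Fits a :class:`~ctca.tensors.FactorModel` to a coupled tensor pair by
minimizing the alpha-weighted masked squared Frobenius objective.
Shared modes (contexts, senders, receivers) are updated against both
tensors simultaneously; each private LR mode is updated against its own
tensor only. Non-negativity is enforced by column-wise HALS updates
floored at a small epsilon, and missing entries are handled by EM-style
imputation: at the start of every sweep the masked entries of each
working copy are filled with the current model estimate, so the masked
objective on the original data is non-increasing across sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .tensors import (
    Alphas,
    CoupledPair,
    FactorModel,
    ParameterError,
    coupled_objective,
    khatri_rao,
    reconstruct,
    relative_error,
    unfold,
)

# axis index of each mode in the (context, LR, sender, receiver) layout
_MODE_AXIS = {"context": 0, "lr": 1, "sender": 2, "receiver": 3}
_SHARED_MODES = ("context", "sender", "receiver")


class NumericalFailure(RuntimeError):
    """The objective became non-finite during fitting."""

    def __init__(self, sweep: int):
        self.sweep = sweep
        super().__init__(f"non-finite objective at sweep {sweep}")


class DegenerateFactorWarning(RuntimeWarning):
    """A factor column had a zero HALS denominator and was left unchanged."""


@dataclass(frozen=True)
class FitConfig:
    """Convergence and initialization controls for the coupled fit.

    tol is the relative objective change below which iteration stops;
    epsilon is the non-negativity floor applied after every column
    update. With n_restarts > 1, seeds seed, seed+1, ... are run and
    the lowest-objective fit is returned.
    """

    rank: int
    alphas: Alphas = Alphas()
    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 0
    init: str = "random"
    n_restarts: int = 1
    epsilon: float = 1e-16

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ParameterError("rank must be >= 1")
        if self.tol <= 0:
            raise ParameterError("tol must be positive")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be positive")
        if self.init not in ("random", "svd"):
            raise ParameterError(
                f"unknown init {self.init!r} (use 'random' or 'svd')"
            )
        if self.n_restarts < 1:
            raise ParameterError("n_restarts must be >= 1")


@dataclass
class FitResult:
    """A fitted model plus its optimization trajectory and diagnostics."""

    model: FactorModel
    objective_trajectory: list[float]
    converged: bool
    n_iter: int
    relative_errors: tuple[float, float]
    seed_used: int
    config: FitConfig


def initialize(pair: CoupledPair, config: FitConfig) -> FactorModel:
    """Build a deterministic non-negative starting model.

    ``"random"`` draws every loading entry i.i.d. from |N(0, 1)| with a
    generator seeded by ``config.seed``. ``"svd"`` takes the leading
    left singular vectors of each mode's unfolding of tensor_a (the
    private-b matrix comes from tensor_b), clips negative parts to
    epsilon, and fills any columns beyond the available singular vectors
    with |N(0, 1)| draws. CP rank may exceed every mode length; that is
    not an error.
    """
    rng = np.random.default_rng(config.seed)
    rank = config.rank
    shapes = {
        "contexts": pair.tensor_a.shape[0],
        "lr_a": pair.tensor_a.shape[1],
        "lr_b": pair.tensor_b.shape[1],
        "senders": pair.tensor_a.shape[2],
        "receivers": pair.tensor_a.shape[3],
    }
    if config.init == "random":
        mats = {
            name: np.abs(rng.standard_normal((n, rank)))
            for name, n in shapes.items()
        }
    else:
        sources = {
            "contexts": (pair.tensor_a.values, 0),
            "lr_a": (pair.tensor_a.values, 1),
            "lr_b": (pair.tensor_b.values, 1),
            "senders": (pair.tensor_a.values, 2),
            "receivers": (pair.tensor_a.values, 3),
        }
        mats = {}
        for name, (tensor, axis) in sources.items():
            u, _, _ = np.linalg.svd(unfold(tensor, axis), full_matrices=False)
            k = min(rank, u.shape[1])
            lead = u[:, :k].copy()
            # resolve sign ambiguity toward the non-negative orthant
            flip = lead.sum(axis=0) < 0
            lead[:, flip] *= -1.0
            mat = np.empty((shapes[name], rank))
            mat[:, :k] = np.maximum(lead, config.epsilon)
            if k < rank:
                mat[:, k:] = np.abs(
                    rng.standard_normal((shapes[name], rank - k))
                )
            mats[name] = mat
    for mat in mats.values():
        np.maximum(mat, config.epsilon, out=mat)
    return FactorModel(rank=rank, **mats)


def impute_working_copy(
    pair: CoupledPair, model: FactorModel
) -> tuple[np.ndarray, np.ndarray]:
    """EM-style working copies: observed entries kept, missing imputed.

    Returns ``M*X + (1-M)*Xhat`` for each modality, where Xhat is the
    current model reconstruction.
    """
    out = []
    for tensor, modality in ((pair.tensor_a, "a"), (pair.tensor_b, "b")):
        hat = reconstruct(model, modality)
        out.append(tensor.mask * tensor.values + (1.0 - tensor.mask) * hat)
    return out[0], out[1]


def _hals_columns(
    factor: np.ndarray,
    numer_terms: list[tuple[float, np.ndarray, np.ndarray]],
    epsilon: float,
    mode_name: str,
) -> np.ndarray:
    """Column-wise HALS on ``factor`` given weighted (B, G) statistics.

    Each term contributes ``alpha * (B[:, r] - A @ G[:, r])`` to the
    numerator and ``alpha * G[r, r]`` to the denominator, where
    ``B = X_(n) @ K`` and ``G = K.T @ K`` for that modality's
    Khatri-Rao product K of remaining-mode factors.
    """
    a = factor.copy()
    rank = a.shape[1]
    for r in range(rank):
        denom = sum(alpha * g[r, r] for alpha, _, g in numer_terms)
        if denom <= 0.0:
            warnings.warn(
                f"zero HALS denominator for factor {r} on mode {mode_name}; "
                "column left unchanged",
                DegenerateFactorWarning,
                stacklevel=3,
            )
            continue
        step = np.zeros(a.shape[0])
        for alpha, b, g in numer_terms:
            if alpha == 0.0:
                continue
            step += alpha * (b[:, r] - a @ g[:, r])
        a[:, r] = np.maximum(epsilon, a[:, r] + step / denom)
    return a


def _kr_stats(
    working: np.ndarray, factors: list[np.ndarray], axis: int
) -> tuple[np.ndarray, np.ndarray]:
    others = [factors[m] for m in range(4) if m != axis]
    k = khatri_rao(others)
    b = unfold(working, axis) @ k
    g = k.T @ k
    return b, g


def update_shared_mode(
    model: FactorModel,
    working_a: np.ndarray,
    working_b: np.ndarray,
    mode: str,
    alphas: Alphas = Alphas(),
    epsilon: float = 1e-16,
) -> FactorModel:
    """HALS update of one shared factor matrix against both tensors."""
    if mode not in _SHARED_MODES:
        raise ParameterError(f"not a shared mode: {mode!r}")
    axis = _MODE_AXIS[mode]
    new = model.copy()
    terms = []
    for alpha, working, modality in (
        (alphas.alpha_a, working_a, "a"),
        (alphas.alpha_b, working_b, "b"),
    ):
        b, g = _kr_stats(working, new.factors(modality), axis)
        terms.append((alpha, b, g))
    attr = {"context": "contexts", "sender": "senders", "receiver": "receivers"}[mode]
    setattr(new, attr, _hals_columns(getattr(new, attr), terms, epsilon, mode))
    return new


def update_private_mode(
    model: FactorModel,
    working_x: np.ndarray,
    modality: str,
    epsilon: float = 1e-16,
) -> FactorModel:
    """HALS update of one modality's private LR matrix; the other is untouched."""
    new = model.copy()
    b, g = _kr_stats(working_x, new.factors(modality), 1)
    updated = _hals_columns(
        new.lr_a if modality in ("a", "protein") else new.lr_b,
        [(1.0, b, g)],
        epsilon,
        f"lr_{modality}",
    )
    if modality in ("a", "protein"):
        new.lr_a = updated
    else:
        new.lr_b = updated
    return new


def _fit_single(pair: CoupledPair, config: FitConfig, seed: int) -> FitResult:
    cfg = replace(config, seed=seed, n_restarts=1)
    model = initialize(pair, cfg)
    alphas = cfg.alphas
    trajectory = [coupled_objective(model, pair, alphas)]
    converged = False
    n_iter = 0
    for sweep in range(1, cfg.max_iter + 1):
        working_a, working_b = impute_working_copy(pair, model)
        model = update_shared_mode(
            model, working_a, working_b, "context", alphas, cfg.epsilon
        )
        model = update_private_mode(model, working_a, "a", cfg.epsilon)
        model = update_private_mode(model, working_b, "b", cfg.epsilon)
        model = update_shared_mode(
            model, working_a, working_b, "sender", alphas, cfg.epsilon
        )
        model = update_shared_mode(
            model, working_a, working_b, "receiver", alphas, cfg.epsilon
        )
        obj = coupled_objective(model, pair, alphas)
        if not np.isfinite(obj):
            raise NumericalFailure(sweep)
        prev = trajectory[-1]
        trajectory.append(obj)
        n_iter = sweep
        if abs(obj - prev) / max(prev, 1e-30) < cfg.tol:
            converged = True
            break
    return FitResult(
        model=model,
        objective_trajectory=trajectory,
        converged=converged,
        n_iter=n_iter,
        relative_errors=relative_error(model, pair),
        seed_used=seed,
        config=config,
    )


def fit_ctca(pair: CoupledPair, config: FitConfig) -> FitResult:
    """Fit the coupled model, optionally with multiple random restarts.

    Each sweep imputes the working copies, then updates contexts, lr_a,
    lr_b, senders and receivers in that fixed order; the objective is
    recorded on the original masked data after every sweep. With
    restarts, seeds ``seed, seed+1, ...`` are run and the result with
    the lowest final objective wins (ties go to the lower seed). The
    returned model is un-normalized (all-ones weights).
    """
    best: FitResult | None = None
    for s in range(config.n_restarts):
        result = _fit_single(pair, config, config.seed + s)
        if best is None or result.objective_trajectory[-1] < best.objective_trajectory[-1]:
            best = result
    assert best is not None
    return best
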