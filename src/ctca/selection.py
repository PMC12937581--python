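"""Rank selection and robustness diagnostics for the coupled fit.

The number of factors is chosen from a reconstruction-error curve over
candidate ranks (elbow criterion: the interior rank farthest from the
chord joining the curve's endpoints, after min-max normalizing both
axes so the choice is invariant to affine rescaling of the error).
Robustness across restarts is quantified with a permutation-matched
factor match score: the product over the five loading matrices of the
cosine between matched columns, averaged over the optimal factor
assignment. A score of 1 means two models agree up to factor
permutation and per-factor scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .solver import FitConfig, FitResult, fit_ctca
from .tensors import Alphas, CoupledPair, FactorModel

_MODES = ("contexts", "lr_a", "lr_b", "senders", "receivers")


class InsufficientCurveError(ValueError):
    """Too few points to locate an elbow."""


class FlatCurveWarning(RuntimeWarning):
    """The error curve is (numerically) linear; the elbow is arbitrary."""


@dataclass
class ErrorCurve:
    """Best combined normalized reconstruction error per candidate rank.

    The combined error is the alphas-weighted sum of squared masked
    residuals over the alphas-weighted sum of squared masked data,
    square-rooted — the same currency the solver optimizes.
    """

    ranks: list[int]
    errors: list[float]
    per_rank_runs: dict[int, list[tuple[int, float]]]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.ranks, self.ranks[1:])):
            raise ValueError("ranks must be strictly increasing")
        if any(e < 0 for e in self.errors):
            raise ValueError("errors must be non-negative")


@dataclass
class StabilityReport:
    """Pairwise factor-match scores across independent restarts."""

    rank: int
    n_runs: int
    pairwise_fms: np.ndarray
    median_fms: float


def combined_normalized_error(
    result: FitResult, pair: CoupledPair, alphas: Alphas
) -> float:
    """sqrt of (alpha-weighted masked SSR) / (alpha-weighted masked SS)."""
    denom = 0.0
    for alpha, tensor in (
        (alphas.alpha_a, pair.tensor_a),
        (alphas.alpha_b, pair.tensor_b),
    ):
        denom += alpha * float(np.sum((tensor.mask * tensor.values) ** 2))
    return float(np.sqrt(result.objective_trajectory[-1] / denom))


def rank_scan(
    pair: CoupledPair,
    ranks: list[int],
    restarts_per_rank: int = 3,
    base_config: FitConfig | None = None,
) -> ErrorCurve:
    """Fit every candidate rank with restarts; keep the best error per rank."""
    if not ranks:
        raise ValueError("ranks must be non-empty")
    if base_config is None:
        base_config = FitConfig(rank=ranks[0])
    curve_errors: list[float] = []
    per_rank_runs: dict[int, list[tuple[int, float]]] = {}
    for rank in sorted(ranks):
        runs = []
        for i in range(restarts_per_rank):
            seed = base_config.seed + i
            cfg = replace(base_config, rank=rank, seed=seed, n_restarts=1)
            try:
                result = fit_ctca(pair, cfg)
            except Exception as exc:
                raise RuntimeError(f"fit failed at rank {rank} (seed {seed})") from exc
            runs.append(
                (seed, combined_normalized_error(result, pair, cfg.alphas))
            )
        per_rank_runs[rank] = runs
        curve_errors.append(min(err for _, err in runs))
    return ErrorCurve(
        ranks=sorted(ranks), errors=curve_errors, per_rank_runs=per_rank_runs
    )


def elbow_rank(curve: ErrorCurve) -> int:
    """Interior rank farthest from the first-to-last chord of the curve.

    Both axes are min-max normalized first, so the result does not
    depend on the units or affine scaling of the error axis. Ties go to
    the smallest rank; an exactly linear curve triggers a flat-curve
    warning and returns the smallest interior rank.
    """
    if len(curve.ranks) < 3:
        raise InsufficientCurveError("elbow selection needs >= 3 ranks")
    x = np.asarray(curve.ranks, dtype=float)
    y = np.asarray(curve.errors, dtype=float)
    x = (x - x[0]) / (x[-1] - x[0])
    span = y.max() - y.min()
    y = (y - y.min()) / span if span != 0 else np.zeros_like(y)
    # chord runs from (0, y[0]) to (1, y[-1]) in normalized coordinates
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    pts = np.stack([x, y], axis=1) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0])
    interior = dist[1:-1]
    if np.max(interior) < 1e-12:
        warnings.warn(
            "error curve is flat/linear; elbow is arbitrary", FlatCurveWarning
        )
    return curve.ranks[1 + int(np.argmax(interior))]


def _unit_columns(mat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=0)
    out = np.zeros_like(mat, dtype=float)
    nz = norms > 0
    out[:, nz] = mat[:, nz] / norms[nz]
    return out


def _congruence_matrix(model_x: FactorModel, model_y: FactorModel) -> np.ndarray:
    cong = np.ones((model_x.rank, model_y.rank))
    for name in _MODES:
        a = _unit_columns(getattr(model_x, name))
        b = _unit_columns(getattr(model_y, name))
        cong *= a.T @ b
    return cong


def factor_match_score(model_x: FactorModel, model_y: FactorModel) -> float:
    """Permutation-optimal mean congruence between two factor models.

    Per factor pair, the congruence is the product over the five loading
    matrices of the cosine between unit-normalized columns; the optimal
    factor assignment maximizes the mean congruence. Insensitive to
    factor order and per-factor positive rescaling.
    """
    if model_x.rank != model_y.rank:
        raise ValueError(
            f"rank mismatch: {model_x.rank} vs {model_y.rank}"
        )
    for name in _MODES:
        if getattr(model_x, name).shape[0] != getattr(model_y, name).shape[0]:
            raise ValueError(f"axis length mismatch on {name}")
    cong = _congruence_matrix(model_x, model_y)
    row, col = linear_sum_assignment(-cong)
    return float(np.clip(cong[row, col].mean(), 0.0, 1.0))


def matched_cosines(model_x: FactorModel, model_y: FactorModel) -> dict[str, np.ndarray]:
    """Per-mode cosines between optimally matched factor columns."""
    cong = _congruence_matrix(model_x, model_y)
    row, col = linear_sum_assignment(-cong)
    out = {}
    for name in _MODES:
        a = _unit_columns(getattr(model_x, name))
        b = _unit_columns(getattr(model_y, name))
        out[name] = np.einsum("ir,ir->r", a[:, row], b[:, col])
    return out


def stability_analysis(
    pair: CoupledPair,
    rank: int,
    n_runs: int,
    base_config: FitConfig | None = None,
) -> StabilityReport:
    """Fit n_runs times from consecutive seeds; report pairwise FMS."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if base_config is None:
        base_config = FitConfig(rank=rank)
    results = []
    for i in range(n_runs):
        cfg = replace(
            base_config, rank=rank, seed=base_config.seed + i, n_restarts=1
        )
        results.append(fit_ctca(pair, cfg))
    fms = np.eye(n_runs)
    for i in range(n_runs):
        for j in range(i + 1, n_runs):
            fms[i, j] = fms[j, i] = factor_match_score(
                results[i].model, results[j].model
            )
    upper = fms[np.triu_indices(n_runs, k=1)]
    return StabilityReport(
        rank=rank,
        n_runs=n_runs,
        pairwise_fms=fms,
        median_fms=float(np.median(upper)),
    )
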