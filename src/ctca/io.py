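"""Readers and writers for expression matrices, interaction tables,
tensor containers and fit results.

Formats
-------
- Expression: MatrixMarket triplets (``.mtx`` + features/barcodes TSV)
  or a dense delimited gene x cell table (header row = cell ids, first
  column = gene symbols).
- Interaction tables: CSV with ``interaction_id,ligand,receptor``
  (subunits joined with ``&`` by default) and
  ``interaction_id,metabolite,producing_genes,consuming_genes,sensor``
  (gene lists joined with ``;``).
- Pre-scored communication: long-format CSV with columns
  ``context,lr,sender,receiver,score``.
- Tensor pairs: an HDF5 container with dense value/mask arrays and
  label lists per modality.
- Fit results: five loadings CSV tables plus a JSON metadata record.

Every writer's output is re-readable by the matching reader with
bit-identical content.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .build import (
    MetaboliteRow,
    MetaboliteTable,
    ProteinLR,
    ProteinLRTable,
    SchemaError,
)
from .selection import ErrorCurve, StabilityReport
from .solver import FitResult
from .tensors import (
    CommTensor,
    CoupledPair,
    DomainError,
    FactorModel,
    validate_coupled_pair,
)


class ParseError(ValueError):
    """A file could not be parsed under its declared format."""


# ---------------------------------------------------------------------------
# expression input
# ---------------------------------------------------------------------------

def read_expression(
    path: str | os.PathLike,
    format: str = "dense",
    features: str | os.PathLike | None = None,
    barcodes: str | os.PathLike | None = None,
    sep: str = ",",
) -> tuple[np.ndarray, list[str], list[str]]:
    """Load a gene x cell expression matrix with labels.

    ``format="mtx"`` reads MatrixMarket triplets (1-based indices) with
    accompanying features/barcodes TSV tables; ``format="dense"`` reads
    a delimited table whose header row holds cell ids and whose first
    column holds gene symbols. Values must be non-negative.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(f"empty expression file: {path}")
    if format == "mtx":
        if features is None or barcodes is None:
            raise ParseError("mtx format requires features and barcodes paths")
        try:
            matrix = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(
                f"invalid MatrixMarket file {path} (indices are 1-based): {exc}"
            ) from exc
        matrix = np.asarray(
            matrix.todense() if scipy.sparse.issparse(matrix) else matrix,
            dtype=float,
        )
        genes = pd.read_csv(features, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
        if matrix.shape != (len(genes), len(cells)):
            raise ParseError(
                f"matrix shape {matrix.shape} does not match "
                f"{len(genes)} features x {len(cells)} barcodes"
            )
    elif format == "dense":
        try:
            frame = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise ParseError(f"cannot parse dense expression table {path}: {exc}") from exc
        if frame.empty and frame.columns.empty:
            raise ParseError(f"empty expression table: {path}")
        genes = [str(g) for g in frame.index]
        cells = [str(c) for c in frame.columns]
        matrix = frame.to_numpy(dtype=float)
    else:
        raise ParseError(f"unknown expression format {format!r}")
    if np.any(matrix < 0):
        gi, ci = np.argwhere(matrix < 0)[0]
        raise DomainError(
            f"negative expression for gene {genes[gi]!r}, cell {cells[ci]!r}"
        )
    return matrix, genes, cells


def read_metadata(path: str | os.PathLike, sep: str = "\t") -> pd.DataFrame:
    """Cell metadata table with cell_id, cell_type and context columns."""
    meta = pd.read_csv(path, sep=sep, dtype=str)
    required = {"cell_id", "cell_type", "context"}
    if not required.issubset(meta.columns):
        raise SchemaError(f"metadata must have columns {sorted(required)}")
    return meta


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------

def _split(text, sep: str) -> tuple[str, ...]:
    if text is None or (isinstance(text, float) and np.isnan(text)) or str(text) == "":
        return ()
    return tuple(part.strip() for part in str(text).split(sep) if part.strip())


def read_interaction_tables(
    lr_path: str | os.PathLike,
    met_path: str | os.PathLike,
    subunit_sep: str = "&",
    list_sep: str = ";",
) -> tuple[ProteinLRTable, MetaboliteTable]:
    """Parse the protein LR and metabolite-sensor CSV tables."""
    lr_frame = pd.read_csv(lr_path, dtype=str)
    for col in ("interaction_id", "ligand", "receptor"):
        if col not in lr_frame.columns:
            raise SchemaError(f"protein LR table lacks column {col!r}")
    lr_rows = [
        ProteinLR(
            interaction_id=str(row.interaction_id),
            ligand_subunits=_split(row.ligand, subunit_sep),
            receptor_subunits=_split(row.receptor, subunit_sep),
        )
        for row in lr_frame.itertuples()
    ]
    met_frame = pd.read_csv(met_path, dtype=str)
    for col in ("interaction_id", "metabolite", "producing_genes", "consuming_genes", "sensor"):
        if col not in met_frame.columns:
            raise SchemaError(f"metabolite table lacks column {col!r}")
    met_rows = [
        MetaboliteRow(
            interaction_id=str(row.interaction_id),
            metabolite=str(row.metabolite),
            producing_genes=_split(row.producing_genes, list_sep),
            consuming_genes=_split(row.consuming_genes, list_sep),
            sensor_subunits=_split(row.sensor, subunit_sep),
        )
        for row in met_frame.itertuples()
    ]
    return ProteinLRTable(lr_rows), MetaboliteTable(met_rows)


# ---------------------------------------------------------------------------
# long-format pre-scored communication
# ---------------------------------------------------------------------------

def read_scores_long(
    path: str | os.PathLike,
    modality: str = "protein",
    missing_policy: str = "mask",
) -> CommTensor:
    """Build a CommTensor from long-format (context, lr, sender, receiver, score).

    Axis orders follow first appearance in the file. Combinations
    absent from the file are masked (``missing_policy="mask"``) or
    stored as observed zeros (``"zero"``).
    """
    frame = pd.read_csv(path, dtype={"score": float})
    required = ["context", "lr", "sender", "receiver", "score"]
    if list(frame.columns[:5]) != required and not set(required).issubset(frame.columns):
        raise SchemaError(f"long-format scores need columns {required}")
    axes = {}
    for col in ("context", "lr", "sender", "receiver"):
        axes[col] = list(dict.fromkeys(frame[col].astype(str)))
    index = {
        col: {lab: i for i, lab in enumerate(labs)} for col, labs in axes.items()
    }
    shape = tuple(len(axes[c]) for c in ("context", "lr", "sender", "receiver"))
    values = np.zeros(shape)
    observed = np.zeros(shape, dtype=bool)
    for row in frame.itertuples():
        pos = (
            index["context"][str(row.context)],
            index["lr"][str(row.lr)],
            index["sender"][str(row.sender)],
            index["receiver"][str(row.receiver)],
        )
        values[pos] = row.score
        observed[pos] = True
    mask = observed.astype(float) if missing_policy == "mask" else np.ones(shape)
    return CommTensor(
        values=values,
        mask=mask,
        context_labels=axes["context"],
        lr_labels=axes["lr"],
        sender_labels=axes["sender"],
        receiver_labels=axes["receiver"],
        modality=modality,
    )


# ---------------------------------------------------------------------------
# tensor pair container (HDF5)
# ---------------------------------------------------------------------------

_LABEL_KEYS = ("context_labels", "lr_labels", "sender_labels", "receiver_labels")


def _write_tensor(group: h5py.Group, tensor: CommTensor) -> None:
    group.create_dataset("values", data=tensor.values)
    group.create_dataset("mask", data=tensor.mask)
    str_dtype = h5py.string_dtype(encoding="utf-8")
    for key in _LABEL_KEYS:
        group.create_dataset(key, data=np.array(getattr(tensor, key), dtype=str_dtype))
    group.attrs["modality"] = tensor.modality


def _read_tensor(group: h5py.Group) -> CommTensor:
    labels = {
        key: [x.decode() if isinstance(x, bytes) else str(x) for x in group[key][()]]
        for key in _LABEL_KEYS
    }
    return CommTensor(
        values=group["values"][()],
        mask=group["mask"][()],
        modality=str(group.attrs["modality"]),
        **labels,
    )


def save_pair(pair: CoupledPair, path: str | os.PathLike) -> None:
    """Write a coupled pair to an HDF5 container."""
    with h5py.File(path, "w") as handle:
        _write_tensor(handle.create_group("tensor_a"), pair.tensor_a)
        _write_tensor(handle.create_group("tensor_b"), pair.tensor_b)


def load_pair(path: str | os.PathLike) -> CoupledPair:
    """Read a coupled pair back from :func:`save_pair` output."""
    with h5py.File(path, "r") as handle:
        tensor_a = _read_tensor(handle["tensor_a"])
        tensor_b = _read_tensor(handle["tensor_b"])
    return validate_coupled_pair(tensor_a, tensor_b)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

_LOADING_FILES = {
    "contexts": "context_loadings.csv",
    "lr_a": "lr_protein_loadings.csv",
    "lr_b": "lr_metabolite_loadings.csv",
    "senders": "sender_loadings.csv",
    "receivers": "receiver_loadings.csv",
}


def _loading_frames(result: FitResult, pair: CoupledPair) -> dict[str, pd.DataFrame]:
    model = result.model
    labels = {
        "contexts": pair.tensor_a.context_labels,
        "lr_a": pair.tensor_a.lr_labels,
        "lr_b": pair.tensor_b.lr_labels,
        "senders": pair.tensor_a.sender_labels,
        "receivers": pair.tensor_a.receiver_labels,
    }
    cols = [f"factor_{i + 1}" for i in range(model.rank)]
    return {
        name: pd.DataFrame(getattr(model, name), index=labels[name], columns=cols)
        for name in _LOADING_FILES
    }


def write_fit_result(
    result: FitResult, pair: CoupledPair, outdir: str | os.PathLike
) -> None:
    """Serialize a fit as five loadings CSVs plus JSON metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in _loading_frames(result, pair).items():
        frame.to_csv(outdir / _LOADING_FILES[name], index_label="label")
    cfg = result.config
    metadata = {
        "rank": result.model.rank,
        "alphas": [cfg.alphas.alpha_a, cfg.alphas.alpha_b],
        "tol": cfg.tol,
        "max_iter": cfg.max_iter,
        "seed": cfg.seed,
        "init": cfg.init,
        "n_restarts": cfg.n_restarts,
        "epsilon": cfg.epsilon,
        "seed_used": result.seed_used,
        "converged": result.converged,
        "n_iter": result.n_iter,
        "relative_errors": list(result.relative_errors),
        "objective_trajectory": result.objective_trajectory,
        "weights_a": result.model.weights_a.tolist(),
        "weights_b": result.model.weights_b.tolist(),
    }
    with open(outdir / "fit_metadata.json", "w") as handle:
        json.dump(metadata, handle, indent=2)


def read_fit_result(outdir: str | os.PathLike) -> tuple[FactorModel, dict]:
    """Load the factor model and metadata written by :func:`write_fit_result`."""
    outdir = Path(outdir)
    with open(outdir / "fit_metadata.json") as handle:
        metadata = json.load(handle)
    mats = {
        name: pd.read_csv(outdir / fname, index_col=0, float_precision="round_trip").to_numpy(dtype=float)
        for name, fname in _LOADING_FILES.items()
    }
    model = FactorModel(
        rank=metadata["rank"],
        weights_a=np.array(metadata["weights_a"]),
        weights_b=np.array(metadata["weights_b"]),
        **mats,
    )
    return model, metadata


def read_fit_labels(outdir: str | os.PathLike) -> dict[str, list[str]]:
    """Axis labels of a serialized fit, keyed by loading-matrix name."""
    outdir = Path(outdir)
    return {
        name: pd.read_csv(outdir / fname, index_col=0).index.astype(str).tolist()
        for name, fname in _LOADING_FILES.items()
    }


# ---------------------------------------------------------------------------
# model-selection outputs
# ---------------------------------------------------------------------------

def write_error_curve(curve: ErrorCurve, outdir: str | os.PathLike) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"rank": curve.ranks, "error": curve.errors}).to_csv(
        outdir / "error_curve.csv", index=False
    )
    runs = {
        str(rank): [[seed, err] for seed, err in pairs]
        for rank, pairs in curve.per_rank_runs.items()
    }
    with open(outdir / "error_curve.json", "w") as handle:
        json.dump({"ranks": curve.ranks, "errors": curve.errors, "runs": runs}, handle, indent=2)


def read_error_curve(outdir: str | os.PathLike) -> ErrorCurve:
    with open(Path(outdir) / "error_curve.json") as handle:
        blob = json.load(handle)
    return ErrorCurve(
        ranks=list(blob["ranks"]),
        errors=list(blob["errors"]),
        per_rank_runs={
            int(rank): [(int(s), float(e)) for s, e in pairs]
            for rank, pairs in blob["runs"].items()
        },
    )


def write_stability_report(report: StabilityReport, outdir: str | os.PathLike) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(report.pairwise_fms).to_csv(outdir / "pairwise_fms.csv", index=False)
    with open(outdir / "stability.json", "w") as handle:
        json.dump(
            {
                "rank": report.rank,
                "n_runs": report.n_runs,
                "median_fms": report.median_fms,
                "pairwise_fms": report.pairwise_fms.tolist(),
            },
            handle,
            indent=2,
        )
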