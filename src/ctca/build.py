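"""Construction of coupled communication tensors from expression data.

Per-context gene x cell expression (log1p-normalized) is aggregated to
mean expression per cell type, then scored against a protein
ligand-receptor table and a metabolite producer/consumer/sensor table
for every (context, interaction, sender, receiver) combination. Scores
fill two 4D tensors sharing the context and cell-type axes.

The scorers shipped here are simplified reference implementations
behind a pluggable surface: the protein score is the mean or product of
ligand and receptor expression (complexes reduced by the limiting
minimum subunit), and the metabolite score is a produce-minus-consume
enzyme surrogate for metabolite presence in the sender times sensor
expression in the receiver. Scores from any external inference tool can
be injected instead via long-format CSV (see :mod:`ctca.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tensors import CommTensor, CoupledPair, validate_coupled_pair

#: sentinel for "cannot be scored" (a gene is absent etc.); distinct from 0
MISSING = None


class SchemaError(ValueError):
    """An interaction table row violates the schema."""


class EmptyContextError(ValueError):
    """No cells exist for the requested context."""


@dataclass
class ExpressionProfile:
    """Mean normalized expression per gene and cell type for one context."""

    matrix: np.ndarray
    gene_labels: list[str]
    celltype_labels: list[str]
    context_label: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.any(self.matrix < 0):
            raise ValueError("expression must be non-negative (log1p-normalized)")
        if len(set(self.gene_labels)) != len(self.gene_labels):
            raise ValueError("duplicate gene labels")
        if len(set(self.celltype_labels)) != len(self.celltype_labels):
            raise ValueError("duplicate cell-type labels")
        self._gene_index = {g: i for i, g in enumerate(self.gene_labels)}
        self._celltype_index = {c: i for i, c in enumerate(self.celltype_labels)}

    def expression(self, gene: str, celltype: str) -> float | None:
        gi = self._gene_index.get(gene)
        if gi is None:
            return MISSING
        return float(self.matrix[gi, self._celltype_index[celltype]])


@dataclass(frozen=True)
class ProteinLR:
    interaction_id: str
    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ligand_subunits or not self.receptor_subunits:
            raise SchemaError(
                f"interaction {self.interaction_id!r} needs >=1 subunit per side"
            )


@dataclass(frozen=True)
class MetaboliteRow:
    interaction_id: str
    metabolite: str
    producing_genes: tuple[str, ...]
    consuming_genes: tuple[str, ...]
    sensor_subunits: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.producing_genes:
            raise SchemaError(
                f"interaction {self.interaction_id!r} needs >=1 producing gene"
            )
        if not self.sensor_subunits:
            raise SchemaError(
                f"interaction {self.interaction_id!r} needs >=1 sensor subunit"
            )


def _unique_ids(rows, kind: str) -> None:
    ids = [r.interaction_id for r in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"duplicate {kind} interaction_id(s): {dupes}")


@dataclass
class ProteinLRTable:
    rows: list[ProteinLR]

    def __post_init__(self) -> None:
        _unique_ids(self.rows, "protein LR")


@dataclass
class MetaboliteTable:
    rows: list[MetaboliteRow]

    def __post_init__(self) -> None:
        _unique_ids(self.rows, "metabolite")


@dataclass(frozen=True)
class BuildOptions:
    """Tensor-construction knobs.

    missing_policy "mask" records unscorable entries in the mask tensor;
    "zero" stores them as observed zeros. protein_method selects the
    ligand/receptor combination rule.
    """

    missing_policy: str = "mask"
    protein_method: str = "mean"

    def __post_init__(self) -> None:
        if self.missing_policy not in ("mask", "zero"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        if self.protein_method not in ("mean", "product"):
            raise ValueError(f"unknown protein_method {self.protein_method!r}")


def aggregate_by_celltype(
    expr: np.ndarray,
    gene_labels: list[str],
    metadata: pd.DataFrame,
    context: str,
    cell_labels: list[str] | None = None,
) -> ExpressionProfile:
    """Mean expression per gene and cell type over one context's cells.

    metadata must carry cell_id, cell_type and context columns; cells
    are matched to expression columns by cell_id (by position when
    cell_labels is omitted). Cell types with no cells in the context
    are dropped from the profile.
    """
    required = {"cell_id", "cell_type", "context"}
    if not required.issubset(metadata.columns):
        raise SchemaError(f"metadata needs columns {sorted(required)}")
    sub = metadata[metadata["context"].astype(str) == str(context)]
    if sub.empty:
        raise EmptyContextError(f"no cells annotated for context {context!r}")
    expr = np.asarray(expr, dtype=float)
    if cell_labels is None:
        cell_labels = metadata["cell_id"].astype(str).tolist()
    if len(cell_labels) != expr.shape[1]:
        raise SchemaError(
            f"{len(cell_labels)} cell labels for {expr.shape[1]} expression columns"
        )
    positions = {str(c): i for i, c in enumerate(cell_labels)}
    missing = set(sub["cell_id"].astype(str)) - positions.keys()
    if missing:
        raise SchemaError(f"cells without expression columns: {sorted(missing)[:5]}")
    celltypes = list(dict.fromkeys(sub["cell_type"].astype(str)))
    cols = np.empty((expr.shape[0], len(celltypes)))
    for j, ct in enumerate(celltypes):
        ids = sub.loc[sub["cell_type"].astype(str) == ct, "cell_id"].astype(str)
        idx = [positions[c] for c in ids]
        cols[:, j] = expr[:, idx].mean(axis=1)
    return ExpressionProfile(
        matrix=cols,
        gene_labels=list(gene_labels),
        celltype_labels=celltypes,
        context_label=str(context),
    )


def complex_expression(
    profile: ExpressionProfile, subunits, celltype: str
) -> float | None:
    """Limiting-subunit rule: minimum expression over the complex's subunits.

    Missing if any subunit gene is absent from the profile.
    """
    subunits = list(subunits)
    if not subunits:
        raise SchemaError("empty subunit list")
    values = [profile.expression(g, celltype) for g in subunits]
    if any(v is MISSING for v in values):
        return MISSING
    return min(values)


def protein_comm_score(
    profile: ExpressionProfile,
    lr: ProteinLR,
    sender: str,
    receiver: str,
    method: str = "mean",
) -> float | None:
    """Ligand expression in the sender combined with receptor in the receiver."""
    if method not in ("mean", "product"):
        raise ValueError(f"unknown method {method!r}")
    lig = complex_expression(profile, lr.ligand_subunits, sender)
    rec = complex_expression(profile, lr.receptor_subunits, receiver)
    if lig is MISSING or rec is MISSING:
        return MISSING
    return (lig + rec) / 2.0 if method == "mean" else lig * rec


def metabolite_presence(
    profile: ExpressionProfile, row: MetaboliteRow, sender: str
) -> float | None:
    """Enzyme surrogate for metabolite availability in the sender.

    max(0, mean producing-gene expression - mean consuming-gene
    expression); genes absent from the profile are dropped from their
    mean, and the score is missing only if every producing gene is
    absent. An empty consuming list contributes zero.
    """
    produce = [
        v for g in row.producing_genes if (v := profile.expression(g, sender)) is not MISSING
    ]
    if not produce:
        return MISSING
    consume = [
        v for g in row.consuming_genes if (v := profile.expression(g, sender)) is not MISSING
    ]
    consumed = float(np.mean(consume)) if consume else 0.0
    return max(0.0, float(np.mean(produce)) - consumed)


def metabolite_comm_score(
    profile: ExpressionProfile, row: MetaboliteRow, sender: str, receiver: str
) -> float | None:
    """Metabolite presence in the sender times sensor expression in the receiver."""
    presence = metabolite_presence(profile, row, sender)
    sensor = complex_expression(profile, row.sensor_subunits, receiver)
    if presence is MISSING or sensor is MISSING:
        return MISSING
    return presence * sensor


def build_coupled_tensors(
    profiles: list[ExpressionProfile],
    lr_table: ProteinLRTable,
    met_table: MetaboliteTable,
    options: BuildOptions = BuildOptions(),
) -> CoupledPair:
    """Score every combination and assemble the coupled 4D tensor pair.

    Contexts keep the given order (e.g. time order); the cell-type axis
    is the union across contexts (senders = receivers), so populations
    appearing late are preserved, with their absent combinations masked
    (or zeroed, per options.missing_policy). Interactions that cannot
    be scored in any context are dropped from their private axis.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 contexts to build a communication tensor")
    contexts = [p.context_label for p in profiles]
    if len(set(contexts)) != len(contexts):
        raise ValueError("duplicate context labels")
    celltypes: list[str] = []
    for p in profiles:
        for ct in p.celltype_labels:
            if ct not in celltypes:
                celltypes.append(ct)

    def score_tensor(rows, scorer):
        n = (len(contexts), len(rows), len(celltypes), len(celltypes))
        values = np.zeros(n)
        observed = np.ones(n, dtype=bool)
        for i, profile in enumerate(profiles):
            present = set(profile.celltype_labels)
            for j, row in enumerate(rows):
                for k, snd in enumerate(celltypes):
                    for l, rcv in enumerate(celltypes):
                        if snd not in present or rcv not in present:
                            score = MISSING
                        else:
                            score = scorer(profile, row, snd, rcv)
                        if score is MISSING:
                            observed[i, j, k, l] = False
                        else:
                            values[i, j, k, l] = score
        return values, observed

    def proteins_scorer(profile, row, snd, rcv):
        return protein_comm_score(profile, row, snd, rcv, options.protein_method)

    values_a, observed_a = score_tensor(lr_table.rows, proteins_scorer)
    values_b, observed_b = score_tensor(met_table.rows, metabolite_comm_score)

    # drop interactions that cannot be scored in any context
    keep_a = observed_a.any(axis=(0, 2, 3))
    keep_b = observed_b.any(axis=(0, 2, 3))
    if options.missing_policy == "mask":
        mask_a = observed_a.astype(float)
        mask_b = observed_b.astype(float)
    else:  # "zero": unscorable entries become observed zeros
        mask_a = np.ones_like(values_a)
        mask_b = np.ones_like(values_b)
    if not keep_a.any():
        raise ValueError("every protein interaction is unscorable in all contexts")
    if not keep_b.any():
        raise ValueError("every metabolite interaction is unscorable in all contexts")

    tensor_a = CommTensor(
        values=values_a[:, keep_a],
        mask=mask_a[:, keep_a],
        context_labels=contexts,
        lr_labels=[r.interaction_id for r, k in zip(lr_table.rows, keep_a) if k],
        sender_labels=celltypes,
        receiver_labels=celltypes,
        modality="protein",
    )
    tensor_b = CommTensor(
        values=values_b[:, keep_b],
        mask=mask_b[:, keep_b],
        context_labels=contexts,
        lr_labels=[r.interaction_id for r, k in zip(met_table.rows, keep_b) if k],
        sender_labels=celltypes,
        receiver_labels=celltypes,
        modality="metabolite",
    )
    return validate_coupled_pair(tensor_a, tensor_b)
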