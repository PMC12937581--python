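import numpy as np
import pandas as pd
import pytest

from ctca import (
    CommTensor,
    FactorModel,
    MetaboliteRow,
    MetaboliteTable,
    ProteinLR,
    ProteinLRTable,
    SimSpec,
    coupled_pair,
    validate_coupled_pair,
)


def random_model(rng, shapes=(3, 4, 5, 2, 3), rank=2):
    c, p, pp, s, t = shapes
    return FactorModel(
        rank=rank,
        contexts=np.abs(rng.standard_normal((c, rank))),
        lr_a=np.abs(rng.standard_normal((p, rank))),
        lr_b=np.abs(rng.standard_normal((pp, rank))),
        senders=np.abs(rng.standard_normal((s, rank))),
        receivers=np.abs(rng.standard_normal((t, rank))),
    )


def random_pair(rng, shapes=(3, 4, 5, 2, 3), mask_fraction=0.0):
    """A coupled pair with random (non-low-rank) values and optional masking."""
    c, p, pp, s, t = shapes
    tensors = []
    for lr_n, prefix, modality in ((p, "lrA", "protein"), (pp, "lrB", "metabolite")):
        shape = (c, lr_n, s, t)
        mask = (rng.random(shape) >= mask_fraction).astype(float)
        tensors.append(
            CommTensor(
                values=np.abs(rng.standard_normal(shape)),
                mask=mask,
                context_labels=[f"context_{i}" for i in range(c)],
                lr_labels=[f"{prefix}_{i}" for i in range(lr_n)],
                sender_labels=[f"celltype_{i}" for i in range(s)],
                receiver_labels=[f"celltype_{i}" for i in range(t)],
                modality=modality,
            )
        )
    return validate_coupled_pair(tensors[0], tensors[1])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_pair(rng):
    return random_pair(rng)


@pytest.fixture
def noiseless_pair():
    spec = SimSpec(
        shapes=(5, 8, 6, 4, 4), rank=2, seed=7, sparsity=0.0,
        noise_level=0.0, missing_fraction=0.0,
    )
    pair, truth = coupled_pair(spec)
    return pair, truth


# --- toy expression fixture used for hand-computed tensor construction ---
# Two contexts (month1, month2), cell types X and Y; Y is absent from
# month1. Genes chosen so every scorer branch is exercised.

TOY_GENES = ["Lg1", "Rc1", "Lg2a", "Lg2b", "Rc2", "Prod1", "Cons1", "Sens1"]


def toy_metadata():
    rows = [
        ("c1", "X", "month1"),
        ("c2", "X", "month1"),
        ("c3", "X", "month2"),
        ("c4", "Y", "month2"),
        ("c5", "Y", "month2"),
    ]
    return pd.DataFrame(rows, columns=["cell_id", "cell_type", "context"])


def toy_expression():
    # columns: c1..c5 in metadata order; rows: TOY_GENES
    return np.array(
        [
            # c1   c2   c3   c4   c5
            [1.0, 3.0, 2.0, 4.0, 6.0],  # Lg1
            [2.0, 2.0, 1.0, 3.0, 5.0],  # Rc1
            [4.0, 4.0, 5.0, 1.0, 1.0],  # Lg2a
            [6.0, 2.0, 3.0, 2.0, 2.0],  # Lg2b
            [0.0, 2.0, 4.0, 2.0, 4.0],  # Rc2
            [3.0, 3.0, 6.0, 2.0, 2.0],  # Prod1
            [1.0, 1.0, 2.0, 4.0, 4.0],  # Cons1
            [2.0, 2.0, 1.0, 3.0, 3.0],  # Sens1
        ]
    )


def toy_tables():
    lr = ProteinLRTable(
        [
            ProteinLR("LR1", ("Lg1",), ("Rc1",)),
            ProteinLR("LR2", ("Lg2a", "Lg2b"), ("Rc2",)),
        ]
    )
    met = MetaboliteTable(
        [
            MetaboliteRow("MET1", "metab", ("Prod1",), ("Cons1",), ("Sens1",)),
        ]
    )
    return lr, met
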