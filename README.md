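# ctca — coupled tensor component analysis of cell–cell communication

Cell–cell communication (CCC) inferred from single-cell transcriptomics
is multimodal: protein ligand–receptor signaling is read directly from
the expression of the interacting genes, while metabolite–sensor
signaling is inferred indirectly from the enzymes that produce and
consume each metabolite. The two kinds of scores live on different
scales and are usually analyzed separately, which hides programs in
which protein and metabolite signals act in concert across time.

`ctca` addresses this by jointly decomposing two 4D communication
tensors that share three axes. For each modality, scores are organized
as a non-negative tensor over (context, interaction, sender cell type,
receiver cell type) — contexts are typically time points. Writing the
protein tensor as χ (C × P × S × T) and the metabolite tensor as χ′
(C × P′ × S × T), the coupled non-negative CP model is

    χ  ≈ Σ_r  c_r ⊗ p_r  ⊗ s_r ⊗ t_r        r = 1..R
    χ′ ≈ Σ_r  c_r ⊗ p′_r ⊗ s_r ⊗ t_r

where the context (c_r), sender (s_r) and receiver (t_r) loading
vectors are **shared** between the two tensors and only the
interaction loadings (p_r, p′_r) are private. Each factor r is a
communication program: a temporal trajectory, a set of sender–receiver
cell pairs, and the protein and metabolite interactions that rise and
fall together. The factors are estimated by minimizing the masked,
weighted squared error

    min  α₁‖M ∗ (χ − χ̂)‖²_F + α₂‖M′ ∗ (χ′ − χ̂′)‖²_F ,   α₁ + α₂ = 1

with alternating least squares (column-wise HALS with a non-negativity
floor). M and M′ are binary masks marking observed entries, so missing
scores — e.g. a cell type absent from an early time point — are
excluded from the fit via EM-style imputation rather than treated as
zeros. The default balancing weights α₁ = α₂ = 0.5 weight the
modalities equally.

The package provides:

- `ctca.tensors` — tensor/factor-model containers, reconstruction and
  the masked coupled objective;
- `ctca.solver` — the masked non-negative coupled ALS fit;
- `ctca.build` — construction of the coupled tensors from per-context
  expression profiles and interaction tables, with simple pluggable
  protein and metabolite scorers (externally computed scores can be
  supplied as long-format CSV instead);
- `ctca.selection` — rank selection (error-curve elbow) and stability
  across restarts (permutation-matched factor match score);
- `ctca.postprocess` — loading normalization, joint sender–receiver
  loadings, top interactions per factor;
- `ctca.simulate` — coupled low-rank simulations with planted factors,
  noise and missingness;
- a `ctca` command line (`build`, `fit`, `rank-scan`, `stability`,
  `simulate`, `export`).

## Worked example

Simulate a coupled pair with two planted programs, fit it, and inspect
the context loadings:

```python
import pandas as pd
from ctca import (SimSpec, coupled_pair, FitConfig, fit_ctca,
                  factor_match_score, normalize_model, display_normalize)

spec = SimSpec(shapes=(4, 12, 8, 3, 3), rank=2, seed=11, noise_level=0.05)
pair, truth = coupled_pair(spec)
result = fit_ctca(pair, FitConfig(rank=2, n_restarts=3, seed=0))
print("converged:", result.converged, "after", result.n_iter, "sweeps")
print("relative errors (protein, metabolite): (%.4f, %.4f)" % result.relative_errors)
print("factor match vs planted truth: %.4f" % factor_match_score(result.model, truth))
normalized = normalize_model(result.model)
print(pd.DataFrame(display_normalize(normalized.contexts),
                   index=pair.tensor_a.context_labels,
                   columns=["factor_1", "factor_2"]).round(3))
```

Output:

```
converged: True after 9 sweeps
relative errors (protein, metabolite): (0.0379, 0.0382)
factor match vs planted truth: 0.9998
           factor_1  factor_2
context_1     0.027     1.000
context_2     1.000     0.377
context_3     0.241     0.008
context_4     0.003     0.040
```

The relative errors sit at the 5% noise floor — the model explains
everything except the injected noise — and the factor match score of
1.0 (up to noise) says the planted loadings were recovered up to factor
order and scale. The context table, rescaled per factor to its
maximum, shows one program peaking at context 2 and the other at
context 1: the shared temporal dynamics that both modalities follow.

The same pipeline from the shell:

```bash
ctca simulate --shapes 4,12,8,3,3 --rank 2 --seed 11 --out scratch/pair.h5
ctca fit --pair scratch/pair.h5 --rank 2 --restarts 3 --out scratch/fit
ctca export --fit-dir scratch/fit --out scratch/tables
```

`export` writes per-factor tables of contexts, sender–receiver cell
pairs (outer product of the shared cell loadings), and protein and
metabolite interactions, each rescaled per factor to its maximum, plus
the interactions whose normalized loading exceeds 0.75 in some factor.

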