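# Methods

## Model

Two non-negative 4D tensors hold communication scores per (context,
interaction, sender cell type, receiver cell type): χ of shape
C × P × S × T for protein ligand–receptor pairs and χ′ of shape
C × P′ × S × T for metabolite–sensor pairs. The coupled CP model
factorizes both into R rank-1 terms with shared context, sender and
receiver loadings and private interaction loadings:

    χ_ijkl  ≈ Σ_r c_ir p_jr  s_kr t_lr
    χ′_imkl ≈ Σ_r c_ir p′_mr s_kr t_lr

All loadings are constrained non-negative, so factors read as additive
parts, as in NMF. Estimation minimizes

    f = α₁ ‖M ∗ (χ − χ̂)‖²_F + α₂ ‖M′ ∗ (χ′ − χ̂′)‖²_F

over all five loading matrices, where M, M′ are binary observation
masks (0 = missing) and α₁ + α₂ = 1 are convex balancing weights. The
coupling is what aligns the two modalities: any temporal or cellular
pattern must be supported by both tensors in proportion to the alphas.

Assumptions worth keeping in mind: scores are treated as approximately
additive across programs; shared modes assume the two modalities
follow the *same* context/cell-pair patterns (modality-specific
dynamics end up split across factors or in the residual); masked
entries are missing-at-random given the model.

## Solver

Alternating least squares with column-wise HALS updates. Per sweep:

1. **Impute** working copies W = M ∗ χ + (1 − M) ∗ χ̂ (and likewise for
   χ′): observed entries are kept, missing entries are filled with the
   current reconstruction. This is an EM surrogate; because missing
   residuals are zero at imputation time, the masked objective is
   non-increasing across sweeps (the full-mask case is plain ALS).
2. **Update** factor matrices in the fixed order contexts → protein
   interactions → metabolite interactions → senders → receivers. For a
   shared mode, each column a_r is moved by the alpha-weighted sum of
   both tensors' least-squares residual gradients and divided by the
   alpha-weighted Gram diagonal, then floored:

       a_r ← max(ε, a_r + [Σ_m α_m ((X_m K_m)_{:,r} − A (K_mᵀK_m)_{:,r})]
                           / [Σ_m α_m (K_mᵀK_m)_{rr}])

   with K_m the Khatri–Rao product of that modality's remaining
   factors. Private modes use only their own tensor. A zero diagonal
   leaves the column unchanged and records a degenerate-factor
   warning.
3. **Record** the objective on the original masked data; stop when the
   relative change drops below `tol` or at `max_iter`.

Fixed conventions: the mode-n unfolding orders remaining modes by
increasing index with the earliest varying fastest, and the matching
Khatri–Rao product is accumulated in reverse index order. Axis order
is (context, interaction, sender, receiver) throughout.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `alphas` | (0.5, 0.5) | convex weights of the two error terms; equal weighting unless the user has a reason to favor one modality |
| `tol` | 1e-8 | relative objective change for convergence |
| `max_iter` | 500 | sweep cap |
| `init` | `"random"` | `\|N(0,1)\|` entries; `"svd"` uses leading singular vectors of each unfolding, negatives clipped |
| `n_restarts` | 1 | seeds `seed, seed+1, …`; lowest final objective wins, ties to the lower seed |
| `epsilon` | 1e-16 | non-negativity floor; keeps columns from locking at exact zero |

The returned model is un-normalized (all-ones per-factor weights);
`normalize_model` moves all column norms into explicit per-modality
factor weights without changing the reconstruction.

Numerical notes: masked entries of the stored values are zeroed at
construction — the mask is the single source of truth, which also
makes the fit bitwise invariant to whatever garbage sat at masked
positions. CP-ALS can enter slow-convergence "swamps" when planted or
estimated factors are nearly collinear; restarts mitigate but do not
eliminate this, and occasional fits stop at the sweep cap with a small
residual plateau while the factors themselves are already essentially
recovered.

## Tensor construction

Per context, expression is aggregated to mean log-normalized
expression per cell type (cells matched to metadata by id). The
shipped scorers are deliberately simple, standing behind a pluggable
surface so scores from dedicated inference tools can be injected as
long-format CSV:

- protein: ligand expression in the sender and receptor expression in
  the receiver, combined by mean or product; protein complexes reduce
  to their minimum subunit (limiting stoichiometry);
- metabolite: sender-side presence max(0, mean producing-enzyme −
  mean consuming-enzyme expression), times sensor expression in the
  receiver; genes absent from the data drop out of their mean, and the
  score is missing only when every producing gene (or any sensor
  subunit) is absent.

The cell-type axis is the union across contexts so late-appearing
populations are kept; combinations involving a cell type absent from a
context, and unscorable interactions, are masked by default
(`missing_policy="mask"`) or stored as observed zeros (`"zero"`).
Interactions unscorable in every context are dropped. Gene symbols
match case-sensitively after whitespace stripping.

## Rank selection and stability

The error curve reports, per candidate rank, the best (over restarts)
combined normalized error sqrt(f / (α₁‖M∗χ‖² + α₂‖M′∗χ′‖²)) — the
same currency the solver minimizes. The elbow is the interior rank
with maximum perpendicular distance to the chord joining the curve's
endpoints, after min-max normalizing both axes; normalization makes
the choice invariant to affine rescaling of the error axis, and a
numerically linear curve triggers a warning (ties go to the smallest
rank).

Stability across restarts uses the factor match score: columns of all
five loading matrices are L2-normalized per mode, the congruence of a
factor pair is the product of the five cosines, and the score is the
mean congruence under the optimal factor assignment
(linear-sum-assignment). It is 1 exactly when two models agree up to
factor permutation and per-factor positive rescaling.

## Synthetic data

`SimSpec` defaults describe the simulated study conditions: shapes
(6, 15, 10, 4, 4) — six contexts, 15 protein and 10 metabolite
interactions, four cell types — rank 3, 5% relative Frobenius noise,
no missingness. Planted loadings are |N(0,1)| with a 30% sparsity
fraction zeroed per column (patchy loadings are what real programs
look like: most interactions and cell types do not participate in
most programs); a column that would become all-zero has its largest
entry restored. Noise is i.i.d. Gaussian scaled to the requested
fraction of the signal norm and added before clipping at zero, so the
realized noise level is at or slightly below nominal. Missingness is
i.i.d. Bernoulli per entry.

What the generator does *not* emulate: count noise and dropout of real
scRNA-seq, correlated missingness (whole cell types absent from a
context), non-multiplicative score distributions, or modality-specific
dynamics that violate the shared-mode assumption. Passing tests
therefore demonstrate correctness and robustness of the decomposition
under its own model class, not end-to-end performance on real data.

Sparse planted factors are occasionally nearly collinear or very
unequal in norm, in which case a rank-(R−1) fit already explains most
of the data and the elbow criterion can land below the planted rank;
the rank-recovery rate in the acceptance summary quantifies this.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
(6, 15, 10, 4, 4) geometry — the scale at which every property can be
checked in seconds per fit — with ten replicates for the stochastic
summaries (noise robustness, rank recovery, coupling benefit).
Exactness checks (reconstruction, objective, HALS updates against
independent oracles) use exhaustive small instances up to 3 per mode
and rank 4.

## Known limitations

- Exactly two coupled tensors; coupling is fixed to the
  context/sender/receiver modes.
- No regularization (sparsity, smoothness) and no automatic tuning of
  the balancing weights; the 0.5/0.5 default is a choice, not an
  optimum.
- Dense storage only; memory scales as the product of the four axis
  lengths per tensor.
- The shipped scorers are reference simplifications; serious analyses
  should inject scores from dedicated protein- and metabolite-CCC
  tools.
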