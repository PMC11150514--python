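# Methods

## Model

The predictor treats miRNA–disease association discovery as bounded
low-rank matrix completion on the heterogeneous block matrix
`H = [[MM, A], [Aᵀ, DD]]`, where `A` is the binary association matrix and
`MM`, `DD` are fused similarity matrices.  The underlying assumptions are
(i) functionally similar miRNAs associate with semantically similar
diseases, so the full association structure is approximately low rank;
(ii) recorded associations are trustworthy positives while zeros are
merely unverified — hence the observation set Ω contains both similarity
blocks and only the 1-entries of the association blocks; (iii) every
meaningful entry lives in [0, 1], enforced as a hard box constraint.

Rather than the nuclear norm, the rank surrogate is the truncated
Schatten p-norm `Σ_{i>r} σ_i^p`, which leaves the `r` dominant singular
values (the signal) unpenalized and shrinks only the tail.  The
non-convexity is handled by a majorize–minimize outer loop: with
truncation factors `A = U_rᵀ`, `B = V_rᵀ` from the current SVD, a
first-order expansion yields per-index weights

```
w_i = p · (1 − σ_i(BᵀA)) · max(σ_i(X), σ_floor)^(p−1)
```

`σ_i(BᵀA)` is 1 for the top `r` indices and 0 beyond, so the weight
sequence is 0 (head) then positive (tail) and — because the σ are sorted
descending and `p ≤ 1` — always non-decreasing.  That ordering is exactly
the condition under which the weighted singular-value contraction
`S_{w,τ}(Q) = U max(Σ − τ·diag(w), 0) Vᵀ` is the exact proximal mapping of
the weighted nuclear norm, so the inner ADMM subproblem is solved in
closed form.

The inner ADMM splits the objective into
- `T`-update: closed-form quadratic solve using the diagonal resolvent of
  the sampling operator `(I + (α/β)P_Ω)⁻¹ = I − (α/(α+β))P_Ω`, followed by
  clipping to [0, 1];
- `X`-update: weighted contraction of `T − E/β` at threshold `1/β`;
- `E`-update: dual ascent `E ← E + β(X − T)`.

Stopping uses the relative change `S1 = ‖X_{k+1}−X_k‖_F/‖X_k‖_F ≤ ε₁`
together with its increment `S2 = |S1_{k+1}−S1_k|/max(|S1_k|,1) ≤ ε₂`.
With `r = 0, p = 1` every weight equals 1 and the scheme reduces exactly
to box-constrained nuclear-norm ADMM — a property the test suite checks
against an independently coded reference.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 20 | weight of the data-fit term on Ω (unitless) |
| `beta` | 5 | ADMM penalty; `1/beta` is the shrinkage threshold |
| `p` | 1 | Schatten exponent in (0, 1] |
| `r` | 5 | number of leading singular values exempt from shrinkage |
| `outer_iters` | 4 | truncation-factor refreshes |
| `reweight_iters` | 1 | weight refreshes per outer step |
| `eps1`, `eps2` | 2e-3, 1e-5 | inner stopping tolerances |
| `max_inner` | 200 | inner iteration safety cap |
| `sigma_floor` | 1e-10 | keeps `p<1` weights finite at zero singular values |
| `phi` | 0.5 | semantic contribution decay per ontology edge |

The defaults `alpha=20, beta=5, p=1, r=5` are the configuration at which
this family of models reports its best cross-validated AUC on the
standard HMDD v2.0 benchmark; `eps1`/`eps2` and the iteration caps are
this package's own numerical choices and are fully configurable.  The
solver warm-starts each outer step from the previous iterates,
initializes `X₁ = T₁ = H`, `E₁ = 0`, takes the final output from `X`
(clipped), and stops the outer loop early once `X` moves by less than
`eps1` in relative Frobenius norm.

## Numerical choices

- **Symmetric contraction path.**  For a symmetric input the weighted
  contraction is computed in the eigenbasis (singular values are eigenvalue
  magnitudes, reconstruction `Σ sign(λ_i)·s'_i v_i v_iᵀ`).  This is the
  same mapping, but when two singular values collide at the truncation
  boundary the SVD basis within the degenerate cluster is arbitrary while
  the weights differ across the boundary; the eigendecomposition still
  separates a ±λ pair cleanly, keeping the iterate exactly symmetric.
  Without this path, symmetry can break catastrophically (observed ~0.27
  max asymmetry on small noisy systems).
- **Log base.**  The information-content contribution uses the natural
  logarithm; the base partially cancels in the similarity ratio but not
  fully, so it is fixed and documented here.
- **Degenerate conventions.**  Scheme-2 similarity returns 0 when both
  totals are 0 (every shared term ubiquitous); fused similarity diagonals
  are forced to 1; ranking ties are broken by miRNA id ascending; matrix
  readers symmetrize asymmetries up to 1e-6 by averaging and reject worse.
- **GIPK in cross-validation** is recomputed from the training matrix of
  each fold, so held-out pairs never influence a training artifact (the
  test suite verifies this by sentinel-poisoning held-out cells); this is
  the leakage-safe choice.
- **Held-out positives** are removed from Ω entirely (not re-included as
  observed zeros), consistent with treating zeros as unverified.
- **LOOCV pooling.**  Leave-one-out AUC pools all test-vs-candidate
  pairwise comparisons into one Mann–Whitney statistic (a "global"
  ranking); a per-disease variant would be the natural alternative and is
  not implemented.

## Synthetic generator

`generate_planted_dataset` draws nonnegative uniform latent factors
`G (nm×k)`, `F (nd×k)`; the truth propensity is `GFᵀ` scaled by its
maximum, so with `noise_sd = 0` its rank is exactly `k`.  The top
`⌊density·nm·nd⌋` entries become known associations (global threshold, so
density is exact).  `MM`/`DD` are RBF kernels over the latent rows (mean
squared-distance bandwidth) with optional symmetric Gaussian perturbation,
clipped to [0, 1] with unit diagonal.  Defaults (`nm=60, nd=40, k=3,
density=0.3, noise_sd=0.05`) give a system dense enough that hold-out
folds retain informative interaction profiles yet small enough to re-solve
hundreds of times; benchmark runs that isolate the completion mechanism
use `noise_sd = 0`.

What the generator does *not* emulate: the heavy-tailed degree
distribution of real HMDD catalogues, the real MeSH topology (the toy DAG
is a layered tree with a shared root), annotation noise (false positives
in the catalogue), and the much lower density (~2.9%) of the real 495×383
benchmark.  Passing the planted-recovery checks therefore demonstrates
that the solver recovers the structure it assumes — not that real-data
AUCs are reproduced; those require the external databases and can be run
through the CLI on user-supplied files.

Problem sizes in the packaged benchmarks (60×40 planted systems, 10
seeds, ≤6×6 prox instances, 20×20 reduction systems) were chosen so the
full suite and the acceptance script each complete in well under a minute
while keeping the recovery statistics stable across seeds.

## Known limitations

- A faithful LOOCV re-solves the completion once per known association;
  above `loocv_cap` (default 200) a warning is emitted and the CLI demands
  `--force`.  The documented fast mode (score once, rank all) is not used
  anywhere results are reported.
- Full SVDs at every inner iteration limit practical system sizes to a few
  thousand rows on one CPU; no randomized SVD or GPU path.
- The functional-similarity matrix `MF` is consumed as given; the
  MISIM-style algorithm that produces it is out of scope.
- Weighted-average similarity fusion and the hard nonzero-primary rule are
  inherited design choices, not optimized.
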