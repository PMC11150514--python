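# mircomplete

Prediction of candidate miRNA–disease associations by low-rank matrix
completion of a heterogeneous similarity network.

MicroRNAs regulate gene expression post-transcriptionally, and their
dysregulation is implicated in many complex diseases; experimentally
confirming which miRNA contributes to which disease is slow and costly.
Given a catalogue of *known* associations (an HMDD-style pair list), a
miRNA functional-similarity matrix and disease ontology DAGs,
`mircomplete` scores every unverified miRNA–disease pair with a
probability-like value in [0, 1], so that laboratory validation can be
prioritized.  It is aimed at computational biologists who want a
reproducible, fully scriptable pipeline with cross-validation built in.

## Method

Let `A ∈ {0,1}^{nm×nd}` be the known association matrix.  The pipeline:

1. **Similarity fusion.**  Disease semantic similarity is the average of two
   DAG-based scores: scheme 1 decays a term's contribution geometrically
   (`W₁(t) = max φ·W₁(child)` with `φ = 0.5`, `W₁(d)=1`), scheme 2 uses the
   information content `W₂(t) = −log(n_DAGs(t)/n_diseases)`.  Gaussian
   interaction-profile kernel (GIPK) similarity
   `exp(−λ‖a_i − a_j‖²)`, with `λ` the reciprocal mean squared profile
   norm, is computed from `A` for both sides.  The fused similarities `MM`
   and `DD` take the primary (functional/semantic) entry where non-zero and
   the GIPK entry otherwise.
2. **Heterogeneous target.**  `H = [[MM, A], [Aᵀ, DD]]`; the observed set
   Ω contains the similarity blocks and the known 1-entries (association
   zeros are unverified candidates, not observations).
3. **Truncated Schatten p-norm completion.**  The completed matrix solves

   ```
   min_X  Σ_{i>r} σ_i(X)^p  +  (α/2)‖P_Ω(X) − P_Ω(H)‖²_F    s.t.  0 ≤ X ≤ 1
   ```

   via an outer loop that linearizes the non-convex norm into a weighted
   nuclear norm, `w_i = p(1 − σ_i(BᵀA))σ_i^{p−1}` (≈0 for the top `r`
   singular values, positive for the tail), and an inner ADMM alternating a
   box-constrained data-fit update, a *weighted* singular-value contraction
   `U max(Σ − diag(w)/β, 0) Vᵀ`, and a dual update.  Defaults
   `α = 20, β = 5, p = 1, r = 5`.  The completed association block is the
   score matrix.

Cross-validation (global leave-one-out and seeded k-fold), AUC/AUPR,
threshold-optimized confusion metrics and a sparsity-sensitivity
experiment are included, along with a planted-low-rank synthetic generator
so the whole pipeline runs without any external download.

## Worked example

Generate a small planted benchmark, score it, and cross-validate:

```sh
mircomplete simulate --nm 20 --nd 12 --rank 2 --density 0.25 --noise-sd 0 \
    --seed 7 --out-dir demo
mircomplete predict --pairs demo/pairs.tsv --mf demo/mm.tsv --out-dir demo/run
head -6 demo/run/predictions.tsv
```

```
disease_id  rank  miRNA_id  score
d001        1     m008      0.7323711129833903
d001        2     m015      0.6669414552760696
d001        3     m005      0.6290788674148399
d001        4     m013      0.5218064118137808
d001        5     m007      0.45361728814904634
```

Each row ranks a *candidate* miRNA (known pairs are excluded) for disease
`d001`; the score is the completed matrix entry, interpretable as an
association probability.  Five-fold cross-validation on the same fixture:

```sh
mircomplete evaluate --pairs demo/pairs.tsv --scheme kfold --k 5 --seed 7 \
    --out-dir demo/eval
```

```
{"scheme": "kfold", "seed": 7, "auc": 0.842013888888889,
 "aupr": 0.5996616302077543,
 "per_fold": [0.7795, 0.8281, 0.8785, 0.8854, 0.8385]}
```

Held-out known associations are ranked against all unknown pairs; an AUC
of 0.84 on this deliberately tiny, GIPK-only run means held-out positives
outscore random unknown pairs about 84% of the time (larger planted
systems with similarity inputs reach ≈0.99; see below).

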