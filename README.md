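# netsmooth

Network-guided prediction of non-response to aromatase inhibitors (AIs) in
ER+ breast cancer.

Aromatase inhibitors (anastrozole, exemestane, letrozole) deprive ER+
tumors of estrogen; resistance is common and heterogeneous, and the genes
driving it differ between tumors even when they sit in the same pathway.
`netsmooth` addresses this by diffusing each tumor's somatic mutations and
differential expression over a confidence-weighted protein-interaction
network, so that tumors altering *different* genes of the *same* network
neighborhood end up with similar profiles, and by scoring each gene's joint
proximity to the tumor's alterations and to drug-relevant gene sets. The
resulting per-tumor features feed standard cross-validated classifiers that
predict non-response, optionally blended with a classifier trained on
cell-line estrogen-withdrawal assays.

## Method

Given the weighted network with edge-weight matrix `W` and weighted-degree
diagonal `Δ`, the Laplacian-normalized matrix is

    W′ = Δ^(−1/2) W Δ^(−1/2)      (|λ|max ≤ 1)

A prior vector `Y : V → [0, 1]` (a binary gene-set indicator restricted to
the network, `Y_S[v] = 1 iff v ∈ S ∩ V`) is smoothed by iterating

    F(t) = α · W′ F(t−1) + (1 − α) · Y,   F(0) = Y

until `‖F(t) − F(t−1)‖₂ < ε` (defaults α = 0.5, ε = 1e−6); the fixed point
is `(I − αW′)^(−1)(1 − α)Y`, which the package also solves directly as a
small-network oracle. Per-sample binary profiles — the mutation matrix `M`
and the differential-expression matrix `D` (entries of the log-fold matrix
`E` beyond σ = 2 per-sample standard deviations) — are smoothed row-wise
into `M_P`, `D_P` with columns equal to the network nodes.

For each smoothed target vector `T` (per-drug protein targets, the
estrogen-receptor proteins ESR1/ESR2, and their transcriptional targets),
the min-combination matrix

    M_{P,T}[i, j] = min{ M_P[i, j], T[j] }

scores gene `j`'s proximity to **both** the tumor's alterations and the
target set. Each such matrix contributes a row mean, a row standard
deviation and its top-10 PCA sample scores as features; per-drug expression
signatures add a Pearson correlation and a dot product against each tumor's
log-fold expression, and categorical clinical variables enter as one-hot
indicators. Non-response labels (1 = discontinued for non-response or died
during treatment) come from treatment records; ER– patients never given an
AI join the pooled task as prior-knowledge positives. Evaluation is
leave-one-out cross-validation scored by rank-based ROC AUC, and a
cell-line classifier can be blended as `p = γ·p_c + (1 − γ)·p_p` with γ
tuned on a stratified 10% holdout. Cell lines are called
estrogen-responsive when the growth measure `(GR_E2 − 1)/(GR_noE2 − 1)`
exceeds 1, with `GR` the day-5/day-0 growth ratio per condition.

A first-class synthetic-data module generates the complete input bundle
with a planted, network-proximal response signal, so every stage is
testable without restricted clinical data.

## Worked example

Simulate a cohort, build features, and cross-validate — from the shell:

```
$ netsmooth simulate --config sim.yaml --out data            # sim.yaml: n_genes: 300, n_samples: 120, module_size: 5, seed: 1
wrote synthetic bundle (120 samples, 300 genes) to data
$ netsmooth features --config data/run.yaml --out features.csv
wrote 129 features for 120 samples to features.csv
$ netsmooth predict --features features.csv --treatment data/treatment.csv \
      --model logistic_l2 --seed 1 --out cv
LOO ROC AUC = 0.9898 (logistic_l2, n=120)
```

The 129 features are 2 smoothed profiles × 5 target sets × (mean, sd,
10 PCA scores) = 120, plus 2 signatures × (correlation, dot) = 4, plus 5
clinical indicator columns; the AUC of 0.99 reflects recovery of the
planted network-proximal signal at full strength. The same study from
Python, including the naive baseline (raw binary mutation/DE columns):

```python
from netsmooth.pipeline import run_synthetic_benchmark
from netsmooth.synthetic_data import SimConfig

res = run_synthetic_benchmark(SimConfig(seed=1), include_naive=True)
print(f"constructed LOO AUC: {res['constructed_auc']:.3f}")   # 0.975
print(f"naive LOO AUC:       {res['naive_auc']:.3f}")         # 1.000
```

At this default scale (200 samples × 500 genes) the naive features keep
pace — raw binary columns are individually informative when the cohort is
large relative to the gene universe. The advantage of smoothing appears in
the per-drug-scale comparison regime (`SimConfig.comparison_regime()`:
120 samples × 3000 genes, target module at a well-connected protein),
where constructed features lead by ~0.14 AUC on average.

Cell-line growth analysis:

```python
from netsmooth import cell_line
from netsmooth.synthetic_data import SimConfig, generate_bundle

bundle = generate_bundle(SimConfig(seed=1))
print(cell_line.summarize_growth(bundle.growth).head(3).round(3))
#            gr_e2  gr_noe2  growth_measure  responsive er_status
# cell_line
# CL00       3.003    1.374           5.354        True  positive
# CL01       3.000    1.349           5.728        True  positive
# CL02       3.077    1.388           5.347        True  positive
```

## Layout

- `netsmooth.genomic_io` — readers/writers (edge lists, sample×gene TSV,
  GMT, signatures, clinical CSV) and expression binarization
- `netsmooth.network_propagation` — Laplacian normalization, iterative
  diffusion, closed-form oracle, batched matrix smoothing
- `netsmooth.feature_construction` — min-combination, row summaries, PCA,
  signature similarities, naive baseline
- `netsmooth.labeling` — non-response labels and ER– augmentation
- `netsmooth.prediction` — classifier roster, LOO CV, rank-based AUC,
  univariate screening, γ blending
- `netsmooth.cell_line` — growth ratios, growth measure, responsiveness
- `netsmooth.synthetic_data` — planted-signal input generator
- `netsmooth.pipeline` — end-to-end orchestration
- `netsmooth.cli` — `netsmooth simulate / propagate / features / predict`

See `docs/methods.md` for modeling assumptions, parameter choices and
limitations.
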