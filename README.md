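# nmrfingerprint

1D NMR metabolic fingerprinting for cell-extract studies: spectral quality
control, bucketing, probabilistic quotient normalization (PQN), discriminant
analysis of principal components (DAPC) with cross-validated dimension
selection, correlation-based identification checks, and metabolite set
enrichment analysis (MSEA).

The package targets study designs like an amyloid-challenge experiment on
neuronal cells: cultures exposed to amyloidogenic proteins (Aβ40, Aβ42,
α-synuclein) in different aggregation states (monomer, oligomer, fibril) plus
untreated controls, profiled by 1D ¹H NMR of polar extracts. Its users are
metabolomics analysts who have bucketed spectra (or processed (ppm,
intensity) traces) plus sample metadata and want to know (i) whether
conditions are distinguishable from the fingerprint, and (ii) which
metabolites and pathways drive the separation. A built-in synthetic-data
generator reproduces the whole study design with known ground truth, so
every stage is testable end to end without any external data.

## The methods

**QC.** Each spectrum's TSP reference singlet at 0 ppm is characterized:
full width at half maximum (linear interpolation of the half-maximum
crossings, converted to Hz via the spectrometer frequency), reference
centering, and the mean |intensity| of signal-free regions relative to the
TSP apex. Spectra failing configurable linewidth/baseline/centering
thresholds are excluded. Buckets are integrated with the trapezoidal rule.

**PQN.** After integral normalization to a fixed total area, each sample
*i* is divided by dᵢ = medianⱼ(xᵢⱼ / rⱼ), where r is the bucket-wise median
reference spectrum. This estimates and removes per-sample dilution exactly
for pure multiplicative scaling.

**DAPC.** The autoscaled table (each bucket centered, unit sample SD) is
reduced by PCA (SVD; eigenvalue λₖ = sₖ²/(n−1)); linear discriminant analysis
on the retained scores solves S_b v = λ S_w v and keeps min(g−1, n_pca) axes
scaled to unit pooled within-group variance. Samples are assigned by Gaussian
posteriors with shared pooled covariance and equal priors. The retained PC
count is chosen by repeated stratified 90/10 cross-validation of held-out
assignment accuracy. Bucket contributions are the squared back-projected
discriminant loadings L = P·W, normalized per axis and aggregated with
eigenvalue-share weights; the top 10% (and 25%) of buckets are reported and
mapped to metabolites.

**Identification checks.** Pearson correlations among each metabolite's
buckets on the PQN-normalized table confirm assignments (min pairwise
r ≥ 0.7 by default) or flag overlapped/low-correlation metabolites, which
are excluded from enrichment. Group intensity summaries report the median,
25–75% box and 5–95% whiskers (type-7 quantiles).

**MSEA.** For a metabolite list of size n against a pathway of size K in a
universe of size N with overlap k, the EASE-modified one-tailed Fisher exact
p-value is the hypergeometric upper tail P(X ≥ k−1) (p = 1 for k ≤ 1),
corrected across pathways by Benjamini–Hochberg.

## Worked example

```bash
python examples/04_dapc_classification.py
```

prints (seed 1):

```
conformation: 4 groups, 30 PCs (cross-validated), 3 LDs, reclassification accuracy 100.0%
combined: 10 groups, 25 PCs (cross-validated), 9 LDs, reclassification accuracy 100.0%

top-10% buckets map to 10 metabolites: met002, met010, met012, met020, met043, met054, met058, met060, met061, met065
planted key metabolites:                 met010, met012, met054, met058, met060, met061, met065, met070
recovered 7/8 planted keys
```

The 4-group conformation design necessarily yields 3 discriminant axes
(g − 1); cross-validation picks the retained PC count; the top-10%
contribution set recovers 7 of the 8 metabolites on which the generator
planted condition-specific fold changes. The other examples (`examples/01`
… `07`) each exercise one capability — simulation, QC, PQN, correlation
checks, enrichment, and the full config-driven pipeline.

A thin CLI mirrors the stages:

```bash
nmrfingerprint simulate --seed 1 --out-dir study/
nmrfingerprint run --config config.yaml
```

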