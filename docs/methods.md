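# Methods

This note documents the models, numerical choices and limitations behind
`nmrfingerprint`. It is written for an analyst deciding whether the
defaults fit their study; everything here is configurable unless stated
otherwise.

## Data model and conventions

A bucket table is a samples × buckets matrix of nonnegative intensities.
Buckets are ppm intervals stored descending (left > right), matching the
standard NMR display and spectrometer bucket exports; bucket IDs encode the
interval as `"<high>..<low>"` so a table is self-describing in a single
delimited file, with an optional second header row carrying metabolite
annotations (`name` or `name|compound_id`). Sample metadata is a separate
delimited file keyed by `sample_id` — conditions are never inferred from
sample names. Pathway libraries use the GMT format (`id`, `name`,
members...); a third token `type=<text>` is accepted as pathway-type
metadata for type-grouped ranking.

Two discriminant designs are derived from the same metadata: the
*conformation* design labels samples by aggregation state only (control,
monomer, oligomer, fibril — 4 groups in the full design), the *combined*
design by protein × conformation (10 groups). Technical replicates are
treated as independent samples when fitting, mirroring a design with
n = 6 per condition; averaging them instead is a caller-side reduction of
the table.

## Spectral QC

The TSP reference singlet is located as the intensity maximum in a window
(default ±0.05 ppm around 0). FWHM is measured by linear interpolation of
the two half-maximum crossings flanking the apex rather than by lineshape
fitting: deterministic, robust to grid spacing, and adequate at typical
digital resolution (~3·10⁻⁴ ppm). The baseline statistic is the mean
|intensity| over signal-free regions (defaults 9.8–10.0 and −0.3 to −0.2
ppm) divided by the TSP apex. Default thresholds — 1.5 Hz FWHM, baseline
ratio 0.01, centering within 0.005 ppm — are typical for 600 MHz cryoprobe
extract spectra; they are package defaults, not values claimed to reproduce
any particular study's exclusion set, and all are exposed in configuration.
Measurement failures (no detectable reference peak) are reported as failed
QC with a reason, never as exceptions, so one broken spectrum cannot abort
a batch.

Bucket values are trapezoidal integrals over the interval, making them
independent of digital resolution; negative integrals (over-corrected
baseline) are clipped to zero with a logged warning.

## PQN

Steps: (1) integral-normalize every sample to a fixed total area (the
conventional constant 100 — a *data-independent* target keeps PQN exactly
invariant to per-sample multiplicative scaling, which a mean-area target
would break); (2) reference = bucket-wise median over all samples (a
control-subset reference is available via `median_subset`); (3) quotients
over buckets with positive reference; (4) dᵢ = median quotient; (5) divide.
The recorded dilution factor composes both steps, so `normalized = raw /
factor`. Dilution is identifiable only up to one global scale; comparisons
with known factors are made after dividing each vector by its median.
Zero-reference buckets are excluded from the quotient median rather than
raising — sparse buckets are expected. Autoscaling uses the n−1 sample
standard deviation and drops zero-variance buckets with a warning.

One experiment type (e.g. CPMG) is normalized per run; the pipeline does
not attempt joint normalization of heterogeneous experiments.

## DAPC

PCA is computed by SVD of the autoscaled matrix; eigenvalues are
sₖ²/(n−1); component signs are fixed so each column's largest-magnitude
loading is positive (bit-reproducible orientation). LDA solves the
generalized symmetric eigenproblem S_b v = λ S_w v on the retained scores
and keeps min(g−1, n_pca) axes ordered by λ; each axis is scaled to unit
pooled within-group variance (vᵀS_w v/(n−g) = 1), which makes scores
comparable across runs and the pooled covariance ≈ identity. When
cond(S_w) > 1e10 a ridge of 1e−8·trace(S_w)/p is added. Assignment uses
Gaussian class-conditional densities with the shared pooled covariance and
equal priors (balanced designs); posteriors are computed with log-sum-exp,
ties broken by group order.

Variable contributions back-project the discriminant axes to bucket space
(L = P·W), square and column-normalize, then aggregate across axes with
weights proportional to each axis's eigenvalue — a single ranked list is
reported because multi-axis models are summarized by one "top fraction"
set, and weighting by discriminatory power is the least arbitrary
aggregation; the choice is recorded in the model export. "Top 10%" counts
*buckets* (ceil(0.10·n), boundary ties included), which are then mapped to
metabolites; both views are reported since either reading is defensible.

**Cross-validated dimension selection.** Repeated stratified splits
(default 90/10, 30 repetitions) score held-out assignment accuracy for each
candidate PC count; the same splits are reused across candidates (common
random numbers reduce selection variance), the best mean wins, and ties go
to fewer components. The default candidate grid (5, 10, 15, 20, 25, 30, 40)
spans the feasible range for a 60-sample design. A point worth knowing:
after autoscaling every bucket has unit variance, so each metabolite's
correlated bucket cluster contributes a PCA eigenvalue roughly equal to its
bucket count, and a deeply truncated basis can leave whole metabolites —
including discriminative ones — outside the retained span. Cross-validation
lands at 20–30 PCs on the default synthetic design and restores both
held-out accuracy and contribution recovery.

## Correlation checks and summaries

Pearson correlations are computed on the PQN-normalized (not autoscaled)
table; autoscaling is a positive-slope affine transform per bucket, so r is
unchanged either way — this is asserted by a property test. A metabolite
with ≥ 2 buckets is *confirmed* when its minimum pairwise r ≥ r_min
(default 0.7; no published cut-off exists for this kind of filter, so the
default is this package's own and is config-exposed); single-bucket
metabolites are labelled as such since they cannot be cross-checked.
Group summaries use type-7 (linear interpolation) quantiles — the numpy
default — for bit-reproducible medians, quartile boxes and 5–95% whiskers.

## Enrichment

`ease_fisher(k, n, K, N)` is the hypergeometric upper tail P(X ≥ k−1) with
unchanged margins — the standard DAVID-compatible reading of the EASE
score — computed through scipy's log-gamma-based tail (no normal
approximation); k ≤ 1 gives exactly 1, so single-compound overlaps can
never drive enrichment. The test oracle recomputes tails in exact rational
arithmetic. BH adjustment is the literal step-up suffix-min, capped at 1,
input order preserved. BH spans all *tested* pathways (overlap ≥
min_overlap, default 1); correcting over the full library instead is a
config switch. The universe defaults to the union of pathway members; an
explicit universe file is supported for fixed-size reference databases.
Ranking groups by pathway type when type metadata is present (overlap
descending within type), else ranks globally by overlap then q-value.

## Synthetic data generator

The generator emulates the target study design, and its defaults are the
study conditions: 10 conditions (control + {Aβ40, Aβ42, α-synuclein} ×
{monomer, oligomer, fibril}) × 3 biological × 2 technical replicates = 60
samples; 232 buckets, 80% assigned to 78 metabolites (1–4 buckets each,
giving 186 assigned buckets — one more than a 185/232 study table, a
rounding artifact of the 20% unassigned fraction); 8 key metabolites with
condition-specific fold changes drawn uniformly from 1.5–3× with random
direction per condition × metabolite; biological CV 15% (shared across a
replicate's technical pair), technical CV 2%, independent per-bucket noise
3%; per-sample dilution uniform on (0.5, 2).

Generative model, all multiplicative log-normal (intensities are
nonnegative and NMR error after normalization is predominantly
multiplicative): metabolite base ~ log-normal (median 1, log-sd 0.8);
level(sample, metabolite) = base × fold(condition) × bio effect × tech
effect; bucket = fixed proportionality constant × level × bucket noise;
unassigned buckets are independent log-normal; dilution multiplies each
row last, mirroring the physical dilution PQN targets. One seed drives
everything; identical seeds give bit-identical tables.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: peak-position drift and overlap between neighboring
metabolites, baseline and phasing artifacts, heteroscedastic noise floors,
correlated biological programs spanning many metabolites, and annotation
error. A small Lorentzian multiplet library (~15 metabolites at plausible
shifts; illustrative, not a claim about real compounds) renders full
spectra — sums of area-parametrized Lorentzians plus a TSP singlet,
optional polynomial baseline and Gaussian noise — for exercising the QC and
bucketing stages; it deliberately omits J-coupling, relaxation/CPMG physics
and shift drift. A second generator plants group structure in exactly three
latent components (two groups differing only along the weakest one) to
validate dimensionality selection.

## Pipeline determinism and problem sizes

The orchestrated pipeline runs both designs from the same normalized table,
writes every intermediate artifact as delimited or structured text, and
produces a report free of timestamps so identical configs yield
byte-identical reports; log lines carry the timestamps. Stage failures
abort with the stage name; partial outputs are retained.

Tests and the acceptance script run at the study's native scale (60 × 232
tables) with 10 replicate simulations for stochastic properties, 20
cross-validation repetitions per candidate during recovery checks, and 200
null simulations for enrichment conservativeness — sizes chosen to make the
statistical assertions stable at comfortably interactive runtimes.

## Known limitations

- No raw-FID processing (Fourier transform, phasing, baseline correction):
  spectra enter already processed, as (ppm, intensity) text.
- No automatic metabolite annotation; annotations are inputs.
- No STOCSY-style covariance spectroscopy; the correlation module works at
  bucket level only.
- Enrichment is over-representation analysis only — no topology-aware
  pathway scoring, and no KEGG/database client (the library file is an
  input).
- The equal-priors assignment assumes balanced designs; strongly unbalanced
  designs would need prior weighting that the current model does not expose.
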