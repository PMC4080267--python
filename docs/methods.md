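# Methods

## Model and procedure

The pipeline treats each modality (genotype signal, DNA methylation
signal) as a probe × sample matrix of normalized array intensities over a
paired three-class design: every subject contributes one blood, one
normal-tissue and one tumor sample, coded ordinally `y ∈ {1, 2, 3}`.
Missing measurements are carried as missing by all I/O and by the
generator; the PCA stage requires an explicit zero substitution
(`substitute_missing_with_zero`), kept as a separate, idempotent
operation so the convention is visible in analysis code.

PCA is computed by economy SVD of the probe × sample matrix,
**uncentered by default**: intensities are positive, so the uncentered
decomposition yields a dominant first component aligned with per-probe
baselines whose sample loadings are flat — a non-discriminating axis
with most of the variance, matching what large SNP arrays show — while
class-discriminating structure appears in later components. A centered
mode is available by flag. Probe scores are `U S`, sample loadings `Vᵀ`,
contributions `s_i²/Σs²`; each component's sign is fixed so its sample
loadings sum to a nonnegative value.

Which component discriminates the classes is decided by a one-way
three-class ANOVA F statistic on the sample loadings
(`rank_discriminating_pcs`). This replaces visual inspection with a
reproducible rule; an explicit PC choice (including several
(genotype PC, methylation PC) combinations per run) can always be given,
since near-degenerate components can swap roles between modalities.

"Outlier" selection is two-sided: the `N` probes with largest |score|
along the chosen component, ties broken lexicographically by probe id.
Selection membership is invariant to the component's arbitrary sign.
`N` defaults to 300; the surviving-probe ladder is reported at thresholds
50…300 because the choice of `N` is itself not sharply determined.

### Filters

* **Overlap significance.** The intersection of the two modalities'
  top-`N` sets is scored by the upper-tail hypergeometric probability
  `P(X ≥ observed)`, `X ~ Hypergeom(M, k1, k2)`, accumulated from log-pmf
  terms with log-sum-exp. Overlaps at array scale have probabilities far
  below 1e-300, so the log form is the primary quantity and the linear
  value underflows gracefully.
* **Pairwise class t-tests.** Welch one-sided tests for tumor > normal,
  tumor > blood, normal > blood (direction configurable; "increasing" is
  the default because the class means of screened probes rise from blood
  through normal to tumor). Adjustment is Benjamini–Hochberg by default,
  applied jointly across probes × 3 comparisons; Bonferroni and
  per-comparison adjustment are flags. A probe survives when all three
  adjusted P-values are below alpha in **both** modalities. Zero-variance
  probes are flagged untestable and excluded with a log entry.
* **Modality bias.** For each class, a paired one-sided t-test of
  genotype − methylation over all (probe, sample) cells of the selected
  set (unpaired Welch mode by flag). When every difference is exactly
  zero the test is defined as P = 0.5 (no evidence either way).
* **Resampling null.** Random probe subsets of the same size, drawn
  `n_iter` times (default 1000), tested per class as above, BH-adjusted
  across iterations within a class; reported as the adjusted-P range plus
  the count significant at 0.05. On bias-free data fewer than 1% of
  iterations are significant.

### Comparison selectors

Pearson and Spearman selection correlate each probe with `y` and take the
largest **signed** coefficients by default (selecting probes ordered with
the classes; an absolute-value flag exists because "largest" is genuinely
ambiguous). PLS selection fits a single-response NIPALS PLS of `y` on the
autoscaled probe matrix and ranks probes by Σ over components of
|weight| × component score variance (one component by default).
Autoscaling matters: with unscaled probes the ranking reduces to
|covariance| and favors high-variance probes regardless of label
structure, which breaks the permutation null. Stepwise-LDA and lasso
selectors are deliberately not implemented — they are not executable at
array scale — and the benchmark table reports `--` for them.

### Drug-screening statistics

Tanimoto similarity uses the strict inequality `best-over-references >
threshold` (0.25/0.20 are the conventional kinase/other cutoffs);
all-zero fingerprint pairs are defined as similarity 0. For repeated
scoring trials, the top-k commonality curve counts the **unique**
compounds in the union of the trials' top-k sets — the quantity whose
random null is `n0(k) = Nc(1 − (1 − k/Nc)^m)` for `m` independent trials,
reducing to `k[1 + (1 − k/Nc)(2 − k/Nc)]` at `m = 3`. An intersection
mode is also emitted because "selected in common" can be read either
way. Rankings over trials use best-score or mean-score aggregation, ties
by compound id.

## The synthetic-data generator

`generate_paired_dataset` emulates exactly the features the analysis
relies on, with defaults chosen once from the published intensity regime:

| parameter | default | meaning |
| --- | --- | --- |
| n_subjects | 30 | patients; 3 × 30 = 90 samples per modality |
| n_probes | 20,000 | probes per modality (desk-scale stand-in for 230–250k arrays) |
| n_signal | 100 | planted class-ordered probes |
| class_effect | (1.3, 2.4, 2.9) | planted genotype class means (blood, normal, tumor), intensity units |
| modality_offset | 0.4 | planted methylation means sit this far below genotype |
| noise_sd | 0.25 | i.i.d. measurement noise per cell |
| missing_rate | 0.002 | per-cell missingness (post-QC call rates ~99.5–99.9%) |
| baseline_mean, baseline_sd | 2.0, 0.5 | per-probe background baselines |
| subject_sd | 0.1 | per-subject offset |

Structural choices and why:

* **Baselines are shared between modalities** — the same locus read out
  on the same normalized scale. Together with subject offsets that are
  shared across a subject's tissues *and* across modalities (one
  patient's DNA feeds both assays), every systematic term cancels in
  paired genotype − methylation differences of background probes, so
  random probe subsets form a true null for the modality-bias test, as
  they must for the resampling control to be meaningful.
* **All noise is modality-specific**, so top-N selections in the two
  modalities are independent under the no-signal configuration and the
  cross-modality overlap is hypergeometric (`k²/M` expectation) — the
  null the overlap P-value assumes.
* **Wide baselines + uncentered PCA** reproduce the dominant
  non-discriminating PC1 (contribution ≳ 0.95 here; real arrays show
  ~0.8 — the generator does not attempt to match that number, only the
  dominance pattern that makes PC choice a real decision).
* Missing values are generated as explicit NaN, never zeros.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: allele-level genotype structure, probe
chemistry and normalization artifacts, linkage between probes,
non-monotone or heteroscedastic class patterns, correlated nuisance
variance components, genomic coordinates. In particular, on cleanly
planted monotone signal all selection methods (PCA-outlier, Pearson,
Spearman, PLS) saturate and recover the planted set equally well, so the
benchmark cannot reproduce the large real-data gap between the
PCA-outlier route and the supervised selectors; that gap reflects the
messier structure listed above.

`generate_rank_trials` draws each trial as
`√c · latent + √(1−c) · noise`, so the pairwise population correlation
equals the concordance parameter exactly (c = 0.95 reproduces the
">0.9 correlation" regime of a reproducible docking screen).
`generate_fingerprints` draws i.i.d. Bernoulli(density) bits.

## Numerical choices, determinism, degenerate inputs

* Hypergeometric tails via log-sum-exp over `hypergeom.logpmf`; the
  enumeration oracle in the tests validates small universes exactly.
* All randomness flows through `numpy.random.default_rng(seed)`;
  identical parameters + seed give byte-identical report bundles
  (asserted in the test suite).
* Ties anywhere (probe scores, correlations, compound scores, reference
  choices) break lexicographically by identifier.
* `N` larger than the probe count clamps with a logged warning;
  `pc_index` out of range, inconsistent overlap counts, empty probe or
  reference sets, fewer than two samples/probes, and non-rectangular TSV
  all raise with the offending field named.
* BH adjustment delegates to statsmodels and is cross-checked against a
  hand-written step-up oracle in the tests.

## Problem sizes used in the automated checks

The calibration checks run at 20,000 probes × 90 samples: 200 simulated
datasets for the null-overlap calibration, 20 for planted-signal
recovery, 1,000 resampling iterations — desk-scale stand-ins for the
230–250k-probe arrays chosen so the full suite completes in a few
minutes. Super-uniformity of the overlap P-value is tested with a
one-sided Kolmogorov–Smirnov test (empirical CDF above uniform): the
exact upper-tail P-value of a discrete count has large atoms
(P(X = 4) ≈ 0.19 at mean 4.5), so a two-sided KS would reject a provably
exact implementation on discreteness alone, while the one-sided test
rejects precisely when the P-value is anti-conservative — the claim that
matters.

## Known limitations

* The pipeline treats the two modalities' intensities as directly
  comparable; whether that holds depends on upstream normalization.
* Uncentered vs centered PCA and one- vs two-sided outlier selection are
  conventions, exposed as flags; defaults follow the dominant-PC1 and
  both-tails patterns described above.
* The discriminating-PC F ranking assumes at least two samples per class
  and can be misled when two components split the class contrast; the
  multi-combination configuration exists for exactly that case.
* No annotation, genomic-region classification, docking, or structure
  prediction: this package ends at probe sets, their statistics, and
  screening-score summaries.
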