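# Methods

## The model

The pipeline treats a bulk tumor cohort as a mixture of a small number of
immune-contexture subgroups that are visible in the expression of genes
covering the cancer-immunity cycle. Samples are observations, the registry's
panel genes are features, and the subgroups are the components of a
Gaussian mixture:

x_i | z_i = c  ~  N(μ_c, diag(σ²_c)),    P(z_i = c) = π_c,

fitted by EM on per-gene z-scores. The covariance is **diagonal** by
design: with a few hundred panel genes and ~100 samples, a full covariance
is singular; the diagonal restriction is the standard remedy and matches
the interpretation of subgroups as coordinated up/down shifts of panels
rather than as rotated ellipsoids. The number of components defaults to
k = 3 (the structure the pipeline is built to detect); a BIC scan
(`select_k`) is provided as a check, using the free-parameter count
k·d means + k·d variances + (k−1) weights.

Fitting is delegated to scikit-learn's `GaussianMixture` (best of `n_init`
EM runs by log-likelihood, seeded). Posteriors and hard assignments are
recomputed from the stored parameters by an explicit Bayes rule, so a
fitted model is a plain serializable parameter set and the assignment step
can be verified against an independent hand-coded density computation.

### Normalization chain

Clustering features are produced by log2(x + 1) followed by a **per-gene
population z-score** across samples (constant genes become all-zero).
The population (n) rather than sample (n−1) denominator is used everywhere
a z-score appears — per-gene normalization, score summaries, burden
normalization, TIC/IRP normalization — so that "mean 0, sd 1 across the
cohort" holds exactly and every z-based oracle in the test suite is
well-defined. Which scale the clustering should run on is in principle
open; log-z is the package's fixed default because it equalizes gene
scales, and the raw/log states are retained so any stage can demand the
scale it needs (CYT and the TIC/IRP geometric means require linear scale).

### Phenotype labeling

Each cluster is labeled along three immune-escape axes from its mean
z-scores over the relevant gene sets: **UB** (panel A), **IFN1** (panel B,
split into production- and signaling-tagged genes), **AP** (panel C).
For a single axis the rule is rank-based: the top cluster gets "+", the
bottom cluster "−", and middle clusters take the sign of their mean z
(zero is the cohort mean after z-scoring, so "above average" reads as
functioning). Ties break deterministically on the cluster index.

The IFN1 axis needs to say *which* arm failed. Each arm is labeled
separately with the generic rule and then combined:

- both arms "+" → `IFN1+`;
- exactly one arm "−" → that arm's letter: `IFN1p-` (production) or
  `IFN1s-` (signaling);
- both arms "−" → the arm with the larger **defect severity** — the mean
  of the other clusters' arm scores minus the cluster's own — gives the
  letter; an exact tie degrades to plain `IFN1-`.

This arm-wise formulation is deliberate. A rule based only on the combined
panel-B mean is unstable for a cluster whose production and signaling arms
point in opposite directions (its combined mean sits near zero and the
sign is noise); labeling the arms separately keeps both decisions far from
the tie region, and the severity comparison picks out the arm that
distinguishes a doubly-defective cluster from its neighbours (a cluster
that is merely *low* in production but uniquely *collapsed* in signaling
is named a signaling defect).

For reporting, clusters are renumbered so the most immune-functional
cluster (highest combined panel B+C mean) is last ("subgroup 3"), and the
remaining clusters are ordered by descending panel-A mean — the
ubiquitination-intact cluster becomes subgroup 1.

## Scores

- **Signature score**: arithmetic mean of the signature genes' expression
  on the matrix's current state; missing genes are dropped and reported.
  The bundled immune/stromal/cell-cycle sets are small generic marker
  lists — explicit replacements, not reconstructions of any published
  score's gene set — and are configurable.
- **Percentile classes**: strictly above the hi-th percentile → high,
  strictly below the lo-th → low (defaults 70/30); percentiles by linear
  interpolation between order statistics (pinned for reproducibility).
- **CYT**: geometric mean of (GZMA+1, PRF1+1) minus 1 on the linear scale.
  The pseudocount keeps zero-in/zero-out; for large values CYT+1 is
  scale-equivariant.
- **TMB**: count of {missense, truncating, inframe} records per sample
  divided by the capture size (default 30 Mb, configurable). Silent
  variants are excluded by default (configurable); amplification and
  deep-deletion records never count toward TMB but do appear in the
  mutation landscape.
- **sCNA burden**: mean |log2 ratio| over the 39 canonical chromosome arms
  (acrocentric p-arms excluded), z-scored across the cohort; per-arm
  subgroup profiles keep the sign so amplification and deletion remain
  distinguishable.
- **Subgroup summaries**: each score is z-scored across all samples and
  then averaged within subgroups, so a subgroup's value reads as "standard
  deviations away from the cohort mean".
- **TIC / IRP**: per-sample geometric means (pseudocount 1 — a single
  zero-expression gene must not annihilate the score) over the 7 TIC and
  6 IRP genes, requiring at least 4 of each to be present; normalized by
  cohort z-score ("within-cohort normalization" is read as z-score, the
  same convention as everywhere else in the pipeline; min-max is not
  offered). Quadrants: 1 = (+,+), 2 = (−,+), 3 = (−,−), 4 = (+,−) with TIC
  on the x-axis; exact zeros count as positive (documented tie rule).

## Statistics

Two-group comparisons are two-sided. "t test" defaults to Welch's
unequal-variance form (a pooled-variance flag restores the classical
test) — the robust default when the variance assumption is unstated. The
Mann-Whitney U test uses the normal approximation with tie correction when
both groups have ≥ 8 samples and otherwise a full enumeration of the rank
distribution (dynamic program without ties, explicit combinations with
midranks). The exact two-sided p-value is the null probability of a U at
least as far from n₁n₂/2 as observed; under this convention identical
groups give p = 1 and fully separated groups of three give p = 2/20 = 0.1.
For response association, NR and PD are pooled as non-responders (PR is
the positive class). Benjamini–Hochberg adjustment is available on
comparison tables but off by default, matching the convention of reporting
unadjusted p-values for descriptive subgroup contrasts.

The calibration simulations use 30-per-group normals for Welch's t and
7-per-group normals for the exact Mann-Whitney — the largest group size
routed to the exact path, where the discrete null still admits an attained
size of 3.79% (by enumeration), within the 5% ± 1.5% band the calibration
checks.

## The synthetic cohort generator

The generator emulates a ~99-sample cohort with three planted subgroups in
proportions 37/15/47. Per-gene baselines are uniform on log2 ∈ [2, 8] with
within-gene noise sd 1.0; subgroup effects are **shifts in z units applied
on the log2 scale** (high = +1, low = −1, very low = −2), so the planted
pattern is exactly what the pipeline's normalization recovers. The default
panel shifts encode the three-subgroup pattern (e.g. subgroup 2's
ubiquitination panel at −2; subgroup 1's IFN production at −1 with
signaling at +1). Gene-level overrides refine the tumor–T-cell interaction
axis, where the pattern is finer than the panel: T-cell activation markers
(PDCD1, CXCR3) are high in subgroups 2–3 while tumor-side responsiveness
(IFNGR1, CD274, CXCL9/10/11) is very low in subgroup 2 and IFNG stays low
everywhere — without these overrides a panel-level shift would plant
subgroup 2 with a *high* tumor-side IRP signal, contradicting the
structure the pipeline is meant to detect. Stromal markers are planted low
in subgroups 1–2 and high in 3; proliferation markers track the
copy-number burden (highest in subgroup 1).

Matched tables are drawn from the same memberships:

- **Mutations**: counted (nonsynonymous) loads are Poisson with
  per-subgroup means of 1.919, 2.644 and 1.700 per Mb at a 30 Mb capture;
  genes are drawn from a weighted list in which EGFR dominates, followed
  by TP53 and CDKN2A, over a large anonymous background — a qualitative
  echo of the never-smoker LUAD driver profile, with no claim of matching
  per-subgroup frequencies. Silent variants are added at 0.3× the counted
  rate; EGFR amplifications and CDKN2A deep deletions appear as
  copy-number-class records (landscape only).
- **Arm CNA**: per-arm log2 ratios ~ N(0, s_c) with s_c chosen so the
  expected |ratio| equals the per-subgroup burden targets (0.35, 0.20,
  0.20 — subgroup 1 carries the highest copy-number burden).
- **Response**: P(PR) = logistic(−1.5 + 1.5·z(TIC shift) + 1.0·z(IRP
  shift)) on the planted per-sample signature shifts; non-responders split
  evenly between NR and PD. The intercept is set so the small ICB preset
  (n = 18) produces roughly a one-third responder rate, matching the scale
  of the ICB-treated validation cohort; the positive coefficients encode
  the working hypothesis that both axes must function for response.

Everything is drawn from a single seeded generator, so identical configs
give byte-identical outputs.

**What the generator does not emulate**: gene–gene correlation beyond the
panel-block structure, library-size/compositional effects, subgroup
overlap or continuous gradients between immune phenotypes, linkage between
mutations and expression, or intra-tumor heterogeneity. Passing
planted-recovery tests therefore shows that the pipeline's inference is
correct *given* block-shift structure of the assumed magnitude, not that
three subgroups exist in any particular real cohort.

## Problem sizes and numerical choices

The recovery property is evaluated over 50 seeded cohorts of n = 99 with
the default effect sizes and n_init = 10 EM restarts; the quadrant
property over 100 seeded ICB cohorts of n = 18; test calibration over
2000 null simulations per test. EM uses reg_covar = 1e-6 and up to 500
iterations; posterior argmax ties go to the lowest component index;
constant score vectors classify as all-mid; a constant burden vector
z-scores to all-zero. Expression TSVs are written with 17 significant
digits and parsed in round-trip float mode, so write→read is bit-exact.

## Benchmarking against deposited data

The reference quantities from the deposited cohorts (subgroup sizes
37/15/47, subgroup TMB means, TIC/IRP r = 0.52 with 4/6 responders in
quadrant 1) require downloading GEO accessions GSE110907 and GSE93157 and
the full 546-gene registry file; the recipe lives in
`tests/integration_gse110907.py` and is not part of the offline test
suite.

## Known limitations

- Phenotype labeling assumes exactly the three-axis reading of the panel
  structure; with k ≠ 3 the rank rule still applies but the display
  strings lose their cohort-specific interpretation.
- The alias table is static (PD-L1→CD274 etc.); no ontology service is
  consulted.
- The full registry's 546-gene membership is user-supplied data; the
  built-in registry is a reduced stand-in sufficient for testing, not the
  published gene list.
- Survival analysis, deconvolution, neoantigen prediction and segmentation
  are out of scope; their outputs are consumed as inputs where relevant.
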