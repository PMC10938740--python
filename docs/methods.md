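# Methods

This note documents the models, defaults and numerical choices behind
`coexscreen`, and what the synthetic cohort does and does not emulate.

## Network construction

Expression enters every network step as `log2(TPM + 1)`; TPM is assumed
non-negative and finite, and missing values are a hard error (no imputation
policy is defined). Gene filtering keeps genes with TPM > 1 in strictly
more than 50% of tumor samples and with log-scale variance strictly above
the 25th percentile (linear-interpolation quantile) of the variances of the
genes passing the first gate.

The network is unsigned: `a_ij = |pearson cor|^β`. β is scanned over 1..20;
for each power the connectivity distribution is binned into 10 equal-width
bins and the scale-free fit index is `−sign(slope)·R²` of
`log10 p(k) ~ log10 k` — positive when the degree distribution decays, the
direction a scale-free network has. The chosen power is the smallest with
index ≥ 0.8, else the argmax. Fewer than 30 genes or 20 samples triggers a
warning: the binned fit is unstable there.

Topological overlap uses the standard formula with `L_ij = Σ_{u≠i,j} a_iu a_uj`
and a unit diagonal; the degenerate isolated-pair case (zero denominator)
is defined as overlap 1. The implementation is a matrix product with the
diagonal zeroed, which equals the triple loop exactly (tested to 1e-12).

**Tree cut.** Modules are extracted from average-linkage clustering of
`1 − TOM`. A fixed cut height cannot work in general: diffuse background
genes coalesce continuously just below the tree root, so any single height
either leaves everything in one cluster or shatters the tree. The cut
height is therefore chosen adaptively: among all merge heights at or below
`cut_height` (default 0.995), the one that maximises the number of clusters
with at least `min_module_size` (default 30) genes, ties resolved toward
the higher height (most inclusive membership; `deep_split ≥ 3` flips the
tie toward finer splits). Undersized clusters are unassigned (label 0), and
unassigned genes are re-admitted to the module with the highest mean TOM
when that mean exceeds the module's median within-module TOM (the PAM-like
stage). Labels are renumbered by decreasing size. This is a documented
simplified hybrid of dynamic tree cut, validated by planted-partition
recovery rather than label-for-label agreement with the reference
implementation.

**Eigengenes.** Per module, each gene's log profile is standardised (mean
0, sd 1, ddof 1) and the eigengene is the first right singular vector,
rescaled to unit sample variance and sign-oriented to correlate
non-negatively with the module's mean standardised profile. Modules whose
eigengenes satisfy `1 − cor < 0.25` are merged greedily (closest pair
first, eigengenes recomputed after each merge, fixpoint stop). Module
membership kME is the Pearson correlation of a gene's log profile with an
eigengene; the hub of a module is its member with maximal kME, ties broken
lexicographically and flagged.

## Deconvolution

The signature matrix is the per-cell-type mean of reference profiles on
the genes shared with the bulk, optionally restricted to top-k fold-change
markers. Proportions solve a per-sample NNLS on the linear TPM scale
(mixing is linear in molecule counts) and are renormalised to the simplex;
`inverse_variance` weighting (1/sd of a gene across the signature's types)
is available but off by default. Cross-subject variance modelling of full
deconvolution frameworks is intentionally out of scope: the screen needs
composition covariates with the right structure, not state-of-the-art
deconvolution accuracy. Only the first T−1 of T proportion columns enter
any regression design (the simplex makes all T collinear with the
intercept).

## Differential methylation

Per CpG, a two-sample t test on beta values with empirical-Bayes variance
moderation: pooled variance `s²` with `d = n₁ + n₂ − 2` degrees of freedom
is shrunk to `(d₀·s₀² + d·s²)/(d₀ + d)` with the prior strength fixed at
`d₀ = 4` and `s₀²` the cross-CpG mean of `s²`; the t statistic is referred
to `d₀ + d` degrees of freedom. Full estimation of the prior (as limma
does) is deliberately not attempted — the fixed-d₀ form is documented,
reproducible, and calibrated under the null in the test suite. A CpG is
differentially methylated when `|Δβ| > 0.2` (mean tumor − mean normal) and
BH FDR < 0.05; both gates are strict inequalities.

## The eigengene–CpG screen

For every (cluster i, DM CpG j) pair an OLS fit of
`EG_i ~ 1 + β_j + proportions(T−1) + EG_{k≠i}` is computed via the
Frisch–Waugh decomposition: the covariate block is orthogonalised once per
cluster (QR), after which every CpG slope, its t statistic (df = n −
covariates − 2) and two-sided p-value follow from one residual-on-residual
regression. This equals the full normal-equations fit to 1e-8 (tested).
CpG values enter as beta by default (`use_m_values` converts to
`log2(β/(1−β))` with clipping at 1e-6). p-values are BH-corrected within
each cluster's family; a CpG is assigned to the cluster with the smallest
FDR among those below α = 0.05, ties broken by larger |slope| then smaller
cluster id, so no CpG is ever reported under two clusters. The regression
direction (eigengene as response, CpG as regressor) follows the screen's
definition even though the causal arrow is debatable.

Two caveats are worth knowing. First, the covariates remove composition
confounding and cross-cluster sharing, but *not* tumor status: a CpG and an
eigengene that both shift between tumor and normal will associate through
that common cause. This is a real property of the design, visible on the
synthetic cohort as extra (truthfully tumor-coupled) assignments to the
DE-shifted module. Second, detected eigengenes of composition-driven gene
blocks (cell-type marker modules) act as additional, partially redundant
composition covariates; this is harmless but slightly inflates the design.

## Chromosomal instability

A segment is altered when |log2 ratio| strictly exceeds 0.3. Per sample
and chromosome, altered base pairs are the length of the *union* of
altered intervals (raw sums could exceed the chromosome after
re-segmentation); the CIN index is the unweighted mean over every
chromosome of the genome model of (altered bp / chromosome length), with
segment-free chromosomes contributing 0, hence CIN ∈ [0, 1]. Chromosomes
are equally weighted, not length-weighted — the literal reading of an
average across chromosomes — and whether sex chromosomes participate is
decided by what the caller lists in the genome model. The association step
is OLS of CIN on each eigengene plus composition covariates, two-sided t
on the slope, BH across clusters.

## Enrichment

The tumor/normal ranking uses Welch t statistics on `log2(TPM+1)`
(descending, ties by gene id), alongside logFC and BH FDR so the
conventional DE gate (|logFC| > 0.5, FDR < 0.05) can be applied by
callers. GSEA is the weighted KS running sum (hit steps `|stat|^p`
normalised to 1, default p = 1; miss steps `1/(N − N_h)`), with a seeded
gene-label permutation null (default 1,000 draws): NES divides ES by the
mean |null ES| of matching sign, and the nominal p is the add-one-corrected
fraction of same-sign null scores at least as extreme. Gene-label (rather
than phenotype) permutation is chosen for desk-scale determinism; its known
caveat — inter-gene correlation inflates significance for co-expressed
sets — applies to module gene sets and is why selection never rests on
GSEA alone. Fisher tests use the conventional two-sided
probability-mass-summation p; the odds ratio gets a Haldane 0.5 correction
(flagged) only when a cell is zero, leaving p untouched. CpG–interval
overlap is half-open (`s ≤ pos < e`); promoter/distal classification uses
distance ≤ 2 kb to the nearest TSS (the window is a config knob; no
standard definition is assumed).

## Selection rule and orchestration

A module is selected when (1) its GSEA FDR < 0.05 with the configured
direction (default: enriched among tumor-down genes), (2) at least 10 DM
CpGs are uniquely assigned to it, and (3) its CIN FDR < 0.05. The CpG
count threshold is an artifact-scale knob with no canonical value; all
three thresholds live in `ScreenParams`. Reports carry a SHA-256 hash of
the full parameter set, so two runs differing in any threshold differ in
provenance. Given a seed the pipeline is deterministic.

## Synthetic cohort

Defaults (the package's study conditions): 150 tumor + 50 normal samples;
5 modules of 150/120/90/70/50 genes among 2,000; module 1 carries a
log2-scale tumor down-shift of 1.0, the CIN link, and — like every
module — 10 linked CpGs; 1,000 CpGs total; 3 cell types with Dirichlet(3,3,3)
proportions and 30 exclusive marker genes each.

* Module-gene expression: `log2(TPM+1) = μ_g + w_g·E_m + c_g·(u_m·Δprops)
  + shift·1[tumor] + ε`, with eigengene truths `E_m` i.i.d. standard normal
  per sample (the minimal structure weighted co-expression analysis
  assumes), loadings `w_g` uniform in 0.6–1.4 of the module effect sd
  (default 1.0), residual sd 0.6, and a shared per-module composition
  direction scaled by `module_composition_sd` (default 0.5 — minor leakage,
  since marker genes model the strong composition signal separately).
* Marker genes mix the reference mean profiles linearly in the true
  proportions (±5% multiplicative noise), making deconvolution well-posed.
* Methylation is generated on the logit scale and mapped through the
  sigmoid, so betas are in [0, 1] with no truncation artifacts. Every CpG
  carries a composition term (`composition_confound_strength`, default 2);
  linked CpGs add `cpg_effect·E_m` (default 1.0) and a logit tumor shift
  (default +1.5, so they pass the |Δβ| > 0.2 gate, hypermethylated); 10%
  of unlinked CpGs get the tumor shift only — differentially methylated
  but linked to no module.
* True CIN is `clamp(0.05 + 0.4·standardised E_cin + ε, 0, 1)` (sd 0.05)
  when linked, independent noise otherwise. Note the clamp left-censors
  roughly the lower half of samples at 0; the association remains strongly
  detectable at n = 200. Segments realise each sample's target: per
  chromosome a fraction with exact mean equal to the target, split into
  1–3 non-overlapping pieces placed with multinomial gaps, amplitudes
  `±(0.35 + Exp(0.3))` so every segment exceeds the 0.3 alteration
  threshold; the recomputed index matches the target to well within ±0.01
  (rounding only).

What the generator does **not** emulate: read-level noise, array probe
chemistry, copy-number dosage effects on expression, batch structure,
correlated eigengenes, or realistic effect-size distributions (values are
chosen for testability). Passing recovery tests therefore demonstrates the
pipeline's correctness and its behaviour under the stated statistical
structure — not performance on real cohorts.

## Problem sizes in tests

The default cohort (above) drives the planted-recovery and end-to-end
tests; null calibrations use 20 seeds of reduced designs (120–150 samples,
150–200 CpGs, 5 eigengenes) and the end-to-end false-positive control runs
10 full null cohorts; the acceptance script mirrors these at 10 and 5
seeds respectively. All are desk-scale choices that keep the whole suite
in the low minutes on one CPU.

## Known limitations

* The tree cut is a simplified hybrid; pathological dendrograms (nested
  tight blocks) may split differently from the reference implementation.
* Gene-label GSEA p-values are anti-conservative for strongly co-expressed
  sets (see above).
* Tumor status is not a screen covariate (by design, matching the screen's
  definition); tumor-coupled CpGs associate with tumor-shifted modules.
* The moderated test fixes the prior strength instead of estimating it.
* Exact sample-id equality is required across layers; no barcode fuzzy
  matching.
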