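# Methods

## The problem

A bulk methylation profile is, to good approximation, a convex combination
of the profiles of its constituent cell compartments. In buccal and
cervical samples the dominant axis is epithelial vs immune content; in
blood it is lymphoid vs myeloid. An exposure such as cigarette smoking can
alter methylation in one compartment and not another, and differences in
cell composition between groups can both create spurious bulk-level
associations and mask real compartment-level ones. All of the machinery in
this package exists to (a) detect smoking-associated CpGs while adjusting
for composition, (b) attribute each association to a compartment, and
(c) score samples in a way that is invariant to their composition.

## Mixture model and notation

For sample *i* with mixing-compartment proportion *f_i* (immune proportion
in buccal/cervical, lymphoid proportion in blood) and CpG *j*:

    E[beta_ij] = f_i * mu_mix,j(t_i) + (1 - f_i) * mu_other,j(t_i)

where *t_i* is the sample's smoking type and mu_c,j(t) the pure-compartment
mean. Observed values add measurement noise:
beta_ij ~ Beta(m_ij * kappa, (1 - m_ij) * kappa), i.e. mean m_ij and
concentration kappa. The beta family is used because methylation fractions
are bounded; a clipped Gaussian would distort means near 0/1 and break the
mixture identity the estimators rely on.

Because E[beta] is linear in *f* within a smoking group, a per-group least
squares line of beta on *f* evaluated at *f* = 0 estimates
mu_other(t) and at *f* = 1 estimates mu_mix(t). Differences between the
current-smoker and never-smoker lines at those endpoints are the
compartment-specific effect estimates:

    delta_beta(0) = intercept_current - intercept_never
    delta_beta(1) = (intercept + slope)_current - (intercept + slope)_never

This identity is exact for noiseless data (tested to 1e-12) and unbiased
under the noise model; its variance is the usual OLS extrapolation variance
sigma^2 (1/n + (x0 - f_bar)^2 / Sxx), which grows with the extrapolation
distance — see Limitations.

## Synthetic cohort generator

The generator is first-class, tested code, and its ground-truth ledger
(per-CpG compartment means for every smoking group, per-sample true
fractions, per-CpG archetype and delta-beta) is the oracle for the
parameter-recovery tests.

Archetype effect patterns (effect size *e*, default 0.2 on the beta scale):

| archetype | buccal epi | buccal imm | cervical epi | cervical imm | blood lym | blood mye |
|---|---|---|---|---|---|---|
| epithelial_hypoM | −e | 0 | −e | 0 | 0 | 0 |
| immune_hypoM | 0 | −e | 0 | −e | −e/2 | −e |
| distal_epithelial_hyperM | 0 | 0 | +e | 0 | 0 | 0 |
| proximal_epithelial_hyperM | +e | 0 | 0 | 0 | 0 | 0 |
| null | 0 | 0 | 0 | 0 | 0 | 0 |

The blood lymphoid share of the immune effect (default 0.5 of the myeloid
magnitude) reflects that myeloid cells carry the stronger smoking signal;
it is configurable but always ≤ the myeloid magnitude.

Key parameters and defaults:

- **n_cpgs = 500**, 100 per archetype including null; **seed** drives a
  hierarchical stream per (tissue, stage), so enlarging one tissue's cohort
  does not perturb another's draws.
- **effect_size = 0.2** beta-scale units; baseline compartment means are
  bimodal over (0.05, 0.95) (mixture of scaled Beta(2,8) and Beta(8,2)),
  with the support of affected compartments shrunk so the programmed effect
  always fits inside (0, 1); a config whose effect cannot fit is rejected
  with the offending CpG/tissue/compartment named.
- **noise_precision kappa = 200** (SD ≈ 0.03 at mid-range, matching typical
  array replicate noise); `None` switches noise off for exactness tests.
- **fraction distributions**: buccal immune ~ Beta(2,6)
  (epithelial-dominant swabs), cervical ~ Beta(3,4), blood lymphoid ~
  Beta(5,5); chosen to span realistic composition ranges for each tissue.
- **n_samples = 150 never + 150 current per tissue** (the reference
  conditions of the test suite; all sizes configurable per tissue and
  smoking type). Sex is "F" throughout, mirroring a female discovery
  cohort; age ~ U(18, 70) affects nothing by default (an optional
  age_slope exists to exercise covariate adjustment).
- **ex-smokers**: mu(ex) = mu(never) + (1 − attenuation)·delta, attenuation
  default 0.7. Reversal kinetics after quitting are not quantitatively
  established, so attenuation is a free parameter, not a claim.
- **dose response**: for current smokers, delta_ij = delta_j +
  dose_slope·pack_years_i in affected compartments (signed convention: a
  negative slope deepens hypomethylation with cumulative dose). Default 0,
  so the ledger's delta is exact; the dose-correlation tests enable it.

What the generator deliberately does **not** emulate: array chemistry
(detection p values, dye bias), probe-level artifacts, SNP-driven
trimodality, batch effects, and — importantly — per-sample biological
variability of scores beyond measurement noise. Passing tests therefore
demonstrate correctness of the estimators under the mixture model, not
robustness to every feature of real cohort data.

## Stage-by-stage choices

**Deconvolution.** Non-negative least squares per sample against the
reference, followed by sum-to-one renormalisation. This matches the
contract of reference-based estimators used in practice while being simple
enough to verify exactly: noiseless mixtures of the reference columns are
recovered to machine precision, and duplicated reference rows or permuted
columns provably change nothing. A Huber-weighted IRLS variant is available
(`robust=True`, default off). Pure samples (all weight on one compartment)
are legal. Two-level estimation fits the immune subtypes jointly with the
non-immune level-1 compartments (so epithelial signal cannot leak into
subtype weights), normalises the subtype shares, and rescales them to the
level-1 immune total. Externally computed fractions can be supplied as a
file to bypass the stage entirely. Where a tissue reference includes a
fibroblast compartment, the immune proportion is taken as immune over all
estimated compartments (the alternative, renormalising over
epithelial + immune only, is a one-line change at the call site).

**EWAS.** OLS of beta on {intercept, current-smoker indicator, age,
composition covariate}, with an extensible extra-covariate list (default
none). Ex-smokers and alternative exposures are excluded at discovery.
P values use the t distribution with residual degrees of freedom — at the
default n = 300 this is nearly normal, but it matters at the small n the
unit tests use. The implementation solves all CpG rows sharing the design
in one vectorised pass (pseudo-inverse once, per-row residual variance);
rows with missing betas fall back to complete-case per-row fits with n
recorded. Constant rows are flagged and given p = 1. Collinear covariates
raise an error naming the offending pair. Holm step-down adjustment is
applied per tissue (statsmodels backend; an exhaustive step-down oracle
verifies it in tests); significant sites are the union of Holm-significant
CpGs across tissues, with chrX/chrY sites dropped only when a chromosome
annotation is supplied. A genomic-inflation factor (median chi-square
ratio) is reported per run; it is ~1.00 on all-null simulations. No
genomic-control correction is applied.

**Delta-beta.** Unweighted OLS per group (no heteroskedasticity
weighting), minimum 20 samples per group and minimum composition spread
0.2 — extrapolating to *f* = 0/1 from a narrower range is statistically
fragile, and the fit refuses rather than returning a silently unstable
number. Blood mirrors the buccal/cervical procedure exactly with lymphoid
proportion as the covariate, so *f* = 1 yields the lymphoid and *f* = 0 the
myeloid estimate. Reported values are clipped to [−1, 1]; the unclipped
estimate and a delta-method SE (sqrt of the two intercept variances) are
retained. Missing tissues yield missing-flagged columns.

**Clustering.** Agglomerative Ward/Euclidean on the six-column delta-beta
matrix, k = 4 by default (k selected by silhouette over 2..8 with
`--auto-k`). No feature scaling — all columns share the delta-beta scale.
Missing entries are imputed as 0 ("no evidence of effect") and flagged.
Rows are sorted lexicographically by CpG id before clustering and cluster
ids renumbered by smallest member, making the result independent of input
order. Labelling is rule-based on cluster means with tolerance tau = 0.02:
an archetype requires its affected compartments to exceed tau in the right
direction and all others to stay within tau; anything else is "unlabeled",
and two clusters matching one archetype keep both with a numeric suffix
and a warning. k = 1 is allowed (single cluster, mean profile = column
means).

**Scoring.** The raw score is the mean beta over the set members present
(missing members skipped; per-sample coverage reported). The correction
fits one line per smoking type — type-specific slopes exactly as the
procedure is defined, with the documented consequence that correcting a
new sample requires a labelled cohort to fit its type's line; a cohort
lacking a fitted type is refused rather than borrowing another type's
line. The target proportion comes from the set's compartment (epithelial
sets → *f\** = 0, immune sets → *f\** = 1). Corrected values are **not**
clipped to [0, 1] (clipping would break the linear contract that corrected
scores are composition-independent within type); out-of-range values are
flagged. Correction fitting needs ≥ 10 samples per type and spread ≥ 0.1 —
laxer than the delta-beta thresholds because scores average many CpGs and
their lines are far less noisy.

**Evaluation.** AUC is the Mann–Whitney probability with ties counting
half, verified against literal pair enumeration. The DeLong CI uses the
placement-value variance (per-case and per-control structural components)
with a normal quantile, on the AUC scale without logit transform, clipped
to [0, 1]; perfect separation collapses the CI with a warning. Monte-Carlo
coverage at nominal 95% measures 94.7% (1,000 replicates, n = 50/50, true
AUC 0.75). Rank tests are two-sided Wilcoxon: exact enumeration for small
untied samples, normal approximation with tie correction otherwise;
identical paired samples return p = 1 by convention. Dose correlation
defaults to Spearman (no linearity assumption between score and
pack-years) with Pearson as an option. Evaluation statistics are
descriptive: no multiplicity correction is applied and raw p values are
reported as such.

**Pipeline.** Stages hand off exclusively through files in a run
directory, so each stage is independently testable, replaceable and
diffable; a manifest records the seed, per-stage row counts and wall
times, SHA-256 hashes of every output, and all warnings raised. Reruns
with the same seed reproduce byte-identical outputs.

## Numerical conventions

- Degenerate designs fail loudly: constant composition within a group,
  too-few samples, collinear covariates, rank-deficient references and
  empty CpG sets all raise with context, never return NaN silently.
- Tie-breaks are deterministic everywhere (stable sorts; reference CpG
  selection orders by descending discriminability then CpG id; cluster ids
  by smallest member).
- All randomness flows from one integer seed through named generator
  streams; no global RNG state is used.
- Beta means are clipped to [1e-6, 1 − 1e-6] before beta-noise sampling to
  keep the distribution parameters valid.

## Known limitations

- **Extrapolation variance.** The delta-beta and corrected-score estimates
  at *f* = 1 from an epithelial-dominant tissue (buccal f_bar ≈ 0.25)
  carry ~5× the variance of the *f* = 0 estimates; with 150 samples per
  group the per-CpG SE at *f* = 1 is ≈ 0.018. Extremes over hundreds of
  null CpGs therefore reach ~0.05–0.07 even when everything is working
  correctly. Single-CpG delta-beta values near the immune end should be
  read with their reported SEs.
- **Corrected-score group differences at the far compartment** inherit the
  same sampling noise: because the generator has no per-sample biological
  score variance, the AUC of a corrected-to-immune epithelial signature is
  unbiased around 0.5 but fluctuates substantially between cohorts
  (SD ≈ 0.18 at these conditions). On real data, biological variance
  within type damps this; on the synthetic model it does not.
- **Errors-in-composition attenuation.** Feeding deconvolution-estimated
  (rather than known) fractions into the extrapolation attenuates slopes
  and inflates delta-beta error (measured buccal epithelial RMSE 0.056 vs
  0.013 with known fractions at the reference conditions). The recovery
  guarantees in the tests are stated for known fractions; with estimated
  fractions they degrade in proportion to the fraction error.
- No per-immune-subtype delta-beta is attempted (the two-compartment
  extrapolation does not identify subtype effects), no IDAT/array
  preprocessing, no enrichment analysis, and no survival or
  logistic-regression modelling.
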