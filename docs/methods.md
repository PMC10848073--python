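# Methods

## Problem and data model

The package operationalizes a 12-gene whole-blood RT-qPCR panel for
predicting glucocorticoid (GC) resistance in relapsing MS. A patient's
measurement is the relative expression `Ct_gene / Ct_ACTB` per panel gene
(unitless, positive; an inverse-abundance scale since lower Ct means more
transcript). Technical replicates are collapsed by the mean of their Ct
values before normalization (median available); whether to average before
or after taking the ratio is not standardized in practice — averaging Ct
first is the common convention and the difference is second-order for
triplicates. A patient missing any panel gene is excluded from composite
scoring (complete-case) and the exclusion is reported; partial scores are
not defined.

## ROC conventions

Candidate thresholds are the distinct observed marker values, with
inclusive positivity (`≥ t` under higher-positive orientation, `≤ t` under
lower-positive), plus a degenerate all-negative sentinel so the curve spans
(0,0)–(1,1). Midpoint thresholds between consecutive observations (an SPSS
convention) are deliberately not used: the panel's scoring rules are stated
against the cutoffs themselves, and the packaged reference cutoffs are
consumed as given. AUC is the tie-corrected Mann–Whitney statistic
(half-credit for ties); a gene's direction is "up" iff AUC > 0.5 in the
higher-positive orientation, ties breaking to "up".

Cutoff selection under a specificity floor maximizes sensitivity subject to
`specificity ≥ floor` (default 0.80); ties break toward higher specificity,
then toward the more extreme threshold. The floor is the only published
constraint; maximizing sensitivity under it is our choice, since any other
rule discards attainable sensitivity. If no threshold qualifies with
positive sensitivity, the degenerate all-negative point is returned with a
warning rather than an error.

## Composite score and score classifier

Up-genes score 1 at `ratio ≥ cutoff`, down-genes at `ratio < cutoff` — the
asymmetric inclusivity is preserved exactly as specified by the panel's
scoring rule. The score is the sum of the 12 bits. The score classifier
re-runs constrained ROC selection on the integer score. A legacy
real-valued cutoff c (the panel's published 8.8) is applied as
`score ≥ ceil(c) = 9`: scores are integers, and a non-integer published
cutoff most plausibly reflects a reporting convention between achieved
score levels. The published score-level sensitivity of 35% is likewise not
expressible as k/16 for 16 resistant patients, suggesting the original ROC
may have been computed on replicate-level rather than patient-level data;
this package computes and reports patient-level values.

## Synthetic cohort generator

Study conditions emulated: a pooled two-center relapse cohort of 31
GC-sensitive (10 discovery + 21 replication) and 16 GC-resistant (15 + 1)
patients — these are the generator defaults — with covariate marginals
matching the published baseline table (age and disease duration as
truncated normals on the printed mean/min/max with sd = range/4; EDSS on a
0.5-step grid centred on the printed median; GC dose truncated normal in
mg; immunotherapy multinomial from the printed counts; sex Bernoulli at the
printed female fraction; center assignment at the printed per-group
proportions). No covariate–expression dependence is induced because none is
published.

Expression uses a one-factor Gaussian latent-liability model per gene,

    Z_ij = δ_j·1[resistant] + λ·L_i + √(1−λ²)·ε_ij ,

calibrated in closed form: with target firing rates (r_res, r_sens) for
gene j's indicator, the threshold is t_j = −Φ⁻¹(r_sens) and the shift
δ_j = Φ⁻¹(r_res) − Φ⁻¹(r_sens). The marginal variance is 1 in both groups
for every λ, so the calibration is exact (to 1e−10 analytically) for any
loading. An affine map with slope `scale` (default 0.1 ratio units per
latent SD, keeping values in a realistic 0.5–2.5 band around the cutoffs
and strictly positive) places the indicator boundary exactly at the
published cutoff, oriented so that the ≥/< scoring rules recover the latent
indicator. Degenerate target rates (0 or 1) become deterministic point
masses one `scale` away from the cutoff, with a warning.

**Rate interpretation.** The published per-gene sensitivity / 1−specificity
columns are ambiguous for down-genes: read in a fixed
higher-ratio-positive orientation they must be complemented to give the
firing rates of the `ratio < cutoff` indicator (`complement`, the default),
or they may already be the down-oriented rates (`as_printed`). Under
`as_printed` the expected resistant score is ≈3.7 of 12, which is
incompatible with a published score cutoff near 9 carrying 35% sensitivity;
under `complement` the expected scores are 8.42 (resistant) and 6.53
(sensitive), consistent with that cutoff. Both modes are exposed;
`complement` is the default.

**Loading λ** (default 0.3) is a free realism knob, not a published
quantity: 0 gives independent genes (the Poisson-binomial oracle regime),
larger values induce the positive inter-gene correlation expected of
co-regulated blood transcripts and widen the within-group score
distribution (variance is non-decreasing in λ, verified by simulation).
0.3 gives mild correlation without degenerating the score distribution.

**What the generator does not reproduce.** It matches the published
per-gene *operating points* (exceedance rates at the cutoffs), not the
published per-gene AUCs or the full marker distributions — a two-point
constraint cannot pin a whole curve, and for several down-genes the printed
operating point and printed AUC are mutually inconsistent under any
location-shift model. Consequently the published headline numbers (score
AUC 0.913, 84%/35% at ≥8.8, per-gene AUCs, DEG counts) are context, not
targets: passing tests show the machinery is correct and calibrated to the
operating points, not that real blood samples would reproduce those
figures. Replicate-level Ct noise, plate effects, and treatment dynamics
are out of scope.

## Statistics

Baseline comparisons: Pearson chi-square without continuity correction
(matches the published sex p-value of 0.91 on the printed counts) and
two-sided Mann–Whitney U (exact enumeration for combined n ≤ 12 without
ties, normal approximation with tie correction otherwise). The logistic
model is fit by maximum likelihood (Newton/IRLS via statsmodels) with Wald
95% CIs — the SPSS default this mirrors. Encoding is fixed for
reproducibility: female = 1, immunotherapy ordinal 0/1/2 (none /
mild-to-moderate / high efficacy; a single ordinal covariate because the
published model reports one odds ratio for it), GC dose in mg unscaled,
center binary (Bern = 1). The center-adjusted model includes all other
covariates plus center. Perfect separation and collinearity raise explicit
diagnostics; non-convergence is never returned silently.

The differential-expression stage is a generic re-implementation: per-gene
Welch t-tests on log-scale expression with Benjamini–Hochberg adjustment
and a volcano rule (|logFC| > 0.5 — read as log2, the volcano-plot
convention — and adjusted p < 0.05, strict inequalities). The commercial
engine originally used for this step is unspecified upstream, so published
DEG counts are not reproduction targets. The panel prefilter keeps genes
with transcriptomic AUC > 0.86 or < 0.14 (strict) and then drops
non-protein-coding genes, reporting counts at each step.

## Numerical choices and problem sizes

Poisson-binomial pmfs by O(n²) convolution (exact; cross-checked against
full 2¹² enumeration). Calibration checks run at n = 5000/group (Monte
Carlo standard-error bands at 3σ); logistic parameter recovery at n = 5000
and CI coverage over 200 replicates of n = 2000 — sizes chosen so
simulation error is well inside the assertion bands while the full suite
stays fast. Seeds are explicit everywhere; identical configs give
byte-identical cohorts.

## Known limitations

- The tie-corrected score AUC is not monotone under adding a weakly
  informative gene (the exact augmentation identity in the test suite shows
  the tie terms can dominate), so panel growth is not automatically
  beneficial under independence.
- The generator's covariates are marginally calibrated only; joint
  covariate structure (e.g. EDSS-dose dependence) is not modeled.
- Complete-case scoring can bias operating points if missingness correlates
  with resistance; the pipeline reports exclusions so this is auditable.
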