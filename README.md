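# gcpanel

Predicting glucocorticoid (GC) resistance in multiple-sclerosis relapse from
a 12-gene whole-blood expression panel.

High-dose GC pulses are first-line treatment for MS relapses, but a sizable
minority of relapses do not respond (no EDSS improvement four weeks after at
least one pulse). `gcpanel` implements a transcriptomic decision rule for
flagging those GC-resistant relapses early, built from RT-qPCR expression of
twelve genes (*PGAP3, LDLRAP1, SNPH, DDX54, ABHD8, FASN, SNX2, RHOT1, EAF2,
ANXA1, AIM2, N4BP2L2*) normalized against the housekeeping gene ACTB.

## The method

1. **Normalization** — relative expression is the cycle-threshold ratio
   `Ct_gene / Ct_ACTB` (technical replicates averaged first). Lower Ct means
   higher abundance, so the ratio is an inverse-abundance scale; all cutoffs
   live on this measured scale.
2. **Per-gene binarization** — each gene has a ROC-derived cutoff chosen
   under a specificity floor (spec ≥ 0.80). Genes up-regulated in
   GC-resistant relapse score 1 when `ratio ≥ cutoff`; down-regulated genes
   score 1 when `ratio < cutoff`.
3. **Composite score** — the sum of the twelve indicator bits,
   `S = Σ_j 1[gene j on its resistance side] ∈ {0, …, 12}`.
4. **Score classifier** — `S` is itself thresholded by ROC analysis under
   the same specificity floor; AUC is the tie-corrected Mann–Whitney
   statistic `U/(n₁n₂)`.
5. **Adjusted model** — logistic regression of resistance on the score,
   adjusted for age, sex, disease duration, immunotherapy class, EDSS prior
   to GC, GC dose, and optionally recruitment center (maximum likelihood,
   Wald 95% CIs).

Because no patient-level data is publicly deposited for this panel, the
package includes a **synthetic cohort generator**: a one-factor Gaussian
latent-liability model calibrated in closed form (probit) so that every
gene's indicator fires at the published operating-point rates in each group,
with a tunable shared loading λ that induces realistic inter-gene
correlation. An exact Poisson-binomial oracle gives the independence-model
score distribution for cross-checks.

The package is organized as scikit-learn estimators —
`PanelBinarizer` (transformer) and `CompositeScoreClassifier`
(fit/predict) — over a functional core (`roc`, `scoring`, `stats`, `de`,
`simulate`, `qpcr`), with a `gcpanel` CLI for end-to-end runs.

## Worked example

```python
from gcpanel import (GeneratorConfig, generate_cohort, CompositeScoreClassifier,
                     load_reference_panel)

panel = load_reference_panel()                      # 12 genes, fixed cutoffs
cov, expr, labels = generate_cohort(GeneratorConfig(seed=1), panel=panel)
clf = CompositeScoreClassifier(panel=panel).fit(expr, labels)
print(clf.score_cutoff_, clf.sensitivity_, clf.specificity_, round(clf.auc_, 3))
```

```
9.0 0.625 0.8064516129032258 0.852
```

On this synthetic 47-patient cohort (31 GC-sensitive, 16 GC-resistant) the
selected rule is *score ≥ 9*: it flags 62.5% of the GC-resistant relapses
while keeping specificity at 80.6% (the floor), and the composite score
separates the groups with AUC 0.852. The same run from the shell:

```bash
gcpanel run --out-dir demo_run --seed 1
# cohort n=47; score cutoff >= 9: sensitivity 0.62, specificity 0.81, AUC 0.852
```

writes `report.json` / `report.md` with per-gene operating points, the score
distribution per class, baseline statistics, and both adjusted logistic
fits. Other subcommands: `simulate`, `normalize`, `score`, `stats`, `fit`.

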