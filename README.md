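# scmetland

Single-cell metabolic landscape analysis for tumor/normal cohorts, built
around the questions a retinoblastoma metabolic study asks of its data:
which cell types run which metabolic programs, which genes drive
metabolic heterogeneity, how tightly glycolysis tracks hypoxia, and
whether a transporter's immunohistochemical expression associates with
clinicopathological risk features.

The single-cell stages operate on gene × cell TPM matrices with per-cell
annotations (sample, tissue group, cell type) and KEGG-style metabolic
gene sets in GMT format; the clinical stage operates on per-patient
immunohistochemistry scores. A synthetic-data module plants known
effects — cell-type pathway programs, expression-dependent dropout, a
latent hypoxia factor, cohorts with exact contingency margins — so every
stage is testable without any data download.

## The statistics at the core

With expression quantified as log2(TPM+1), cell types with fewer than
50 cells removed, and technical zeros optionally imputed (each filled
entry is flagged):

- **Relative expression.** For gene *g* and cell type *t*,
  *r₍g,t₎ = E₍g,t₎ / mean₍t′₎ E₍g,t′₎*, where *E* is the mean expression.
  *r* is centred at 1 (no type specificity).
- **Pathway activity.** For pathway *p*,
  *PA₍p,t₎ = Σ₍g∈p₎ w₍g₎ r₍g,t₎ / Σ₍g∈p₎ w₍g₎*, with weights
  *w₍g₎ = 1/(number of metabolic pathways containing g)* and per-pathway
  Tukey-fence outliers excluded. Significance: shuffle the cell-type
  labels, recompute, and report the add-one two-sided p-value on
  |PA − 1|.
- **PCA variability score.** *s₍g₎ = Σ₍c₎ |loading₍g,c₎|* over the
  minimal prefix of components explaining >80% of variance (imputed
  entries excluded pairwise from the covariance); genes ranked by *s₍g₎*
  feed a preranked GSEA with the weighted Kolmogorov–Smirnov running
  sum (hit steps ∝ |score|ᵖ, miss steps 1/(N−N₍hit₎)).
- **Signature scores.** Per-cell hypoxia/glycolysis/OXPHOS scores as
  the mean of per-gene z-scores, correlated per cell type (Spearman by
  default).
- **IRS and association.** Immunoreactivity score = staining intensity
  (0–3) × percent-positive grade (1–3); high iff IRS ≥ 4. Each binary
  clinical feature vs the high/low class is tested with a two-sided
  Fisher's exact test (point-probability convention, log-space exact
  summation).

## Worked example

`examples/04_clinical_association.py` rebuilds a 47-patient MCT1
immunohistochemistry cohort from its published 2×2 margins and tests
each clinicopathological feature:

```
cohort: 47 patients, 36 high / 11 low (76.6% / 23.4%)

                  feature  yes_high  yes_low  no_high  no_low  odds_ratio  p_value  significant
                 sex_male        19        3       17       8    2.980392 0.178875        False
                age_le_2y        16        6       20       5    0.666667 0.732232        False
           uveal_invasion        12        2       24       9    2.250000 0.464312        False
     optic_nerve_invasion        25        2       11       9   10.227273 0.004429         True
anterior_chamber_invasion         1        2       35       9    0.128571 0.132285        False
```

Only post-laminar optic nerve invasion associates with high MCT1
expression (p = 0.0044) at α = 0.05. The other examples demonstrate the
single-cell stages: `01` recovers a planted 2× pathway program
(PA = 1.086 in the target type, permutation p = 0.002), `02` finds the
planted program's pathway at the top NES of the variability GSEA, `03`
recovers a planted hypoxia–glycolysis coupling of ρ = 0.8 from per-cell
signature scores (Spearman 0.78/0.83 in the two types), and `05` runs
every stage from one config:

```bash
python examples/01_pathway_activity.py
scmetland run config.yaml          # same pipeline from a YAML config
```

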