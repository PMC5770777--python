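# mirclock

Analysis pipeline for studying how whole-blood miRNA expression changes
with age, and whether a miRNA-based "biological age" predicts mortality and
cardiometabolic disease.

Whole-blood miRNA panels are typically profiled by qPCR and reported as
cycle-threshold (Ct) values, where **lower Ct means higher expression** —
so a *positive* Ct-on-age slope means expression *falls* with age. Cohorts
with family structure (parents and adult children) violate the independence
assumptions of ordinary regression, so every association in this package
runs through a kinship-aware linear mixed model. The package provides:

- **`simulate`** — a pedigreed synthetic-cohort generator (two-cohort age
  structure, polygenic miRNA variation, technical covariates, Ct-27
  detection censoring, miRNA-coupled mRNA with latent batch factors and
  cell mixtures, proportional-hazards mortality, cardiometabolic traits),
  with all generating parameters emitted as ground truth.
- **`preprocess`** — Ct QC (detection limit, 5-SD outliers, expression and
  sample-missingness filters, limit-value fill), technical-covariate
  residualization, and partial-least-squares cell-count imputation.
- **`lmm`** — recursive pedigree kinship (2φ) and a restricted-maximum-
  likelihood mixed model `y = Xb + g + e`, `g ~ N(0, σ²_A K)`, fitted by a
  single eigendecomposition of K plus a 1-D profile over
  h² = σ²_A/(σ²_A+σ²_E).
- **`age_assoc`** — the per-miRNA differential-expression scan vs. age with
  Bonferroni control and discovery/replication concordance reports.
- **`clock`** — a pedigree-respecting train/test split and an elastic-net
  age predictor (coordinate descent on the `(2n)⁻¹‖y−Xβ‖² +
  λ(α‖β‖₁+(1−α)/2‖β‖₂²)` objective, α = 0.5, λ by pedigree-blocked 10-fold
  CV or fixed), giving "miRNA age" and **Δage = miRNA age − chronological
  age**.
- **`survival`** — Cox proportional hazards (Newton–Raphson, Efron ties)
  for Δage vs. all-cause mortality, Kaplan–Meier curves by Δage tertile,
  and mixed-model Δage–trait associations with treatment-based exclusions.
- **`coexpr` / `targets` / `enrich`** — surrogate-variable-adjusted
  miRNA–mRNA coexpression with Benjamini–Hochberg FDR, canonical seed-match
  site prediction (8mer / 7mer-m8 / 7mer-A1 / 6mer), and hypergeometric /
  Fisher-exact gene-set enrichment.

## Worked example

```python
import pandas as pd
from mirclock import (
    SimParams, simulate_cohort, qc_filter, kinship_from_pedigree,
    diffexpr_scan, standardized_residuals, split_by_pedigree,
    train_clock, predict_age, delta_age, cox_fit,
)
from mirclock.preprocess import design_matrix

cohort = simulate_cohort(SimParams(rng_seed=1))
ct, qc_report = qc_filter(cohort.ct)

phen = cohort.phenotypes.loc[ct.index]
K = kinship_from_pedigree(cohort.pedigree)
covs = ["sex", "batch", "rna_concentration", "rin", "ratio_260_280"]
scan = diffexpr_scan(ct, phen, K.loc[ct.index, ct.index], covs)

ped = cohort.pedigree[cohort.pedigree["individual_id"].isin(ct.index)]
split = split_by_pedigree(ped, seed=1)
tr, te = split.index[split == "A"], split.index[split == "B"]
model = train_clock(standardized_residuals(ct.loc[tr], phen.loc[tr]),
                    phen.loc[tr, "age"], seed=1, pedigree=ped)
pred, r = predict_age(model, standardized_residuals(ct.loc[te], phen.loc[te]),
                      phen.loc[te, "age"])

dt = delta_age(pred, phen["age"])
X = pd.concat([dt[["delta_age"]],
               design_matrix(phen.loc[te], ["age", "sex"], add_intercept=False)],
              axis=1)
fit = cox_fit(phen.loc[te, "surv_time"], phen.loc[te, "surv_event"], X)
```

On the default desk-scale cohort (300 families, ~1350 samples, 150 miRNAs)
this prints:

```
QC kept 1368 samples x 146 miRNAs
123 of 146 miRNAs age-associated at p < 3.4e-04
clock: 86 miRNAs selected, held-out r = 0.73
mortality: HR 1.026 per year of delta-age (95% CI 0.987-1.066, p = 0.201)
```

Reading the numbers: most of the panel is genuinely age-associated by
construction (the generator plants age effects on ~85% of miRNAs, a
majority with expression declining in older individuals); the elastic net
selects a sparse subset whose combined prediction correlates ~0.7 with
chronological age in the held-out pedigrees; and at this scale the
*measured* Δage — a noisy readout of the latent aging deviation that
drives mortality in the generator — carries a positive but non-significant
hazard ratio. The direct recovery of the generating hazard (HR 1.10 per
latent Δage-year) is part of the reproduction script below.

The same stages are scriptable from the shell (`mirclock simulate`,
`mirclock qc`, `mirclock diffexpr`, `mirclock clock-train`,
`mirclock assoc-survival`, `mirclock coexpress`, `mirclock targets`,
`mirclock enrich`), or end to end via a YAML config:

```bash
mirclock run --config pipeline.yaml --out results/ --seed 1
```

## Layout

```
src/mirclock/      library (simulate, preprocess, lmm, age_assoc, clock,
                   survival, coexpr, targets, enrich, pipeline, cli)
tests/             pytest suite incl. recovery/calibration acceptance tests
scripts/           acceptance.py
docs/methods.md    modeling assumptions, parameter choices, limitations
```
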