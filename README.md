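# pgxlos

Unmanaged pharmacogenomic and drug–drug interaction risk versus hospital
length of stay (LOS), as a tested, reusable analysis pipeline.

The package is aimed at health-services and pharmacoepidemiology
researchers who want to study how *pharmacogenetic interaction
probability* (PIP) and *drug–drug interaction* (DDI) severity relate to
inpatient LOS in claims-like data. Real claims are proprietary, so the
package ships a synthetic-cohort generator calibrated to the marginal
profile of a Medicare Advantage COVID-19 inpatient population (61%
female, mean age 77 ± 11, 34% institutional-SNP enrollment, mean LOS
≈ 12.6 days), and every stage of the analysis is exercised against it.

## What it computes

**PIP** — the probability that testing a 14-gene pharmacogene panel
(CYP2C19, CYP2C9, CYP2D6, CYP3A4, CYP3A5, CYP2B6, CYP4F2, DPYD,
HLA-B\*57:01, IFNL3, SLCO1B1, TPMT, UGT1A1, VKORC1) would reveal at
least one clinically actionable gene–drug or gene–drug–drug interaction
for a patient's screened medications. With per-gene actionable
phenotype mass p_g (the population frequency of phenotypes actionable
for at least one screened drug at gene g, set to 1 when a co-prescribed
inhibitor phenoconverts the gene for a screened substrate), and
assuming independence across genes:

    PIP = 1 − ∏_g (1 − p_g)

categorized as low (≤ 25%), moderate (> 25% to ≤ 50%), high (> 50%).
All scoring is parameterized by an editable knowledge base (phenotype
frequencies, actionable sets, pair severities, inhibitor relations); a
curated fixture is bundled.

**DDI** — worst-case severity over all unordered pairs of screened
drugs on the ordinal scale minimal < minor < moderate < major <
contraindicated; the analysis dichotomy flags moderate-or-worse.

**LOS model** — zero-truncated negative binomial (ZTNB) regression with
log link: LOS ≥ 1 day, NB2 dispersion θ, μ = exp(x′β), and

    P(Y = y | Y ≥ 1) = NB2(y; μ, θ) / (1 − (θ/(θ+μ))^θ),   y = 1, 2, …

Exponentiated coefficients are rate ratios for expected LOS. Two models
are fitted: a baseline model (age, gender, PIP, DDI) and an adjusted
model whose extra covariates are screened by a cross-validated LASSO
(1-SE rule) before an unpenalized refit, with subgroup re-fits per
HCC-count stratum and per chronic condition (COPD, diabetes,
hyperlipidemia, hypertension).

## Worked example

```python
from pgxlos import (default_knowledge_base, compute_pip, compute_ddi,
                    GeneratorConfig, generate_raw_cohort,
                    apply_cohort_filters, build_design_matrix, fit_ztnb,
                    rate_ratio_table)

kb = default_knowledge_base()
pip = compute_pip(kb, {"metoprolol", "omeprazole"})
print(round(pip.probability, 3), pip.category)
# 0.622 high        (CYP2D6 mass 0.46 and CYP2C19 mass 0.30 combine:
#                    1 - 0.54*0.70 = 0.622, above the 50% cut)

ddi = compute_ddi(kb, {"furosemide", "gentamicin", "aspirin", "ibuprofen"})
print(ddi.max_severity, ddi.flag_moderate_plus)
# major True        (the worst matched pair governs)

cfg = GeneratorConfig(n_patients=8233, seed=1)   # ≈6025 survive filtering
cohort, tally = apply_cohort_filters(generate_raw_cohort(cfg, kb))
print(len(cohort), round(cohort.los_days.mean(), 1))
# 6007 12.7         (deaths, short enrollment, missingness excluded)

design = build_design_matrix(cohort, ("age", "gender", "pip_category", "ddi"))
fit = fit_ztnb(design, cohort["los_days"].to_numpy())
print(rate_ratio_table(fit)[["term", "display", "p_display"]].to_string(index=False))
#              term           display p_display
#               age 1.01 (1.00, 1.01)    <0.001
#       gender_male 1.09 (1.04, 1.14)    <0.001
#      pip_moderate 1.13 (1.08, 1.19)    <0.001
#          pip_high 1.17 (1.09, 1.26)    <0.001
# ddi_moderate_plus 1.04 (1.00, 1.09)     0.072
```

A rate ratio of 1.17 for high PIP reads: holding the other covariates
fixed, patients whose medication list implies a > 50% chance of an
actionable pharmacogenomic finding stay about 17% longer than low-PIP
patients in this simulated cohort.

The same pipeline is available from the shell:

```sh
pgxlos simulate --out cohort.csv --seed 1
pgxlos score    --meds meds.csv --out scores.csv
pgxlos fit      --cohort cohort.csv --model adjusted --out fit.json
pgxlos analyze  --out results/ --seed 1     # all tables + stratum fits
```

## Layout

- `pgxlos.pgx_kb` — knowledge-base types, validation, TSV/JSON i/o
- `pgxlos.risk_scoring` — medication screening, PIP, DDI
- `pgxlos.cohort_synth` — synthetic claims cohorts, study filters, design matrices
- `pgxlos.ztnb_model` — ZTNB likelihood, MLE, Wald rate-ratio inference
- `pgxlos.covariate_selection` — LASSO screen (10-fold CV, 1-SE rule) + refit
- `pgxlos.pipeline` — orchestration, descriptive/rate-ratio/LOS tables
- `pgxlos.recovery` — replicated parameter-recovery studies
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
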