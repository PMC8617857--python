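# Methods

## The two exposure scores

### Pharmacogenetic interaction probability (PIP)

PIP answers: *if this patient were tested on a fixed pharmacogene
panel, how likely is at least one clinically actionable finding for the
drugs they are actually taking?* It is a function of (a) population
phenotype frequencies per gene and (b) per-drug sets of actionable
phenotypes, both held in an editable knowledge base.

For gene *g*, the actionable mass is

p_g = Σ { freq(ph) : ph actionable for ≥ 1 screened drug interacting with g },

the frequency of the *union* of actionable sets over the gene's
in-list drugs (two drugs sharing an actionable phenotype do not double
count). Phenotypes at different genes are treated as independent —
the natural prior for unlinked pharmacogenes and the assumption that
makes the union probability closed-form — giving

PIP = 1 − ∏_g (1 − p_g),

which the implementation accumulates in log space
(`log1p`/`expm1`) so that many small p_g do not lose precision.
Categories are low (PIP ≤ 0.25), moderate (0.25 < PIP ≤ 0.50), high
(PIP > 0.50); the published percentage bands are rounded displays of a
continuous probability, so the boundaries are implemented as half-open
intervals on proportions.

**Gene–drug–drug interactions (phenoconversion).** When a screened
inhibitor targets gene *g* and some *other* screened drug has an
interaction at *g* whose actionable set contains the induced phenotype,
the patient is a deterministic phenocopy: the triple is actionable with
certainty and p_g = 1. A probability-weighted shift would also be
defensible; the deterministic phenocopy is the simplest mechanism that
makes drug–drug–gene interactions contribute, and each such triple is
flagged in `PipResult.contributing` so downstream users can see exactly
why a gene became certain. Only inhibition is modelled, not induction.

**Screening window.** A medication counts when its active interval
intersects [admission_start − 30 days, admission_end]. Records with
start after end are rejected per record (logged), not fatally. Drugs
absent from the knowledge base contribute nothing and are reported per
patient (`unscored_drugs`), never dropped silently.

### DDI severity

All unordered pairs of screened drugs are looked up in the pair table
(ordinal scale minimal < minor < moderate < major < contraindicated);
only the most severe matched pair is retained, and the analysis
dichotomy is moderate-or-worse versus minimal/minor/none. Severity of
gene–drug interactions is out of scope (actionable/not is the only
dichotomy on that axis); dose and frequency are ignored.

### The bundled knowledge base

The fixture covers the 14-gene panel with phenotype frequencies close
to published U.S. population values, ~20 drugs, 8 severity-graded
pairs, and 2 CYP2D6 inhibitors. One calibration is deliberate: the
CYP2D6 profile (IM 0.39, PM 0.07) makes the single-drug PIP of
metoprolol exactly 0.46, the drug's published single-drug anchor. The
actionable sets are illustrative of guideline/label logic, not a
reproduction of any proprietary rule base; the score is
knowledge-base-parameterized by construction, so users can substitute
their own tables (TSV bundle or JSON; validation reports *all*
violations with machine-readable codes, not just the first).

## The outcome model

LOS in days is a strictly positive count (a retained admission lasts
≥ 1 day), modelled as a zero-truncated NB2 with log link:
Var(Y) = μ + μ²/θ before truncation, and

log P(y | y ≥ 1) = log NB2(y; μ, θ) − log(1 − (θ/(θ+μ))^θ).

The truncation correction uses a log1mexp evaluation that stays
accurate both when P₀ ≈ 1 (tiny μ) and P₀ ≈ 0 (large μ), and the NB2
kernel is computed with log-gamma arithmetic, so the pmf is stable into
the Poisson limit (θ → ∞). Hurdle/zero-inflated variants, random
effects and robust variances are out of scope.

**Fitting.** Maximum likelihood jointly over (β, log θ): BFGS on the
mean negative log-likelihood with an analytic score, warm-started from
a Poisson regression with a method-of-moments θ₀, polished by L-BFGS-B
if needed. Convergence requires the score's infinity norm below 1e-6
(per-observation scale); the fit is deterministic — no randomness, a
fixed initialization. The covariance is the inverse observed
information, obtained by central finite differences of the analytic
score. Confidence intervals and p-values are 95% Wald with no
small-sample correction (cohorts here are in the thousands); rate
ratios are exp(β). A non-converged fit refuses to report intervals.
Rank-deficient designs are rejected with the collinear columns named —
never silently dropped. The implementation is cross-checked in the test
suite against an independent zero-truncated NB implementation
(statsmodels) and against a brute-force lattice-search MLE on small
instances; the cross-check never substitutes for the implementation.

**Design matrices.** Reference coding: female; low PIP; minimal/minor
DDI; HCC 0-1; urban; white; non-enrolled SNP. Age is centered at the
cohort mean (the per-year slope is unaffected); income is centered and
scaled to USD 10,000. Column order is deterministic.

## Covariate selection

The adjusted model screens candidates with a Gaussian LASSO of log(LOS)
on standardized predictors — a fast, stable screen; a penalized ZTNB
would add cost without changing the refit, since selection is treated
purely as a pre-filter. λ is chosen by 10-fold cross-validation with
the one-standard-error rule (fold assignment fixed by the seed).
Multi-level categoricals are selected as a group (any nonzero indicator
selects the covariate, which then contributes all its indicators).
The exposures (PIP category, DDI flag) are always forced; subgroup
models also force the stratification controls. Inference comes from the
unpenalized ZTNB refit on the selected set with selection treated as
fixed — naive post-selection inference, stated as such; under the 1-SE
rule a pure-noise candidate is picked up in roughly the α-level
fraction of replicates (checked loosely in the tests). RAF and HCC
count are both offered as candidates even though they are related by
construction; genuine collinearity is reported by the refit, not
resolved silently.

## The synthetic cohort generator

The generator emulates the *statistical shape* of a Medicare Advantage
COVID-19 inpatient claims cohort, not its clinical content:

- **Marginals** (defaults): 61% female; age ~ Normal(77, 11) clipped to
  [40, 102]; race 62/30/3/2/2/1 (white/Black/Hispanic/other/
  Asian-Pacific/unknown); residence 47/37/16; income ~ Normal(63027,
  17435) USD; SNP none/C/D/I = 56/4/6/34 (at most one per member); HCC
  count categories 24/33/20/23; COPD/diabetes/hyperlipidemia/
  hypertension 24/52/58/32%; PIP categories 58/30/12; DDI groups
  (none-or-minor / moderate / major / contraindicated) 52/16/25/7.
- **Medications are real objects, not labels**: each patient receives a
  drug bundle whose *scored* PIP category and DDI group under the
  knowledge base equal the assigned ones (bundle combinations are
  validated against the KB at generation time), plus an out-of-window
  historical drug and an in-window drug unknown to the KB, so the
  screening window and unscored-drug paths are exercised on every run.
- **Outcome**: LOS is drawn directly from the zero-truncated NB2 with
  log-mean intercept + x′β (rejection of zeros), matching the fitted
  likelihood exactly — parameter recovery is then a clean consistency
  check. Default generating coefficients: moderate PIP +9%, high PIP
  +16%, DDI +4%, male +8%, +0.5% per year of age; HCC 2-3/4-5/6+
  +10/20/30%; conditions +3 to +8%; I-SNP −25%; RAF 0 (deliberately
  null); dispersion θ = 1.5 and intercept 2.2835, calibrated once so
  the filtered cohort's mean LOS is ≈ 12.6 days with SD ≈ 11. Where a
  published estimate exists it is the default; the remaining values are
  modest, realistic choices fixed up front. Optional per-HCC-stratum
  effect modifiers give stratum-specific exposure effects for subgroup
  studies.
- **Contamination** for the filters: 16% in-hospital death on the index
  admission, 12% sub-12-month enrollment, 10% repeat admissions, 1%
  missing income. These are independent, so the expected post-filter
  yield is their product (≈ 0.73); studies targeting an analysis n of
  6,025 generate ≈ 8,233 raw members.
- **Confounding knob**: by default exposures affect LOS only through β
  (no hidden confounding). `confounding_strength > 0` tilts high PIP
  toward high HCC counts, creating disease-burden confounding for
  sensitivity tests of the adjustment machinery.
- Admission dates are ISO dates in Jan–Jun 2020 for realism; filters
  operate on durations and flags, not calendar logic.

**Filters** (application order, each tallied): keep the earliest
COVID-flagged admission; drop in-hospital deaths at that admission;
drop enrollment < 12 months; drop missing non-race fields (unknown
race/ethnicity is retained as its own level). Filtering is idempotent.

What the generator does *not* emulate: ICD-10/NDC code streams,
prescription behaviour correlated with disease, COVID severity, kidney
or hepatic function, mortality processes (death is a contamination flag
only, since deaths are excluded), or inter-admission dynamics. Passing
recovery tests therefore demonstrate that the estimation chain is
consistent under the stated generative model — not that the published
real-data estimates are correct, which proprietary data make untestable
here.

## Stratified analyses and reports

HCC strata partition the cohort; chronic-condition strata overlap (a
patient with two conditions appears in both), and each condition model
forces the other three conditions as controls. Subgroup runs re-run
covariate selection within the stratum (configurable). Significance is
displayed at p < 0.05 with no multiplicity correction, and the report
footnotes that convention. Mean-LOS tables use normal-approximation
95% CIs; an empty cell is reported missing (not zero) and a
single-patient cell keeps its mean with an undefined CI. Every table
number is recomputable from the persisted fit JSONs.

## Recovery studies and problem sizes

`pgxlos.recovery` runs the replicated round-trip studies used by the
acceptance checks: total-cohort adjusted PIP effects and baseline
demographic effects at 25–40 replicates of analysis-n ≈ 6,025;
per-stratum exposure effects at 100 replicates (stratum n ≈ 1,500–2,000,
where a single replicate's sampling error is several percentage
points); the hypertension mean-LOS gap at 100–300 replicates (the
intercept and PIP coefficients for that study are obtained by inverting
the ZTNB truncated mean, μ/(1 − P₀), at the target cell means).
Replicate counts were set from per-replicate standard-error estimates
so the Monte-Carlo error of each reported mean is small relative to the
quantity; each study derives its replicate seeds from a single master
seed via `SeedSequence`.

## Known limitations

- Cross-gene independence and deterministic phenoconversion are
  modelling choices; the proprietary scoring system they echo may
  weight these differently.
- Post-selection inference is naive; selected-model CIs do not account
  for the screen.
- The Wald/observed-information variance has no sandwich protection
  against dispersion misspecification.
- The fixture knowledge base is small; PIP values outside its drug list
  are floors, not estimates.
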