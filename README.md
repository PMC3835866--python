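# sgapaf

Population-level risk-factor analysis for **small-for-gestational-age
(SGA)** birth: from linked perinatal records to stratified marginal
logistic models and **model-based population attributable fractions (PAFs)**
with cluster-bootstrap confidence intervals.

SGA (birthweight below the 10th gestational-age- and sex-specific
percentile) is the standard measure of inadequate fetal growth.  For
perinatal epidemiologists asking *"how much SGA could be prevented if a
modifiable exposure were removed from the population?"*, the quantity of
interest is the PAF.  This package implements the full analysis chain used
in registry-based studies of that question:

1. **SGA classification** against a percentile standard (strictly below the
   10th percentile, per completed week 24–44 and sex);
2. **cohort construction** from linked birth records: inclusion filters
   (singleton, livebirth, 24–44 weeks), validation of each mother's
   obstetric history against her linked records, and derivation of history
   covariates (parity, inter-pregnancy interval, previous caesarean /
   preterm / stillbirth / SGA);
3. **stratified model building** (preterm; term, diabetic mother; term,
   non-diabetic mother): chi-squared screening at P<0.10, VIF diagnostics,
   backward elimination at P<0.01 with a 10% change-in-aOR confounder rule,
   re-entry and interaction passes;
4. **final fits by GEE** — logit link, exchangeable working correlation
   across births to the same mother, robust (sandwich) standard errors —
   reported as adjusted odds ratios aOR = exp(β) with 95% CIs;
5. **PAF estimation** by coefficient-zeroing counterfactual,

   PAF = 100 · (Σᵢ p̂ᵢ − Σᵢ p̂ᵢ⁰) / Σᵢ p̂ᵢ,

   where p̂ᵢ⁰ sets the factor's coefficients to zero with everything else
   unchanged, and 95% **bias-corrected percentile intervals** from a
   mother-level cluster bootstrap (default 10,000 replicates).

Because real linked registry data are confidential, the package ships a
**synthetic cohort generator** that reproduces the structure the analysis
relies on (mothers with 1–3 correlated births, configurable factor
prevalences and effects, ~5.2% preterm, ~10% SGA by construction, corrupted
history reports) and retains a **truth ledger** — per-birth outcome
probabilities and counterfactuals — so every stage is testable against
known ground truth.

## Worked example

```python
from sgapaf import (CohortConfig, generate_cohort, make_synthetic_standard,
                    stratify, fit_gee, adjusted_ors, bootstrap_paf)
from sgapaf.pipeline import build_cohort, analyse_stratum, SelectionConfig

std = make_synthetic_standard()              # P10 at 39 weeks = 2500 g
cohort, ledger = generate_cohort(CohortConfig(n_mothers=20_000, seed=20260922), std)
labelled, tally = build_cohort(cohort, std)
res = analyse_stratum(stratify(labelled)["term_nondiabetic"], "term_nondiabetic",
                      SelectionConfig(), ("smoking",), bootstrap_reps=2000,
                      seed=20260922)
```

Running the equivalent numbered scripts (`analysis/01...` → `05...`) prints,
for the default 20,000-mother cohort:

```
term_nondiabetic: n=20670, working alpha=0.0085
  final factors: ['country_of_birth', 'illicit_drug_abuse',
                  'pregnancy_hypertension', 'previous_sga', 'smoking',
                  'socioeconomic_group']
term_nondiabetic:
  smoking: PAF 10.76% [8.97, 12.61]
```

Read: among term births to non-diabetic mothers, the fitted model
attributes 10.8% of SGA births to smoking in pregnancy (planted truth in
this simulation: 10.98%) — i.e. the expected reduction in SGA births if
smoking's effect were removed, holding all other risk factors and every
mother's covariates fixed.  The bracket is the 95% bias-corrected
cluster-bootstrap interval.

A command-line interface exposes the same stages:

```bash
sgapaf simulate --n-mothers 10000 --seed 1 --outdir results/run
sgapaf build   --outdir results/run
sgapaf paf     --seed 1 --reps 2000 --outdir results/run
sgapaf report  --outdir results/run
# or end-to-end, optionally from a YAML config:
sgapaf all --n-mothers 10000 --reps 1000 --seed 1 --outdir results/run
```

## Layout

```
analysis/    numbered narrative drivers (simulate → build → fit → PAF → validate)
src/sgapaf/  the library: growth, cohort, gee, selection, paf, simulate, pipeline, cli
tests/       pytest suite incl. statistical acceptance tests
docs/        methods note (models, assumptions, design choices, limitations)
scripts/     acceptance.py (see above)
```
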