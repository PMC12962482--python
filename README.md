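# ipn-cea — cost-effectiveness of AI-assisted pulmonary nodule risk stratification

A decision-analytic cost-effectiveness model comparing two strategies for
the initial cancer risk stratification of an indeterminate pulmonary
nodule (IPN): **clinician assessment alone** versus **clinician assessment
with AI support** (a radiomics-based lung cancer prediction score billed
as a per-patient fee). It is written for health-economics and
thoracic-oncology researchers who want a tested, scriptable version of
this analysis: every number in the published-style tables is produced by
library code that can be re-parameterized, perturbed, and re-run.

## The model

A decision tree follows a 60-year-old operative candidate with an
incidentally discovered 1.1 cm nodule through guideline-based management.
The chosen strategy assigns the nodule to a low / intermediate / high
cancer-probability class with truth-conditional probabilities taken from a
12-reader classification study; management then proceeds identically in
both arms:

* **high risk** — diagnostic wedge resection with frozen section;
  malignant nodules proceed to lobectomy in the same operation,
* **intermediate risk** — PET or non-surgical biopsy (practice-dependent
  split); PET-avid nodules go to surgical biopsy, non-avid to
  surveillance; biopsies may be diagnostic, falsely negative, or
  non-diagnostic,
* **low risk** — CT surveillance; malignant nodules eventually grow and
  reach lobectomy with a stage-shifted (delayed) stage distribution, or
  progress to unresectable disease.

Terminal payoffs are discounted life years (DEALE-derived: life expectancy
= 1/(μ_background + μ_disease), μ_disease = −ln S₅/5, discounted at 3%/yr)
and payer costs in 2021 USD (Medicare DRG/CPT/APC reimbursements, stage-
specific anticancer regimens at average sales price + 4.3%, and unrelated
annual medical costs over each year of survival). Expected values come
from standard rollback; strategies are compared by

    ICER = (C_AI − C_clin) / (E_AI − E_clin)      [$ per life-year gained]
    NMB(λ) = λ·E − C                              [net monetary benefit]

with a willingness-to-pay λ of $100,000 per life-year gained. On top sit
one-way, tornado, threshold, and two-way deterministic sensitivity
analyses, and a 400-draw second-order Monte Carlo probabilistic
sensitivity analysis with cost-effectiveness acceptability curves.

## Worked example

```python
from ipn_cea import default_parameters, run_base_case

report = run_base_case(default_parameters())
print(report.formatted())
```

prints

```
strategy      cost        effect (LY)
clinician     $213,750    14.63
ai_assisted   $213,841    14.66
incremental   $92         0.0254
ICER: $3,601/LY   (cost-effective at $100,000/LY)
```

Reading: the average patient costs the payer ~$214k over a lifetime
(dominated by unrelated annual medical costs and stage-dependent cancer
treatment) and lives 14.6 discounted life years. AI assistance adds its
$650 fee but recovers most of it by classifying malignant nodules as
high-risk more often (60% vs 47%), which buys 0.0254 discounted life
years per patient — about $3,600 per life-year gained, far below the
usual $100k threshold.

The same numbers and every sensitivity analysis are available as numbered
drivers:

```bash
python analysis/01_reader_study.py            # synthetic 12-reader study
python analysis/02_base_case.py               # the table above
python analysis/03_deterministic_sensitivity.py
python analysis/04_thresholds.py              # prevalence & accuracy cut-offs
python analysis/05_twoway_pet.py              # PET frequency x specificity
python analysis/06_psa_ceac.py --seed 1       # PSA + acceptability curve
```

each writing its tables under `results/`. A `ipn-cea` CLI wraps the same
functions (`ipn-cea run`, `ipn-cea tornado`, `ipn-cea psa --seed 1 ...`,
`ipn-cea print-defaults`); custom scenarios go through a YAML/JSON config
(`--config`) that overrides any subset of the packaged inputs.

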