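# Methods

## Model structure

The model is a single-stage decision tree (no Markov cycles). The root
decision selects the stratification strategy; everything below is chance.
Each arm draws the nodule's true state from the malignancy prevalence
(base 0.65, the mix seen in dedicated nodule/thoracic-surgery clinics),
then the assigned risk class from the strategy- and truth-conditional
stratification row, then follows guideline-based management:

* High-probability nodules undergo diagnostic wedge resection with frozen
  section. Benign: operatively complete (wedge operative mortality
  0.0083). Malignant: completion lobectomy in the same operation
  (lobectomy mortality 0.022), staged by the *immediate* distribution
  (I/II/III = 0.75/0.17/0.08).
* Intermediate-probability nodules split between PET and non-surgical
  biopsy with probability `p_intermediate_pet`. PET-avid nodules
  (malignant 0.89, benign 0.23) proceed to surgical biopsy (the wedge
  subtree); non-avid nodules to surveillance. Biopsied malignant nodules
  are diagnostic (0.92, → immediate lobectomy), falsely negative
  (0.037, → surveillance), or non-diagnostic (0.043, → surgical biopsy
  with probability `p_surgical_biopsy`, else surveillance); biopsied
  benign nodules are diagnostic (0.56, workup ends) or non-diagnostic
  (0.44, same routing).
* Low-probability nodules enter CT surveillance. Benign nodules grow with
  probability 0.1 (→ diagnostic wedge) or remain stable (four
  surveillance CTs, $652). All malignant nodules eventually grow (one
  growth-triggering CT, $163): 4% progress to unresectable disease
  (III/IV split 0.5/0.5), the rest reach lobectomy with the *delayed*,
  stage-shifted distribution (0.72/0.19/0.09).

Assumptions carried by this reconstruction, where the published figure
leaves the subtree composition open:

* **One admission, one DRG.** A wedge resection that converts to
  lobectomy under the same anesthetic is billed as the lobectomy DRG
  alone, and carries lobectomy mortality (the dominant operative risk).
  DRG payment is per inpatient stay, so adding the wedge DRG on top would
  double-bill the admission. This is the main lever on the incremental
  cost: the AI arm sends more malignant nodules straight to combined
  surgery, and billing both DRGs would charge the AI arm ~$9k extra on
  each of those transfers.
* Growing benign nodules under surveillance resolve by diagnostic wedge
  resection (the guideline response to growth); growing malignant nodules
  proceed directly to lobectomy — their malignancy is established
  intraoperatively, but no separate wedge DRG is billed (see above).
* Benign nodules with a diagnostic biopsy terminate with no further
  surveillance cost.
* PET-negative and falsely-negative-biopsy malignant nodules follow the
  full delayed-surveillance arm, including the stage shift.
* The AI fee ($650) is charged exactly once per patient in the AI arm.
* The two routing preferences that guidelines leave to clinician and
  patient (`p_intermediate_pet`, `p_surgical_biopsy`) have no literature
  base value; both default to 0.5 (symmetric ignorance) and are varied
  0–1 in deterministic sensitivity analyses.

## Payoffs

Life years are discounted terminal payoffs (benign 16.44; stage I 16.32,
II 8.42, III-resectable 5.04, III-unresectable 3.84, IV 3.34). They are
consistent with DEALE life expectancies discounted continuously at 3%/yr
(`deale_life_expectancy` and `discount_life_years` document the
derivation: 16.44 ↔ a 22.66-year background horizon), and are consumed as
given; operative deaths score exactly zero life years.

Costs are one-time procedure/treatment amounts accrued along the path
plus unrelated annual medical costs: the undiscounted horizon is
recovered from the discounted payoff (`invert_discount`), and costs
accrue at the end of each survival year, discounted discretely, at
$9,056/yr through attained age 65 and $12,961/yr after (base age 60, so
survival years 1–5 bill the younger rate), with the final partial year
prorated. Whether the published model accrued these costs over discounted
or undiscounted year counts is not stated; accruing over the undiscounted
horizon was chosen because "each year of survival" is a calendar notion,
and the alternative only rescales both arms' totals without materially
moving the increment. Stage I receives no adjuvant therapy; stage II and
resectable III receive the adjuvant regimen cost ($200,446); unresectable
III receives chemoimmunotherapy plus IMRT ($193,426 + $166,933); stage IV
receives its regimen ($421,376). Regimen line items (agents, doses,
infusion counts) are packaged for audit with unit prices back-derived
from the published line totals at the 4.3% Medicare markup; AUC-dosed
carboplatin is priced per administration because the Calvert formula
needs renal function, which is not a model input. (The stage II–IIIA
line items sum to $197,136, not the $192,182 printed alongside them; the
line totals are taken as authoritative, and the model's treatment costs
come from the cost table, not from re-summing regimens.)

## Parameters

Every input carries a base value, a deterministic range (±20% unless the
literature reports wider), and a PSA family. Multinomial rows —
stratification rows, stage distributions, the biopsy outcome partitions,
the unresectable III/IV split — are registered as groups: setting one
component rescales its complements proportionally so the row keeps
summing to 1 (`renormalize_complement`). The clinician/malignant row is
printed as .47/.42/.10, which sums to 0.99; the constrained middle
component is repaired to 0.43.

A YAML/JSON config can override any subset (sections: `probabilities`,
`stratification`, `stage_distributions`, `life_years`, `costs`,
`structure`); unknown keys are rejected by name, single-component
overrides renormalize their row, and whole rows are taken verbatim.

## Deterministic sensitivity analyses

One-way curves rebuild and roll back the tree at each grid value (the
base point is spliced into the grid so the base case is always
reproduced bit-for-bit). The tornado evaluates the ICER at both range
bounds; bars are sorted by |ICER(high) − ICER(low)|. A bound that drives
the comparison out of the positive-gain quadrant (no life-year gain at
extra cost) has no ICER — the point is dominated — so such entries cannot
be drawn as ICER bars: they are flagged `rankable=False` and listed after
the rankable bars rather than being assigned an infinite span. Threshold
analysis bisects the ICER−WTP sign change to a 1e-4 bracket, scoring
dominated points as +∞ (never cost-effective) and strictly-dominant
points as −∞, which keeps the search monotone; an absent sign change is
reported as "no crossing", not raised. The two-way analysis is a full
factorial rebuild; PET specificity is exposed as a derived parameter
(1 − benign PET avidity) so the grid can be specified in the units the
literature uses.

## Probabilistic sensitivity analysis

Each sampled parameter's distribution is moment-fit from the
deterministic inputs: mean = base case, **sd = half the deterministic
range**. Probabilities get betas, costs gammas, and each multinomial
group is drawn jointly from a Dirichlet whose total concentration is
solved so the first (anchor) component's beta marginal has the target sd
— independent per-component betas cannot guarantee rows sum to 1 (the
diagnostic-biopsy range reaches 1.0). Life-year payoffs and structural
settings are fixed, as are the two routing knobs: a mean-0.5 knob with
sd 0.5 has no feasible beta fit, and they encode practice variation
rather than sampling uncertainty, which the 0–1 deterministic analyses
already cover. Draws are validated (rows sum to 1, probabilities in
range), rolled back, and scored by net monetary benefit on a $0–200k WTP
grid in $1k steps; ties split 0.5/0.5; the CEAC crossing interpolates the
first upward crossing of 0.5.

**What the PSA does and does not show.** Under this variance rule the
acceptability of AI assistance at $100k/LY is close to a coin flip
(~0.53 at 400 draws) even though the base case and every deterministic
analysis favor AI. The driver is measurable by sampling one block at a
time: the clinician stratification ranges (e.g. 0.20–0.58 for calling a
malignant nodule high-risk) are plausibly the *across-reader spread* of
the underlying study rather than uncertainty in the mean reader, and
half-range sds on those rows alone flip the preferred strategy in ~44% of
draws; sampling the immediate and delayed stage distributions
independently flips another ~26% by allowing draws in which delayed
resection yields *better* stages than immediate — a logical
impossibility, since the delayed row is the immediate row plus a stage
shift. Tighter (e.g. standard-error-of-the-mean) distributions or
coupled stage rows would push acceptability toward the deterministic
conclusion; the half-range rule is kept because it is the stated study
condition, and the CEAC should be read as a deliberately conservative
stress test, not as evidence against the base case.

## Synthetic reader study

`reader_study` stands in for the 12-reader, 300-nodule classification
study behind the stratification rows: every (reader, nodule) read is an
independent multinomial draw from the truth- and strategy-conditional
row, counts are tallied per (strategy, truth, class), and relative
frequencies recover the matrix. It reproduces exactly the marginal
frequencies the model consumes; it does **not** model reader random
effects, within-nodule correlation across strategies (the same readers
read the same nodules with and without AI), or case-mix difficulty — so
passing recovery tests says nothing about inter-reader variance in real
data. The malignant/benign split of the cohort is not published; 150/150
is an explicit knob.

## Numerical conventions

Chance-node probabilities must sum to 1 within 1e-9; rollback and
exhaustive path enumeration agree within 1e-9 (this dual route is a
permanent test oracle). Bisection tolerance 1e-4 on the parameter axis;
CEAC grid $1k; display rounding (whole dollars, two-decimal life years)
happens only in formatted output, never in stored tables. All randomness
flows through `numpy.random.default_rng(seed)` with a deterministic
parameter ordering, so equal seeds give byte-identical outputs.

## Problem sizes

The packaged analyses use: 80-point prevalence and 71-point accuracy
one-way grids, an 11×9 two-way PET grid, 400 PSA draws, and a 12-reader ×
300-nodule synthetic study; moment-recovery tests use 10,000 draws. The
full tree has 56 root-to-terminal paths per strategy.

## Limitations

No Markov survival modelling, competing non-cancer mortality during
surveillance, loss to follow-up, recurrence treatment costs, neoadjuvant
therapy, segmentectomy, or SBRT; costs are consumed already converted to
2021 USD; QALY weighting is out of scope (life years are the effect
unit). The exact composition of the published subtrees and the two
routing probabilities are not recoverable from public material; every
contestable reconstruction choice above is stated explicitly and most are
single-line switches in `tree.py`.
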