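# Methods

This package implements a new-user retrospective cohort analysis of
biologic initiators with ulcerative colitis (UC) or Crohn's disease (CD)
over US administrative claims, together with a synthetic claims generator
that stands in for the proprietary commercial-claims source. This note
documents the model, the algorithms, the calibration of the synthetic
defaults, the numerical conventions, and what the synthetic validation does
and does not establish about real data.

## Study design

Patients enter the cohort at the **index date**, the date of their first
claim for one of seven biologics (adalimumab, certolizumab, infliximab,
natalizumab, ustekinumab, golimumab, vedolizumab) inside the accrual window
2010-04-01..2015-03-31 (primary, 12-month follow-up) or 2010-04-01..
2014-03-31 (secondary, 24-month follow-up). All windows use closed
whole-day intervals anchored on the index date: baseline is
`[index-365, index-1]`, follow-up `[index, index+365·years-1]`; index-day
claims (including the initiating claim) belong to follow-up.

Eligibility is a fixed-order cascade, each stage logged in an attrition
table: (1) unambiguous index drug — two different biologics on the earliest
in-window date exclude the patient (the source design is silent on this
tie; exclusion is conservative and logged); (2) age ≥ 18 at index;
(3) continuous enrollment with both medical and pharmacy benefits over
baseline plus follow-up, zero-day tolerance, abutting spans merged (whether
both benefits are required during follow-up as well as baseline is
ambiguous in the source; this implementation requires both throughout, and
the enrollment checker takes the window as parameters so the choice can be
toggled); (4) at least one UC (ICD-9-CM 556.xx) or CD (555.xx) diagnosis
during baseline or on the index date, with cohort assignment by the larger
count of *distinct diagnosis-coded visit dates* — equal nonzero counts are
excluded as ties, matching the source's tie-exclusion rule; (5) washout: no
biologic claim of any drug in `[index-365, index-1]` (new-user
requirement); (6) no cancer diagnosis (ICD-9-CM 140-208, configurable
prefixes) from baseline start through follow-up end. "Healthcare visit" is
a distinct service date carrying the diagnosis, across settings and all
four diagnosis fields, not a claim line.

## Biologic identification

Self-injected products are identified on pharmacy claims by NDC;
infused products on medical claims by drug-administration HCPCS code.
Vedolizumab (approved 2014, no product-specific permanent code until 2016)
uses a rule-based algorithm: a pharmacy claim with a vedolizumab NDC, a
medical claim with unclassified-biologic code J3590 whose *first-listed*
diagnosis is 555.xx/556.xx, or a medical claim with C9026 or J3380.
"C9026 and J3380" is read as a list of alternative codes, and "primary
diagnosis" as the first-listed field — both stated conventions, not
derivable from the source.

The shipped code lists (`data/drug_codes.yaml`) are documented defaults —
the standard J-codes plus representative labeled NDCs — and are fully
overrideable; the pipeline's correctness is independent of the specific
lists, which production use should replace with a maintained formulary
extract.

## Treatment episodes and persistence

Continuous use of the index drug is assumed while no two successive claim
dates for it are more than the **permissible gap** apart: the drug's
expected maintenance dosing interval plus a 30-day grace period (defaults:
adalimumab 14+30, certolizumab 28+30, golimumab 28+30, infliximab 56+30,
natalizumab 28+30, ustekinumab 56+30, vedolizumab 56+30 days; the intervals
are labeled maintenance schedules, overrideable). Gaps are measured
between claim/administration dates, not days-supply exhaustion, so one rule
serves both routes. The episode also ends when follow-up extends more than
the permissible gap past the last claim; the episode end is the last
covered claim plus the gap, censored at follow-up end, and
`time_on_therapy = episode_end - index + 1` days. Strictness convention: a
claim arriving exactly `gap+1` days after its predecessor constitutes a
disqualifying gap even though it covers its own date — the day-by-day
oracle used in the tests therefore chains coverage (an event renews
coverage only if it falls within the gap of the previous chained event).

The **as-treated** population comprises patients whose episode runs
unbroken through the full follow-up; the **ITT** population all eligible
initiators. Only index-drug claims feed the episode; other biologics
neither extend nor break it (subsequent switching is out of scope).

### Known bias of the gap method

Gap-based classification cannot observe discontinuation inside the final
`permissible_gap` days of follow-up: a patient whose last claim falls
within the gap of the window end is classified persistent regardless of
what happened after. Under an exponential discontinuation time with median
m, the upward bias of the 1-year persistence estimate is approximately
`gap × f(365)` — 3-5 percentage points for 44-86-day gaps at the medians
seen here. Consequences adopted in this package:

* The **parameter-recovery experiment** (`experiments.persistence_recovery`)
  validates the full measurement chain against the closed form
  `exp(-365 ln2 / m)` using a fine-resolution instrument (3-day dosing
  grid, 3-day grace, so a 6-day permissible gap), for which the
  discretization bias is under one percentage point and recovery within
  3 binomial SE at n = 2000/drug is a fair test. Under the default 30-day
  grace the closed form is *not* recoverable — that discrepancy is the
  method's bias, not an implementation defect.
* The **default discontinuation medians** of the generator are calibrated
  by inverting the measurement model rather than the survival function:
  the published persistence percentages are themselves gap-rule
  measurements, so medians solve `p = exp(-t* ln2 / m)` where `t*` is the
  smallest dosing-grid multiple ≥ `364 - permissible_gap`. This gives
  adalimumab 225 d (from 37% pooled 1-year persistence), infliximab 335 d
  (~56%), natalizumab 533 d (67%); certolizumab (150 d) and golimumab
  (160 d) come from their ~152-day published median time on therapy, and
  ustekinumab (250 d) and vedolizumab (300 d), for which no percentage is
  printed, are set at plausible intermediate values.

## Synthetic claims generator

The generator emulates the *structure* of commercial claims — multi-span
enrollment with benefit flags, diagnosis-coded medical claims across
settings (IP, ED, OP-clinic, OP-hospital, office, other), pharmacy fills
with NDC/days-supply, per-claim paid amounts, service year — with known
per-patient ground truth. Model choices (all single-parameter and
right-skewed, chosen for closed-form recovery tests):

* **Discontinuation** ~ Exponential per drug (memoryless), median as above.
* **Biologic claims** on a regular grid at the dosing interval from index
  until the true discontinuation time, by pharmacy fill (days_supply =
  interval) or facility administration depending on the drug's route;
  vedolizumab administrations rotate through the three identification
  routes so all arms of the algorithm are exercised.
* **Utilization** ~ Poisson annual counts per window (defaults: baseline
  inpatient 0.45, ED 0.72, outpatient 16.5, other 0.5; follow-up 0.17 /
  0.45 / 18.0 / 0.5) on distinct service dates; inpatient stays get a
  1+Poisson(3)-day length of stay. IBD diagnosis codes ride on the
  baseline outpatient visits (so visit counts stay Poisson-faithful);
  both-coded patients receive strictly unequal UC/CD visit-date counts.
* **Costs** per claim ~ log-normal per category (inpatient stay ~$19k
  mean, ED visit ~$1.8k, outpatient visit ~$430, non-biologic fill ~$410)
  and per drug for biologic claims (per-administration means chosen so a
  persistent year costs ~$36-77k, bracketing the published follow-up
  pharmacy means). Amounts are nominal in the service year; the analysis
  inflates them.
* **Market shares** (pooled UC+CD: adalimumab 0.49, infliximab 0.43,
  certolizumab 0.045, others ≤ 0.014) back-derived from the published
  as-treated counts divided by their persistence percentages; disease mix
  UC 0.34 / CD 0.64 / both-coded 0.02 from the published cohort ratio;
  age-band distribution equal to the published UC 1-year column; 12%
  enrollment-gap, 2% baseline-biologic, 3% cancer defect rates; 57% of
  otherwise-clean patients retain 24-month coverage (published 2-year /
  1-year cohort ratios are 0.55-0.59).

One induced protocol defect at most per patient, recorded as the expected
exclusion reason in the ground truth (relative to the 1-year design). A
deterministic `inject_edge_cases` appendix adds one hand-built patient per
exclusion rule — under-age, UC/CD visit-count tie, baseline biologic
(whose pre-index claim must predate the accrual window, else it would
itself be the index event), cancer, baseline enrollment gap, missing IBD
diagnosis, same-day two-drug index, plus a clean control.

What the generator does **not** emulate: realistic ICD-9 code frequencies
beyond UC/CD/cancer and a small comorbidity pool; dose titration,
induction schedules, stockpiling or early refills (claims sit exactly on
the dosing grid, so the gap rule is exercised at its cleanest); switching
or re-initiation; claim adjudication/denial; capitated plans; seasonality.
Passing tests therefore demonstrate algorithmic correctness and parameter
recovery under the stated generating model — not robustness to the
irregular fill patterns of real claims. The exponential (constant-hazard)
discontinuation model cannot match the published 1-year and 2-year
persistence simultaneously (real discontinuation hazard falls with time on
therapy), so simulated 2-year persistence runs below the published values;
the 1-year quantities are the calibrated ones.

## Utilization and cost rollups

Inpatient claims merge into **stays** when date ranges overlap or abut; a
stay belongs to the window containing its admission date. ED and
outpatient **visits** are distinct service dates in the setting class
(outpatient = clinic + outpatient hospital + physician office; whether the
source deduplicated same-day claims across settings is unknown — the
distinct-date rule is a stated reconstruction). Costs attribute to the
window containing the claim's service start (pharmacy: fill date).

**Pharmacy cost** = pharmacy-claim dollars plus dollars on medical claims
whose HCPCS is in the medication set (facility-administered drugs); such
claims still count as visits but their dollars leave the setting
categories, so no dollar is counted twice. **Total medical cost** = all
remaining medical-claim dollars in every setting — it exceeds
inpatient+ED+outpatient by the "other-setting" remainder — and
**combined = total medical + pharmacy** holds exactly; the tests assert
both the identity and claim-dollar conservation per patient-window.

Costs are restated to US$2015 with annual averages of the US Medical Care
CPI (BLS series CUUR0000SAM, shipped in `data/cpi_medical.yaml`,
overrideable): `factor(y) = index(2015)/index(y)`; a service year missing
from the table is a hard error.

## Aggregation and formatting

Group rows (cohort × drug × population × window) report n, the count and
percentage with any admission/ED/outpatient use, and mean (sample SD, n-1
denominator) for each count and cost field. Percentages round half-up
through a one-extra-decimal intermediate — the convention the published
tables follow (126/616 prints as 20.46 via 20.455; single-stage half-up
would give 20.45; every checked printed cell is consistent with the staged
rule). Characteristics and utilization percentages print to 2 decimals,
initiation shares and persistence proportions to 1. Quantiles of time on
therapy use linear interpolation. Note that a censored median of 365 days
arises whenever more than half a group persists through follow-up.

## Numerical conventions and degenerate inputs

Calendar arithmetic is whole days throughout; age is completed years,
`(index - birth) // 365.25`. Empty populations yield empty cohorts and
zero-count attrition; empty aggregation groups are omitted with a log
entry; undefined quantiles are NaN. Events tied on the same day deduplicate
(a duplicate index-day claim is a zero gap). Malformed NDCs (non-numeric
after removing dashes, or longer than 11 digits) are skipped with a
warning; 10-digit NDCs zero-pad to 11. Same-seed configurations produce
byte-identical tables (single `numpy` Generator, sequential per-patient
draws).

## Validation summary

The test-suite and `scripts/acceptance.py` recompute: the published worked
examples through the formatters (45.1% persistence from 2195/4864 and
4017/8910; the printed characteristics/utilization cells); exact
equivalence of the episode walk with a day-by-day coverage brute force on
randomized event streams; per-drug recovery of `exp(-365 ln2/m)` within 3
binomial SE at n=2000/drug under the fine-resolution instrument; exact
per-patient cost identities and dollar conservation on a 5000-patient run;
correct exclusion of every injected edge case with monotone attrition; and
the directional baseline-to-follow-up pattern (admissions and ED down,
pharmacy and combined costs up) on the calibrated defaults. Problem sizes
(5000-patient main run, 2000 per drug for recovery, ~1200 oracle streams)
keep a full run to a couple of minutes on one core while leaving binomial
checks well-powered.
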