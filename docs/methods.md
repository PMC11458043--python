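# Methods

## The decision problem

Long-term proton-pump-inhibitor (PPI) use in older adults is frequently
inappropriate and carries excess risk of pneumonia, Clostridium difficile
infection (CDI) and hypomagnesemia.  A pharmacist-led deprescribing service
reviews every ambulatory PPI user aged ≥ 65, and for inappropriate regimens
recommends discontinuation, dose reduction, or a switch to a histamine-2
receptor antagonist (H2RA).  The prescriber may accept or reject the
recommendation; after an accepted action, GERD rebound may force
reinstatement of the standard-dose regimen.  The package compares this
service against usual care (everyone stays on standard-dose PPI) over a
one-year horizon, in expected direct medical cost (USD) and expected QALY
loss per patient evaluated, from a public-healthcare-provider perspective
(the bundled defaults describe Hong Kong, USD 1 = HKD 7.8).

## Model structure

Each strategy is a probability tree.  The deprescribing arm branches on
inappropriate use → recommendation mix (the three recommendation
probabilities sum to 1 and are renormalised inside the tree builder after
sampling or one-way excursions) → prescriber acceptance → rebound.  Every
resulting drug exposure then branches over the three adverse events, treated
as mutually exclusive within the year (their one-year probabilities are
small; joint occurrence is second order), with a no-event branch carrying
the complementary probability.  Hypomagnesemia splits into non-hospitalized
(no modelled utilisation or disutility) and hospitalized care; pneumonia
into outpatient care or hospitalization with survival/death; CDI is always
hospitalized with survival/death.  Usual care has 8 terminal paths, the
deprescribing arm 80.

Exposure determines adverse-event risk.  Risks in PPI users are derived from
the non-user yearly rates `p0` and odds ratios `OR` on the odds scale,
`p = OR·p0 / (1 − p0 + OR·p0)`.  Standard-dose ORs apply to usual care,
appropriate use, rejected recommendations and reinstated (post-rebound)
patients — rebound onset averages under 20 days, so a reinstated patient is
effectively a full-year standard-dose user.  Low-dose ORs apply to dose
reduction without rebound.  Discontinuation and switch to H2RA without
rebound carry the non-user baseline rates (no H2RA-specific ORs exist in
the input set).

The engine keeps two independent evaluation routes — brute-force terminal
path enumeration and recursive rollback — and the test suite requires them
to agree to 1e-12, both on the real model and on 100 randomly generated
synthetic trees whose expectations are accumulated in closed form at
generation time.

## Payoffs

**Costs** per path: 12 months of the effective regimen (months are
30.4375 days, a 365.25-day drug year; reinstated patients pay the interim
regimen for `rebound_onset_days` and standard-dose PPI for the remainder),
plus adverse-event management (length-of-stay × daily bed cost for
hospitalized events, clinic visits for outpatient pneumonia), plus — in the
deprescribing arm only — the pharmacist service cost
`salary / working_minutes_per_month × minutes_per_case`, charged once per
patient because every patient is reviewed.  Costs are not discounted (the
horizon is one year).  Patients who die are still charged the full year of
medication; the mortality probabilities are small and the simplification is
conservative against the intervention.

**QALY losses** relative to a symptom-free year at the age-specific utility:
`disutility × days/365` for each episode.  Rebound accrues the off-medication
relapse disutility after discontinuation and the on-medication disutility
after dose reduction or switch, over `rebound_onset_days` (default 20).
Hospitalized pneumonia survivors accrue the inpatient disutility over the
length of stay plus the ambulatory disutility over the 31-day convalescence;
outpatient pneumonia accrues the ambulatory disutility over 31 days.  A
death adds `utility × (1 − (1+r)^−LE)/r`, the discounted stream of remaining
life-years at the age-specific utility (r = 3%/year), and replaces any
post-event accrual (a pneumonia death carries the inpatient episode loss but
no convalescence).  Patients with controlled symptoms on continued PPI carry
no baseline GERD disutility: the relapse disutilities are defined for
symptomatic rebound episodes only.  This choice affects absolute, not
incremental, QALY losses.

## Remaining life expectancy

The death loss needs the remaining life expectancy at the cohort age, which
is itself a model parameter (base 80, range 65–88).  The configuration
therefore carries an age → remaining-years life table (linear interpolation,
clamped at the ends), approximating the Hong Kong 2022 life table averaged
over sexes: 21.3 years at 65, 10.1 at 80, 5.1 at 90.  This makes the age
parameter functional in both one-way and probabilistic analysis.  A scalar
`remaining_life_expectancy_years` override bypasses the table.

## Distributions and sensitivity analysis

Each uncertain input declares a family (beta, gamma or triangular) plus a
base value and range.  The range is read as an approximate central 95%
interval: beta and gamma are moment-matched to mean = base and
sd = (high − low)/3.92 (the multiplier is exposed as `sd_scale`);
triangular uses (low, base, high) as (min, mode, max).  Inputs with no
published range (the two unit fees) are fixed in both analyses.

One-way analysis evaluates each non-fixed parameter at both range endpoints,
all others at base, ranks by the spread of the tracked outcome (ICER by
default, NMB available) and flags any verdict flip as a threshold.

The PSA draws all non-fixed parameters jointly and independently
(the recommendation-mix betas are renormalised to the simplex rather than
replaced by a Dirichlet, staying faithful to the declared per-branch
families), evaluates **both strategies on the same draw** (common random
parameters — the only reading under which a per-draw incremental scatter is
meaningful), and summarises means with normal-theory CIs of the mean,
empirical 2.5/97.5 percentile intervals, and the proportions of draws that
are QALY-saving, cost-saving and cost-effective (NMB > 0) at the
willingness-to-pay threshold of one GDP per capita (USD 49,023/QALY).
A draw whose adverse-event probabilities cannot form a valid tree is
rejected, redrawn from the same stream and counted.  All randomness flows
from a single integer seed; runs are byte-reproducible.

## Problem sizes and numerical choices

The base case evaluates 88 terminal paths in under a millisecond; the full
one-way analysis (42 parameters, 85 evaluations) takes well under a second;
a 10,000-draw PSA takes ~15 s on one CPU.  Probability normalisation is
enforced at every chance node to 1e-9 (accumulated with `math.fsum`);
equal-cost/equal-effect comparisons classify as equivalent; an exactly-zero
QALY difference decides dominance on cost alone; the ICER is reported even
under dominance, with the dominance flag carrying the verdict.

## What the synthetic generator does and does not emulate

`generate_synthetic_model` produces random chance trees (depth ≤ 4,
branching ≤ 3, Dirichlet branch probabilities) with payoffs on the real
model's scales (costs up to 10⁴ USD, QALY losses up to 10) and closed-form
expectations stored at generation time.  It verifies the *evaluation
engine* — normalisation, enumeration, rollback — not the clinical content:
passing it says nothing about whether the deprescribing tree, the payoff
composition or the input values are right.  Those are covered by the
hand-derived oracles in the unit tests and by comparison with the published
results for the default configuration.  `perturb_parameters` jitters base
values within their published ranges to emulate region-specific input sets;
it cannot manufacture genuinely new epidemiology.

## Known limitations

* One-year fixed-horizon tree: no adverse-event recurrence, no Markov
  extension, no within-year timing beyond the rebound-onset offset.
* Adverse events are mutually exclusive within the year.
* Indirect costs (productivity loss) and unmodelled outcomes (e.g. gut
  microbiome changes) are out of scope.
* Non-hospitalized hypomagnesemia is a terminal path with zero cost and
  zero disutility — no ambulatory management is modelled.
* The absolute QALY-loss level depends strongly on the death-loss
  convention (utility × discounted remaining life expectancy) and on the
  life table supplied in the configuration; incremental results are far
  less sensitive to it.
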