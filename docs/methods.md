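# Methods

## The decision problem

A state government ran a pilot in which people attending primary-care
diabetes clinics were screened for diabetic retinopathy with fundus
cameras; images were graded centrally, and patients with suspected
sight-threatening diabetic retinopathy (STDR) or ungradable images
(mostly cataract) were referred to secondary care for examination and,
where indicated, laser photocoagulation or cataract surgery.  The
package asks whether that cascade was good value: what the programme
cost end to end, how many quality-adjusted life years (QALYs) the
treatments bought, and how the resulting cost per QALY compares with the
WHO-style willingness-to-pay benchmark of one GDP per capita per QALY.

The comparator is no screening.  Because no routine programme existed
before the pilot, the analysis assumes patients treated through the
cascade would otherwise have progressed to sight loss; the comparator
arm therefore carries zero incremental cost and zero incremental QALYs,
and the programme totals are themselves the increments.

## Disease model

STDR progression is a three-state annual-cycle Markov cohort model:
**STDR → blind → dead**, with dead absorbing and no recovery from
blindness.  The cohort enters at age 59 (the average age at STDR
diagnosis in the pilot), 100% in the STDR state, and is run to the
life-table terminal age so that QALYs are lifetime QALYs.

Within a cycle at age *a*:

- death is resolved first: `p_dead = min(rr × qx(a), 1)`, where `qx` is
  the general-population annual death probability and `rr` the
  state-specific mortality uplift — 1.9 in the STDR state (excess
  mortality of diabetes), 2.34 in the blind state;
- progression applies to survivors of the STDR state:
  `p_blind = p_prog × (1 − p_dead)`, with `p_prog` = 0.09/year untreated
  and 0.02/year after laser treatment.

This death-first ordering is a modelling choice (the competing risks are
not separately timed within a year); it keeps every transition row
summing to exactly 1 without renormalisation.  The uplift multiplies the
annual death *probability*; a hazard-scale variant
(`q' = 1 − (1−q)^rr`) is available on `MortalityUplift(scale="hazard")`
but is not the default, since published uplifts of this kind are quoted
on the rate.  The blind-state uplift *replaces* the diabetes uplift by
default (2.34 × general-population rate); set
`ModelParams(blind_uplift_combined=True)` to compound them (1.9 × 2.34)
if the excess risks are read as multiplicative.

Utilities are 0.70 in STDR and 0.55 blind (EuroQol scale, 1 = full
health).  Discounted QALYs are

QALY = Σ_{t=1..H} [occ_STDR(t)·u_STDR + occ_blind(t)·u_blind] (1+r)^−t

with r = 3%/year and the first year's benefit discounted once.  No
half-cycle correction is applied by default (occupancy is counted at end
of cycle); `half_cycle_correction=True` switches both life expectancy
and QALYs to the trapezoid rule.  The per-person gain from laser
treatment is the difference between the treated and untreated cohorts'
discounted QALYs; it is positive whenever treatment slows progression
and blindness has the lower utility, and it includes a survival
component because the blind state carries the higher mortality uplift.

Cataract surgery is modelled as pure quality of life: a gain of
0.20/year, damped by an annual 0.07% HRQoL decline with age, accrued
over the diabetes-uplifted survival curve (no blind state) and
discounted at 3%.  The decline is documented only for the cataract
pathway, so it is not applied to the STDR/blind utilities by default
(`decline_in_stdr_model` switches it on).  The cataract cohort also
enters at 59 — the only age available — but the entry age is
configurable.

## Costing

The ledger is bottom-up with every line tagged health-system or
societal:

- **Screening** (5307 patients): sixteen cameras at INR 300,000
  annuitized over a 5-year life (annuity-immediate at 3%, the same rate
  as benefit discounting, giving ≈ INR 1.048 million/year); INR 560,000
  staff training; INR 70 staff time, INR 15 administration and INR 15
  community-health-worker (ASHA) support per screen.  ≈ INR 403 per
  patient screened.
- **Examination** (830 attendees): INR 205 staff/administration plus
  INR 350 + 350 travel and INR 100 + 150 opportunity cost for patient
  and attendant → INR 1155 per examination.
- **Treatment**: laser package INR 12,000 plus 3 secondary-care
  attendances at INR 950 (345 patients); cataract surgery INR 18,000
  plus 1 attendance (160 patients).  A bilateral-treatment scenario adds
  one extra laser package (health-care cost only) for a configurable
  fraction of laser patients.

All arithmetic is full precision; rounding (nearest INR 5 for
per-patient components, nearest INR 100 for headline per-patient
aggregates, nearest 0.1 million for totals, whole QALYs) happens only in
report rendering, and reports carry both forms.  The pinned replication
scenario uses the published explicit counts (1662 referred, 830
examined, 345/160 treated) rather than the published percentages, which
are not exactly self-consistent (31% of 5307 is 1645, not 1662);
`cascade_from_rates` logs any such discrepancy when both are supplied.

## Sensitivity analysis

**One-way (tornado).**  Each of ten inputs — the three utilities, the
HRQoL decline rate, both transition probabilities, the blind-mortality
relative risk, the laser and cataract unit costs, and the aggregate
screening cost per person — is moved to 0.9× and 1.1× its central value;
probabilities and utilities pushed outside [0, 1] are clipped with a
warning.  The table reports the ICER at each leg and is sorted by span.

**Probabilistic.**  Gamma distributions for non-negative unbounded
inputs (unit costs, the blind-mortality relative risk), beta for
unit-interval inputs (utilities, transition probabilities, the decline
rate), all fitted by the method of moments with SD = 25% of the point
estimate (gamma shape = (μ/σ)² = 16 under this rule).  Draws are
independent across parameters; each parameter has its own random
substream keyed by a hash of its name under the root seed, so adding or
removing a parameter leaves the other streams unchanged.  Cascade counts
stay fixed.  10,000 iterations re-run the full model and ledger
(≈ 12 s on one core).  The CEAC reports, at each willingness-to-pay
value, the fraction of iterations with positive net monetary benefit
(wtp × QALYs − cost).

Because parameters are sampled independently, about a quarter of draws
invert the utility ordering (u_STDR < u_blind), and in roughly 2–3% of
iterations the implied harm from averting blindness outweighs the
cataract benefit, making total QALYs negative.  Such draws count against
the programme at every willingness-to-pay, so at SD = 25% the CEAC
saturates slightly below 1; the saturation-at-1 property holds exactly
whenever every drawn QALY total is positive (e.g. at smaller SDs).  A
config flag can instead enforce `p_treated ≤ p_untreated` by resampling;
it is off by default because the published analysis states no ordering
constraint.

## Synthetic life table

The mortality input the published analysis used (official
Registrar-General data for India) has no public accession, so the
package generates a Gompertz–Makeham table: hazard
μ(x) = c + a·e^{bx}, qx = 1 − exp(−μ(x)), closed with qx = 1 at age 110.
Defaults (c = 0.0015, a = 1.8×10⁻⁵, b = 0.11) are calibrated with the
`implied_life_expectancy` helper so the diabetes-uplifted (×1.9)
remaining life expectancy at 59 is ≈ 12.8 years, the magnitude this
population operates at; general-population LE at 59 is ≈ 17.4 years.
The generator emulates smooth adult mortality only — no infant/accident
hump, no cohort effects, no sex split — so model outputs that depend on
the mortality input (life expectancies 12.10/12.58 years, per-person
gains 0.64/1.99) are of the right magnitude but are not replications of
the published 12.34/12.81 and 0.65/1.81; passing tests on the synthetic
table demonstrate correct model mechanics, not agreement with official
mortality data.  Any real single-year or abridged CSV table drops in
via `load_life_table` (abridged bands are expanded by holding the band
qx constant).

The synthetic cascade draws sequential binomials down the referral tree
(defaults: 31.3% referral, 50% attendance, 59.4% STDR diagnosis among
attendees, 70% treatment uptake; 48.1% ungradable among referrals, 20%
cataract-surgery uptake), seed-reproducible, for scenario analyses that
want sampling variation in the counts.

## Numerical choices and problem sizes

- Transition rows sum to 1 within 1e−12; trace occupancy is conserved
  within 1e−10 over 100+ cycles; the trace is validated against a
  100,000-individual microsimulation (3 Monte-Carlo SEs per state per
  cycle) and against the fundamental-matrix closed form
  π₀·δQ(I−(δQ)^H)(I−δQ)^{−1}u on constant-mortality tables (1e−9).
- Ties/degenerate inputs: zero QALY totals yield a NaN ICER reported as
  "indeterminate", never a division error; `annuitize` degenerates to
  straight-line at rate 0; an input life table without a closing qx = 1
  row is closed by appending one (warning logged).
- Test and verification sizes: 10⁶ draws for distribution-moment
  checks, 10⁵ individuals for the microsimulation, 10⁴ PSA iterations —
  the full published iteration count.

## Known limitations

- No progression from non-sight-threatening retinopathy into STDR, no
  bilateral-eye vision states, no treatment waning or repeat laser.
- Follow-up consultations after treatment, screening in later years,
  and counterfactual treatment of patients who would have been treated
  anyway are outside the ledger, as in the source analysis.
- QALY↔DALY conversion is not attempted; the GDP threshold is applied
  to QALYs directly.
- The acceptability probability at the GDP threshold depends on the
  mortality input and on exactly which inputs enter the PSA; with this
  package's assumed ten-parameter set and synthetic table it is ≈ 95%,
  higher than the 82% reported for the original analysis, whose exact
  PSA configuration is not recoverable from the published description.
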