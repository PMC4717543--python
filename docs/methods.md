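# Methods

`strokesim` is a closed-cohort, discrete-time state-transition (Markov) model
of ischemic stroke and ischemic heart disease (IHD) mortality in a population
aged 35–94, built to compare the deaths prevented or postponed (DPP) by
medical-treatment improvements versus population-level dietary and smoking
policies over 10- and 20-year horizons.

## The cohort model

**States.** `WELL`, `TIA`, `ACUTE_MINOR`, `ACUTE_MAJOR`, `POST_STROKE`, and
three absorbing death states `DEAD_STROKE`, `DEAD_IHD`, `DEAD_OTHER`.  The
acute states are one-year tunnel states: survivors of the first post-stroke
year always continue to `POST_STROKE` (keeping them in `ACUTE_*` would
re-apply first-year case fatality every cycle).  The published description of
this model family names these clinical states but its state diagram is not
machine-readable; this particular arrow set is a documented reconstruction,
not a verbatim copy.

**Cohort.** The model is a closed cohort that is stroke-free at the start
year (2012): per stratum, `count × (1 − prevalence)` persons start in `WELL`,
and prevalent cases are excluded from the accounting entirely.  The
consequence — benefits to existing stroke survivors are not counted — is a
known, deliberate limitation of this design.  Inputs arrive in 5-year age
bands (as published demographic sources do), but the engine tracks
single-year-of-age cohorts that look up their band's transition matrix, so
cohorts age across band boundaries; band counts are spread uniformly over
the band's five ages.  Persons passing age 94 leave the model ("aged out").

**Transition rows.** Per (sex, band) stratum, with `i` the annual first-ever
stroke incidence among the stroke-free:

| from | to | probability |
|---|---|---|
| WELL | ACUTE_MINOR / ACUTE_MAJOR | `i × (1 − s)` / `i × s` (severity split `s`) |
| WELL | TIA | `tia_incidence_ratio × i` |
| WELL | DEAD_IHD | observed IHD death rate |
| WELL | DEAD_OTHER | all-cause − CVD death rate |
| TIA | ACUTE_* | `tia_stroke_multiplier × i` (severity-split) |
| ACUTE_* | DEAD_STROKE | first-year case fatality (by severity) |
| ACUTE_* | POST_STROKE | remainder after deaths |
| POST_STROKE | ACUTE_* | `recurrence_multiplier × i` (severity-split) |
| POST_STROKE | DEAD_STROKE | observed chronic stroke death rate |
| POST_STROKE | DEAD_IHD / DEAD_OTHER | as in WELL |

Residual probability goes to the diagonal, so rows sum to one by
construction; any negative residual is a hard error naming the stratum and
row.  Rates are used directly as annual probabilities (they are small at
these ages); validity is enforced, not assumed.

Letting `WELL` individuals die of IHD at the observed IHD rates is a
deliberate modelling choice: the alternative (IHD deaths only via risk-factor
pathways) would make IHD deaths — and therefore the IHD component of every
policy's benefit — structurally zero in a stroke-free cohort.

**Cycle convention.** Annual cycles, one transition per cycle, no half-cycle
correction.  Headline outputs are *differences* between a baseline and a
scenario run on identical cohorts, which cancels most half-cycle bias.

**Engine parameters** (all exposed on `EngineParams`; none is a published
estimate):

| parameter | default | meaning |
|---|---|---|
| `severity_split_major` | 0.5 | fraction of incident strokes that are major |
| `tia_incidence_ratio` | 0.5 | TIA incidence as a multiple of stroke incidence |
| `tia_stroke_multiplier` | 2.0 | stroke risk after TIA vs WELL |
| `recurrence_multiplier` | 2.0 | recurrent-stroke risk post stroke vs first-ever |

## Incidence back-calculation

National stroke incidence is rarely observed; the model derives it from
prevalence, mortality and case fatality under a discrete illness-death model
with **zero remission** (structural: no function accepts a remission rate).
Within a band of width 5 years, susceptibles leave at rate `i + m` and the
diseased at `m + e`, with `m` the all-cause mortality rate and `e` the
excess hazard of the diseased; constant rates give a closed-form band
transition.  The excess hazard is derived from the severity-mixed first-year
case fatality as `e = −ln(1 − cf)` — a stated convention that overstates
chronic excess (first-year mortality exceeds later years), which biases the
recovered incidence slightly upward at old ages.

`estimate_incidence` inverts the forward map band by band with bracketed 1-D
root finding (Brent), which is exact to the solver tolerance (residual
< 1e-8) because the forward map is strictly increasing in incidence.  When
even zero incidence overshoots the target (prevalence falling faster than
differential mortality explains) the band is floored at zero and flagged.
Twelve prevalence points constrain eleven transitions, so the last band
(90–94) is unidentified and copies its neighbour.  An initial-guess argument
exists for interface compatibility but carries no statistical weight.

## Scenarios and effect application

Seven scenarios: `baseline` (nothing changes), and
{conservative, feasible, optimal} × {treatment, policy}.

* **Treatments** (12 therapies across acute care, secondary and primary
  prevention) move uptake from the 2012 baseline `u0` to a target `u1`.  The
  target transitions are scaled by `1 − (u1 − u0) × eligible_fraction × RRR`.
  Printed target uptakes are authoritative; the conservative column is *not*
  recomputed as `1.1 × u0` because some published targets deviate from that
  rule.  Eligibility fractions (e.g. the thrombolysis time window, atrial
  fibrillation prevalence for warfarin) are not published; the default 1.0
  is an upper-bound simplification and is configurable per treatment.
* **Policies** (salt, trans-fat, saturated fat, fruit & vegetables, smoking
  prevalence) change a population exposure by dose `d` against the effect's
  reference dose `d_ref`.  Scaling is log-linear in the risk ratio:
  `multiplier = exp((d/d_ref) × ln(1 − RRR))`, which preserves
  multiplicativity and can never produce a negative risk, unlike linear RRR
  scaling at large doses.  At the reference dose the multiplier is exactly
  `1 − RRR`.
* **Half effect for stroke.** The trans-fat and saturated-fat RRRs were
  quantified for coronary heart disease; they apply to IHD transitions at
  full RRR and to stroke transitions with the RRR halved (halving the RRR,
  not the log risk ratio, matching how the convention is stated in RRR
  units).
* **Scopes.** Each effect's outcome scope follows its published description:
  salt and fruit & vegetables are stroke-scoped, trans/saturated fat are
  both-scoped (half effect on stroke), and the smoking-prevalence effect —
  whose description names no outcome — is applied to both stroke and IHD,
  smoking being an established risk factor for both.  A stroke-scoped effect
  never touches an IHD transition (tested).
* **Targets.** Acute treatments scale `ACUTE_* → DEAD_STROKE`; secondary
  prevention scales `POST_STROKE → {ACUTE_*, DEAD_STROKE}` (and
  `→ DEAD_IHD` for both-scoped effects); primary prevention scales
  `WELL → ACUTE_*` (and `→ DEAD_IHD`); policies scale `WELL/TIA → ACUTE_*`
  and `WELL/POST_STROKE → DEAD_IHD`.  Whether the original model applied
  policy effects to incidence transitions, death transitions, or both is not
  fully specified in its published description; this mapping is a documented
  reconstruction.
* **Independence.** Joint effects multiply (no interaction structure), which
  tends to overstate combined benefit.  Rows are re-balanced through the
  diagonal after scaling, and a row whose multipliers are all exactly one is
  left untouched byte-for-byte, so null scenarios reproduce baseline deaths
  bit-for-bit.

**DPP.** `DPP = (cumulative stroke+IHD deaths, baseline) − (same, scenario)`
over the same cohort and horizon, total and by sex, with
`percent_reduction = DPP / baseline deaths × 100`.  Attribution shares come
from one-intervention-at-a-time runs normalised to 100% (marginal
decomposition of the joint run is the unimplemented alternative; one-at-a-time
is stated wherever shares are reported).

## Probabilistic sensitivity analysis

Effect sizes are drawn independently as lognormal risk ratios: `μ = ln(1 −
RRR)` (the median equals the central risk ratio) and `σ = (ln(1 − ci_low) −
ln(1 − ci_high)) / 3.92`.  Proportions, where the caller supplies intervals,
use a method-of-moments beta fit with `σ = width / 3.92`; the shipped inputs
print no intervals for uptakes or case fatality, so those default to point
masses.  Two published CIs do not bracket their central value (secondary
aspirin, saturated fat); they are loaded as printed and normalised — bounds
sorted, then widened to include the central value — with a logged warning,
never silently replaced.

Each draw redraws all distributed parameters jointly, reruns the full
baseline-versus-scenario pair, and records the DPP.  The 95% uncertainty
interval is the empirical 2.5–97.5 percentile range; the min–max range over
draws is reported alongside and labelled distinctly (published scenario
tables print sometimes one, sometimes the other).  Draws producing an
invalid transition table are rejected and redrawn; more than 10% rejections
aborts with diagnostics.  A seed and draw count fully determine the result.

## Synthetic data generator

The generator produces internally consistent bundles with the statistical
structure the model assumes, emulating a middle-income national profile:

* population pyramid strictly declining over 5-year bands (band-to-band
  ratios drawn in 0.70–0.88), ~10⁶ persons by default, men slightly
  outnumbering women at these ages;
* Gompertz all-cause mortality `A·exp(b·(age−37))` with `A ≈ 0.0026` (men) /
  `0.0017` (women) and `b ≈ 0.085`, spanning roughly 0.002/yr at 35–39 to
  0.2–0.3/yr at 90–94;
* CVD fraction of deaths rising from ~18% to ~44% with age, IHD taking
  40–48% and stroke 18–25% of CVD deaths;
* stroke prevalence logistic in age with a plateau near 4.5–5.5%;
* first-year case fatality ramping with age, minor ~0.04–0.20 and major
  ~0.20–0.52.

Seed-level jitter perturbs global parameters only, never individual bands,
so the monotone age gradients hold exactly for every seed.  These magnitudes
were fixed once as a realistic profile that also guarantees the engine's
hard validity precondition (all transition rows stochastic) across seeds.
What the generator does **not** emulate: secular trends, regional and
socioeconomic heterogeneity, migration, correlated measurement error between
tables.  Tests passing on synthetic bundles therefore demonstrate the
*mechanics* (conservation, inversion, ordering, uncertainty propagation),
not calibration to any real country's mortality.

## Numerical choices and problem sizes

* Transition rows must sum to 1 within 1e-12; conservation of persons is
  enforced at 1e-9 × cohort per cycle.
* Incidence inversion: Brent root finding with `xtol = 1e-14`, residual
  tolerance 1e-8, bracket expanded by doubling.
* Near-degenerate band dynamics (`i + m ≈ m + e`) switch to the analytic
  limit to avoid cancellation.
* The default analysis runs a ~10⁶-person cohort (as state occupancy masses,
  not individuals) over 10 and 20 annual cycles; PSA uses 1000 draws.  The
  verification suite cross-checks the matrix engine against a
  200,000-individual microsimulation sharing its transition tables
  (agreement within 3 binomial standard errors) and re-inverts 50 randomly
  generated incidence truths to within 1% per band.

## Known limitations

* No lag between exposure change and mortality change; scenario targets are
  reached instantly at the first cycle.
* Independent effects overstate joint benefit; no interaction or mediation.
* Closed cohort: no new 35-year-olds enter after the start year, and
  prevalent stroke survivors at baseline receive no benefit.
* `DEAD_OTHER` competing mortality is age-band constant within a cycle; no
  period improvement in background mortality over the horizon.
* The TIA pathway and recurrence multipliers are conventions, not estimates;
  sensitivity to them is exposed through `EngineParams` but not part of the
  default PSA.
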