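# Methods

This note records the modelling choices behind `retinasim`: the pathway
model and its assumptions, the parameters that matter and their defaults,
what the synthetic cohort generator does and does not emulate, and the
numerical conventions.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Care pathway model

Patients hold exactly one condition — nAMD, DR, or pooled medical retina
(MR, which includes retinal vein occlusion; no RVO-specific parameters are
available, so RVO is not split out).  A patient is either *treated* (ever
receives an injection or laser) or *observation-only* (monitoring reviews
only).  Time within a patient is organised into care years of 365 days
starting at first attendance; parameters are indexed by year 1, 2, 3, with
year 3 applying to every later year.

Per care year, a treated patient draws an annual injection count and a
follow-up (FU) assessment count from the regimen's count distributions; an
observation patient draws a monitoring-review count.  Visits are spread
evenly over the year.  At the year boundary a Bernoulli discharge draw with
probability P(condition, status, year) decides whether the patient exits
permanently.  Discharge is independent of attendance outcomes — a
simplification; no outcome (visual acuity) modelling is attempted.

### Regimens

* **PRN** (as needed): injection means 4 / 3 / 2.5 per year in years
  1 / 2 / 3; FU assessments are separate visits (means 4.8 / 4 / 3.6).
* **Treat and extend**: injection means 8 / 6 / 5.  (The year-3 figure is
  quoted as "4–5" in one place and 5 in another in the motivating analysis;
  the default is 5, configurable.)  The assessment is folded into the
  injection visit (`combined_assessment`), so each injection also counts as
  a delivered follow-up assessment in the activity KPI, and only the excess
  of the FU draw over the injection draw remains as standalone FU visits.
  Consequence: under T&E the follow-up *assessment* KPI rises while
  standalone clinic visits barely do — injection-bed load is where the
  regimen bites.

T&E is parameterised by annual counts, not by an interval-extension state
machine: only annual counts are quoted for the motivating service, and the
downstream KPIs depend on counts alone.

### Count distributions

Annual counts are small integers observed between 1 and 14 per
patient-year.  They are modelled as `round(X)` clipped to [1, 14] for
X log-normal, and are *specified by the natural-scale mean and SD of the
integer variate* — matching how service averages are quoted.  Two
consequences:

* Not every (mean, sd) is attainable: an integer variate with mean 1.4 has
  sd ≥ √0.24 ≈ 0.49, so the quoted (1.4, 0.37) pair for observation FUs is
  infeasible as stated.  The calibrator matches the mean exactly (every
  downstream average depends on it) and gets as close as the support allows
  in sd.  The pair is plausibly a natural-scale mean with a *log-scale* SD
  (0.37 is what a log-normal fit to counts concentrated on {1, 2, 3} with
  mean 1.4 reports as sdlog); the natural-scale reading is kept because the
  value is quoted alongside natural-scale averages.
* Fitting uses the **discretised likelihood** (each integer count
  contributes its rounding-cell probability), not log-moment MLE on raw
  counts: on rounded data the log-moment fit under-reports the mean by
  ~0.05 at mean 1.4, while the discretised MLE tracks the sample mean.
  Below 30 observations, or when all counts are equal (the scale parameter
  degenerates), the fitter falls back to the empirical distribution.

Where only a mean is quoted, the SD defaults to mean × (0.37/1.4) — the one
fully specified coefficient of variation.  Sampling is by inverse CDF, so
under common random numbers a larger-mean distribution with the same CV
yields pointwise larger draws; the paired T&E-vs-PRN ordering tests rely on
this.

### Discharge model

P(c, s, y) = discharges(c, s, y) / at-risk(c, s, y), where a patient is at
risk in year y if their observation span covers y care years and they were
not discharged earlier.  Aggregate shares are reported against the whole
cohort (treated ≈ 1 %, observation ≈ 19 % of all patients), the convention
of the itemised reference counts; the within-status shares (≈ 7 % and
≈ 23 %) are also exposed (`status_share`).

### Virtual-clinic eligibility

Eligible = attended at least once in (as_of − 24 months, as_of] AND no
*attended* injection or laser in (as_of − 6 months, as_of] AND not
discharged.  Windows are half-open (exclusive old end, inclusive at
`as_of`); laser counts as treatment (the conservative reading of
"observation only"; the laser-inclusive alternative would only enlarge the
set).  DNA'd visits count neither as attendance nor as treatment.

## Forecasting

Arrival forecasting is an ordinary-least-squares additive decomposition:
intercept + linear trend + 11 month-of-year contrasts, requiring ≥ 24
months of history, forecasting 12 months by default, then scaling month m
by (1 + g)^(m/12) for annual population growth g and flooring at zero.  The
original analysis used an external forecasting package with unspecified
model selection; a fixed transparent smoother is preferred for
reproducibility.  Accuracy is 100 − MAPE clipped to [0, 100] (zero-actual
months excluded), the simplest reading of "accuracy ≈ 90–99 %".  Simulated
arrivals are Poisson with the forecast monthly mean, drawn by inverse
transform so that larger means give pointwise larger counts under common
random numbers.

## Engine conventions

* Time: integer days from scenario start; day 0 is a Monday; a month is
  365/12 days; weekly resource schedules repeat with period 7.
* Booking: earliest day ≥ due date with a free slot *and* enough remaining
  minutes in every required resource pool.  The slot calendar is derived
  from the clinic-session schedule at `slot_minutes` granularity unless
  supplied explicitly.  One rebooking attempt after a DNA/cancellation,
  within `rebook_within_days`; the rebooked appointment attends.  Demand
  that cannot be placed before the horizon is recorded as overflow, never
  dropped, and capacity shortfall is a reported finding, not an error.
* Tie-breaking: simultaneous events are ordered by (day, patient index,
  visit-type rank, planning sequence) — fully deterministic.
* Utilisation = busy minutes / scheduled minutes per pool per month; busy
  can never exceed available because booking checks remaining minutes.
* Replications: default 100 in the shipped defaults, 15-month horizon with
  a 3-month warm-up excluded from KPIs (none of these are externally
  specified; they give stable monthly means at desk scale).  Tests and the
  packaged examples run far fewer replications, stated inline.
* Random streams: per replication and patient, separate generators for the
  care-path draws (status, counts, discharge) and for non-attendance, and
  per month-condition generators for arrivals, all keyed from the scenario
  seed.  Scenario levers therefore change only the draws they govern.

## Accounting

Revenue and cost are per attended visit (`TariffTable`); surplus ≡ revenue
− costing, enforced within £1 (the reference table's printed surplus is £1
off its own subtraction, so the identity is asserted at that tolerance).
Percentage changes are integer-rounded half away from zero.  The follow-up
KPI counts hospital visits delivering an assessment (standalone FU visits
plus combined-assessment injections); virtual reviews are reported
separately.  A virtual review is billed at the same follow-up tariff as a
hospital review (making the diversion revenue-neutral, as observed for the
motivating service) and costed at £37.50, the midpoint of the quoted
£30–45 community band, against £89 for the hospital review.  Fixed costs
of running a virtual clinic are *not* modelled, so here diversion lowers
costing, whereas the motivating service reported a small increase from
set-up and running costs.

## Synthetic cohort generator

The generator emulates the *composition* of the reference cohort exactly:
attended appointment counts per activity category and condition, discharge
counts per (condition, status, year), case-mix patient counts, and the
eligible-set size are allocated cell by cell, not sampled — only visit
dates and patient assignments are random.  Specifics:

* The reference cohort total follows the itemised table (6,530; the
  running-text figure 6,520 is a rounding of the same cohort).
* The split of the 1,025 treated patients across conditions is not
  itemised anywhere; the shipped 400/280/345 (AMD/DR/MR) split is an
  assumption chosen to be feasible against the activity table at ≤ 14
  injections per patient-year.
* Injections within a patient-year sit at regular intervals with ± 7-day
  uniform jitter (smooth workload, no invented seasonality).
* Patients who must not appear eligible are confined to the first 12
  months of the window; treated non-discharged patients carry one
  treatment inside the final 6 months.  This makes the planted eligible
  set exact but means the generator does not emulate realistic attendance
  *timing* for those groups — a green eligibility test establishes the
  filter's correctness, not temporal realism.
* DNA (5 %) and cancellation (3 %) rows are appended at stated assumed
  rates; no rates are quoted for the service.

## Shipped defaults and their status

`defaults.yaml` carries resource schedules, visit durations, tariffs and
booking rules.  The motivating service's actual values were not available;
every entry is ASSUMED and documented as such in the file.  Consequently
absolute utilisation, costing and revenue levels produced with the
defaults are illustrative only, and all acceptance-level checks involving
them are relative or structural (orderings under paired seeds, bounds,
identities).  The desk-scale prevalent caseload (1,000 patients, 18.2 %
treated, 172 eligible) is the 5,206 active patients of the reference
service scaled by ≈ 0.19 to keep default runs interactive.

## Known limitations

* No laser visits are generated by the engine (they are calibrated and
  billed as categories, but laser demand shares generic clinic resources
  and is small); no intra-day queueing; no staff rostering.
* Discharge and attendance are independent; no censoring-adjusted survival
  estimation of discharge.
* One growth scalar per run (no age stratification); no prediction
  intervals on forecasts.
* Newly arriving simulated patients never become virtual-clinic eligible
  within the default 15-month horizon (eligibility needs a 24-month
  history); diversion applies to the prevalent caseload.
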