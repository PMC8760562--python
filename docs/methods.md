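# Methods

## The population model

The simulator emulates the incidence pattern of a very rare, life-limiting
genetic disease: exactly one affected birth per year, at integer times
t = 1..500 on the simulation clock.  Individual *t*'s lifespan is one draw
from a Weibull distribution whose (mean, median) follow the scenario
schedule for that birth year; individuals are mutually independent.  The
long 464-year lead-in before the observation window [465, 500] lets the
standing population reach stationarity (every scheduled mean is far below
the lead-in), so window-based estimators see a mature mix of old survivors
and recent births — the situation a real death-record review faces.

Deliberate simplifications, and what they imply for interpreting results:

* **No within-year birth jitter.**  Births happen at exact integer times.
  Sub-year jitter would perturb window membership by far less than the
  Monte-Carlo spread of any reported quantity.  One visible consequence: the
  individual born exactly at year 500 enters the prospective sample with
  zero follow-up (a censored record at time 0), which is why censored
  observation times are allowed to be 0 while event times must be positive.
* **Deterministic unit birth prevalence.**  No Poisson variation in birth
  counts, no diagnostic ascertainment, no competing risks.  Passing tests
  therefore demonstrate properties of the *estimators* under a clean
  incidence process, not robustness to demographic noise.
* **Weibull lifespans.**  A two-parameter family pinned down by the target
  mean and median; no covariates, no Gompertz-style old-age acceleration.

## Scenario schedules

All scenarios start from base targets (mean 25.3, median 20.8) years.
Scenario 1 keeps them constant; scenario 2 adds 0.05·(t−1) years to both;
scenario 3 follows scenario 2 until year 460 and freezes at (48.25, 43.75);
scenario 4 is constant until year 460 and then adds 0.5·(t−460) to both.
Both moments shift by the same additive amount — an equal shift is the only
choice consistent with the analytic true medians over the window (43.75 and
32.05 for scenarios 3 and 4); a shape-preserving scale change would move the
median by a different amount than the mean.  True values are arithmetic
averages of the scheduled targets over the 36 window birth years 465..500
inclusive.

The inversion from (mean, median) to (scale, shape) solves the scale-free
ratio equation by bisection-safe root finding (`brentq`, relative tolerance
1e−12) on the shape bracket [0.2, 7.0].  The ratio Γ(1+1/k)/(ln 2)^(1/k) is
strictly decreasing there, which guarantees a unique root; beyond k ≈ 7.1 it
turns around and creeps back toward 1, so the bracket is deliberately kept
inside the monotone region.  All scheduled ratios are ≈ 1.216, solved at
shapes near 1.3.  Per-year parameters are solved once per schedule and
cached, so a 1000-replicate experiment performs 500 inversions, not 500,000.

## Sampling the population

With window [465, 500] and horizon 500 (all boundaries closed):

* period sample — complete lifespans with 465 ≤ death ≤ 500;
* cohort sample — complete lifespans with 465 ≤ birth ≤ 500 (36 records,
  deaths after year 500 included);
* retrospective sample — every individual with death ≥ 465; observed time
  min(death, 500) − birth, event iff death ≤ 500.  Entry is at birth: the
  left truncation inherent in "everyone who died since year 465" is
  deliberately *ignored*, because that is precisely the bias mechanism under
  study;
* prospective sample — every individual with birth ≥ 465, censored at the
  horizon the same way.

Censoring weights: event records always carry weight 1; censored records
carry 1 (`unit`), a fixed w ∈ (0, 1] (0.1 by default — a value reported to
work well in practice), or the fraction of uncensored records in the sample
(`uncensored_percentage`), computed per sample per replicate.

## Estimators and conventions

The weighted product-limit curve uses S(t_j) = Π_{i≤j}(1 − D_i/Y_i), with
D_i the total weight of events at t_i and Y_i the total weight of records
with observed time ≥ t_i.  Censored records tied with an event time remain
at risk for that event (censoring "just after" deaths).  With unit weights
this is the standard Kaplan–Meier estimator (verified against lifelines to
machine precision in the test suite); as the censored weight tends to zero
it tends to the empirical curve of the events alone.

Median conventions matter at these sample sizes and are chosen to mirror how
such analyses are run in practice:

* **KM medians and period medians** use the first-crossing rule: the
  smallest event time with S(t) ≤ 0.5 (a float tolerance of √ε absorbs
  rounding in the cumulative product), "not reached" if the curve never gets
  there.  The period median is *defined* as the median of the uncensored KM
  curve — the ⌈n/2⌉-th order statistic — so the equivalence between the
  period approach and the no-censoring retrospective KM holds exactly on
  every replicate, not just in expectation.
* **Cohort medians** use the ordinary midpoint-interpolated sample median,
  the standard descriptive summary for a fully observed cohort.  At n = 36
  the two conventions differ by about half an inter-order-statistic gap
  (~0.9 years at the base survival), which is visible in the summary tables.

Mean estimates are always complete-data arithmetic means; restricted-mean
survival and KM-based means are out of scope, as are variance estimates and
confidence intervals for the curves.

## The experiment layer

A replicate simulates one population and computes all estimates; an
experiment runs 1000 replicates per scenario (the study's design size; the
full four-scenario experiment takes a few seconds).  Replicate r of scenario
s draws its generator from a seed sequence keyed on (base seed, s), so
scenarios are mutually independent and every result is reproducible from one
integer.  Undefined estimates (a KM median that is never reached, or an
empty period sample — the latter essentially impossible at ~35 expected
window deaths) are carried as missing and excluded from averages; each
summary cell records the fraction of replicates in which it was defined and
is reported as NA when that fraction falls below 0.5.  That threshold
reproduces the qualitative pattern of sparse-event scenarios: under
scenarios 2–3 only ~5 of the 36 prospectively followed individuals die
within ≤35 years of follow-up, the curve rarely reaches 0.5, and the
prospective-KM cell is not reportable.

Aggregation reports, per scenario and estimator: the across-replicate mean
and standard deviation (ddof = 1), the defined fraction, and the bias
(true − averaged estimate) for period and cohort estimates.  Human-readable
CSV output is rounded to 2 decimals with NA rendered literally; JSON output
keeps full precision, sorted keys, and is byte-stable across reruns with the
same seed.

## Known limitations

* The weighted-KM weighting scheme is one concrete choice (case weights in
  both risk set and event totals).  It is exact in both limits (standard KM
  at w = 1, events-only curve as w → 0) and monotone in w, but other
  weighting conventions exist and can shift medians by a few tenths of a
  year at these sample sizes.
* Conditioning on "median defined" induces selection effects in
  sparse-event settings: the averaged prospective KM median in scenario 4
  is computed over the ~69% of replicates where the curve reaches 0.5, and
  such conditional averages are sensitive to exactly how definedness is
  resolved.  The defined fraction is always reported to keep this auditable.
* Results quantify estimator behaviour under the scheduled Weibull models
  only; they are a sensitivity analysis, not a forecast for any real
  population.
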