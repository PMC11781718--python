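# Methods

## Model structure

`ossim` implements a state-transition model of a woman's life from age 20 to
85 in 65 annual cycles.  The base health states are: healthy; healthy with
non-gynecologic abdominal surgery; healthy with other gynecologic surgery;
healthy with tubal ligation; healthy with hysterectomy; healthy with
salpingectomy; healthy with hysterectomy + salpingectomy; healthy with
hysterectomy + bilateral salpingo-oophorectomy (HE+BSO); ovarian cancer; and
the absorbing states death from ovarian cancer and death from other causes.
Each living, pre-cancer state carries a hazard ratio (HR) multiplying the
age-specific ovarian-cancer incidence.  A surgery event moves a woman to a
new surgical state only if that strictly increases her risk reduction — the
HR acts as a ratchet and can never rise along a trajectory.

Two pieces of history matter: time since salpingectomy (the OS effect takes
force only after a latency L, base 5 years) and time since cancer diagnosis
(excess mortality and follow-up costs for 10 and 5 years respectively).
The cohort engine removes this history dependence exactly by *tunnel
expansion*:

* salpingectomy states are split by years-since-OS k = 1 … ⌈L⌉−1 plus an
  "effective" state, and additionally by the **pre-OS fallback HR** — the HR
  that applies during latency.  The fallback is min(HR before OS, fallback of
  the new base state): 1.0 for a salpingectomy from a baseline-risk state,
  the hysterectomy HR (0.79) when OS is concomitant with hysterectomy, and
  the tubal-ligation HR (0.72) when OS follows a ligation.  Carrying the
  fallback in the state keeps the expanded chain exactly Markov even on rare
  paths (e.g. sterilization-OS followed by hysterectomy during latency).
* the cancer state is split by years-since-diagnosis d = 1 … 10; afterwards
  survivors move to a post-cancer survivor state with background mortality
  and population utility only.

With the base case this yields a ~45-state chain whose one-cycle operator is
validated to be row-stochastic to 1e-12.  The microsimulation replays the
identical operator at the individual level, so the cohort engine is its
exact oracle.

### Within-cycle event order

Competing annual events are resolved in a fixed, documented order by
partitioning a single uniform draw per woman-cycle: (1) death from
background (net) mortality; (2) death from ovarian cancer (post-diagnosis
states); (3) ovarian-cancer incidence at the state-modified hazard;
(4) surgery, mutually exclusive by category in the priority HE+BSO >
hysterectomy > sterilization > other-gynecologic > non-gynecologic; else no
event.  Input validation guarantees the competing probabilities sum to at
most 1 at every age.

Because all strategies consume the same uniform matrix (a counter-based
Philox stream keyed by the seed), runs use common random numbers: paired
strategy contrasts difference out most Monte-Carlo noise, and results are
bit-reproducible for a given seed and configuration.

### Rewards, half-cycle correction, discounting

Occupancy rewards (life years, QALYs, annual follow-up cost) use a
trapezoidal half-cycle convention: cycle t contributes ½·(v_t + v_{t+1}),
where v is the state value at the cycle boundaries (0 when dead), and a half
cycle is deducted at model entry.  An event-free lifetime therefore accrues
64.5 undiscounted life years over 65 cycles, and a state entered or left
mid-horizon receives half weight in the transition cycle.  One-time amounts
(OS cost at surgery, primary treatment at diagnosis, palliative cost at
cancer death) are booked in the event cycle.  Cycle t is discounted by
(1+r)^−t with r = 3 %/yr for both costs and effects; both the effect-side
and cost-side half-cycle weightings can be switched off independently
(`half_cycle_effects`, `half_cycle_costs`), since conventions differ across
modeling tools.

## Key parameters

| parameter | base | unit | note |
|---|---|---|---|
| HR hysterectomy / tubal ligation / salpingectomy / HE+BSO | 0.79 / 0.72 / 0.35 / 0.06 | – | cohort-study estimates; salpingectomy 95 % CI 0.17–0.73 |
| OS latency L | 5 | yr | fractional L supported: the HR is blended linearly within the straddling year, so threshold search on L is well posed |
| OS cost | 216.19 | € | 13 min × €16.63/min OR time; sensitivity range €66.52–748.35 (4–45 min) |
| cancer primary / follow-up / palliative cost | 30,133.22 / 36,366.49 ×5 yr / 12,103 | € | direct medical costs, payer perspective |
| cancer utility | 0.61 | – | 0.23·0.81 (non-advanced) + 0.77·0.55 (advanced); applied for the 10 post-diagnosis years, then population utility (the duration is a modeling choice aligned with the excess-mortality horizon) |
| discount rate | 0.03 | 1/yr | varied 0–5 % |
| GDP per capita | 47,183 | € | 1× / 2× cost-effectiveness benchmarks |
| OS uptake | 1.0 | – | fraction of eligible surgeries where OS is accepted; exposed as a parameter |
| age floor, other/non-gyn OS | 40 | yr | hysterectomy and sterilization OS at any age |

Design choices on points the model family leaves open: HE+BSO and
hysterectomy HRs apply immediately (the latency is attached to the OS effect
only); sterilization under strategies I–III is performed as bilateral
salpingectomy (HR 0.35 path) and under IV as tubal ligation (HR 0.72);
HE+BSO is only reachable from states with an intact uterus; OS is performed
— and billed — only when the ratchet admits the transition (an OS that
cannot reduce risk, e.g. when a sampled salpingectomy HR exceeds the current
state's HR, is not carried out).  Money is kept at cent precision for
reporting, probabilities at full double precision.

## Synthetic inputs

The registry tables behind the original parameterization are not
redistributed; `ossim.synth` generates complete substitutes with the same
statistical structure:

* background mortality (net of ovarian-cancer deaths): Gompertz–Makeham
  hazard, ≈ 1.7·10⁻⁴ at 20 rising to ≈ 5 % at 85;
* ovarian-cancer incidence: discretized gamma-density bump peaking in the
  late 60s, scale and location calibrated (via the no-OS cohort engine
  itself) to a lifetime risk of 1:86 and a mean diagnosis age of 64;
* post-diagnosis mortality: constant annual probability calibrated to a 77 %
  ten-year case fatality;
* surgery schedules: unimodal gamma bumps (hysterectomy, HE+BSO,
  sterilization truncated above 55) and, for the two categories only counted
  from age 40, a decaying-exponential (other-gyn, cesarean-dominated) and a
  broad bump (non-gyn), calibrated to survival-weighted mean ages 52 / 33 /
  46 / 60 and lifetime proportions 13 % / 3 % / 8 % / 22 %;
* sterilization is stored as the inpatient schedule scaled so that 2.5× of
  it reaches the 5 % lifetime population proportion, mirroring the
  inpatient-to-population calibration.

All calibrations are monotone 1-D bisections run in a fixed order and
alternated twice where targets interact; the result is deterministic given
the seed.  Seeds jitter the underlying shape constants by ±5 % before
calibration, so different seeds give genuinely different curves with the
same anchors.  The generator reproduces curve *shapes* and headline
epidemiology, not provenance: passing tests demonstrate correctness of the
engines and analysis machinery under realistic input structure, not
agreement with any specific national registry.  Consequently base-case
outputs (prevented fractions, ICERs, breakeven costs) are of the published
magnitude but not digit-identical to any published table.

## Numerical choices

* Threshold search and breakeven use bisection on the noise-free cohort
  engine: OS cost to ±€0.5, HRs to ±0.005, latency to ±0.1 yr, discount
  rate to ±0.0005.  The incremental cost is affine in the OS unit cost
  (slope = expected discounted salpingectomies per capita), which the tests
  exploit as an independent oracle.
* The sterilization-multiplier calibration bisects to x-convergence and
  verifies the lifetime proportion within ±0.1 percentage points.
* PSA defaults: log-normal salpingectomy HR with median 0.35 matching the
  0.17–0.73 CI (σ ≈ 0.372, samples clipped to ≤ 1), uniform OS cost on
  [66.52, 748.35]; both are explicit, overridable assumptions.
* Degenerate inputs are well-defined: zero prevented cases report NaN for
  "salpingectomies per prevented case" and undefined ICERs rather than
  raising; a zero-effect comparison is classified by cost sign alone.
* Ages at OS and diagnosis are recorded as the age at the start of the event
  cycle; dispersion is the population SD over events.

## Problem sizes

The cohort engine is exact and runs in milliseconds per strategy.  The
bundled analyses use paired microsimulations of 150,000 women (acceptance
script) with Monte-Carlo SEs reported, and 200-sample PSAs; the test suite
uses 20,000–60,000 women.  These sizes keep per-capita outcome SEs well
below the contrasts of interest while the full suite completes in seconds;
`convergence_scan` reproduces the ~1/n variance decay and reports the n at
which the prevented-case fraction stabilizes to a chosen relative SE.

## Limitations

* Inputs do not distinguish histological subtypes or high-risk (e.g. BRCA)
  subpopulations; results are population averages.
* Only inpatient-sector direct medical costs are modeled; societal costs,
  costs of the index surgeries themselves, and complications of OS (assumed
  risk-neutral) are excluded.
* Annual cycles with a fixed within-cycle event order; no continuous-time
  event timing.
* The 0.61 cancer utility's duration (10 years) and the post-survivor
  reversion to population utility are modeling choices; both are
  configurable.
* The synthetic generator targets structure and anchors, not any specific
  registry; national extrapolations in reports are linear scalings of the
  prevented fractions.
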