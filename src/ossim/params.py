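"""Model inputs for the opportunistic-salpingectomy (OS) lifetime model.

This module defines every input of the decision-analytic model: the health
states, age-indexed annual transition probabilities (``AgeSchedule``), the
ovarian-cancer hazard ratios attached to prior surgery, utilities, costs,
the four implementation strategies, and the bundled ``ParameterSet`` with
its validator and delimited-text (CSV + YAML) round-trip.

Conventions
-----------
* Ages are integer years in [20, 85]; schedules are dense (one value per age).
* Probabilities are annual event probabilities in [0, 1].
* Monetary values are euros, rounded to cents where reported.
* Hazard ratios (HRs) multiply the baseline age-specific ovarian-cancer
  incidence; lower HR means stronger risk reduction.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

AGE_MIN = 20
AGE_MAX = 85
N_AGES = AGE_MAX - AGE_MIN + 1  # 66 single-year bins


class ModelError(Exception):
    """Base class for errors raised by this package."""


class InvalidInputError(ModelError, ValueError):
    """A scalar operation received an out-of-domain argument."""


class ValidationError(ModelError, ValueError):
    """A parameter table or set violates an invariant.

    ``problems`` is a list of human-readable messages, each naming the
    offending table cell (age row and column) where applicable.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class CalibrationError(ModelError, RuntimeError):
    """A calibration target is unreachable within the admissible range."""


class HealthState(str, Enum):
    """Base health states of the transition diagram.

    DEATH_OTHER and DEATH_OC are absorbing.  Every non-absorbing,
    non-cancer state carries an ovarian-cancer hazard ratio (1.0 for the
    surgery states that confer no risk reduction).
    """

    HEALTHY = "HEALTHY"
    NONGYN_SURG = "NONGYN_SURG"
    OTHER_GYN_SURG = "OTHER_GYN_SURG"
    TUBAL_LIGATION = "TUBAL_LIGATION"
    HYSTERECTOMY = "HYSTERECTOMY"
    SALPINGECTOMY = "SALPINGECTOMY"
    HE_SALPINGECTOMY = "HE_SALPINGECTOMY"
    HE_BSO = "HE_BSO"
    OVARIAN_CANCER = "OVARIAN_CANCER"
    DEATH_OTHER = "DEATH_OTHER"
    DEATH_OC = "DEATH_OC"


ABSORBING_STATES = frozenset({HealthState.DEATH_OTHER, HealthState.DEATH_OC})

#: Surgery event categories (mutually exclusive within a cycle), in the
#: fixed competing-risk priority order used by both engines.
SURGERY_CATEGORIES = ("he_bso", "hysterectomy", "sterilization", "other_gyn", "nongyn")


@dataclass(frozen=True)
class AgeSchedule:
    """A dense mapping from integer age (20-85) to an annual value.

    Used both for event probabilities and for the age-specific population
    utility.  Values are stored as a length-66 float array indexed by
    ``age - 20``.
    """

    p: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.p, dtype=float)
        if arr.shape != (N_AGES,):
            raise ValidationError(
                f"AgeSchedule must cover every age in [{AGE_MIN}, {AGE_MAX}] "
                f"(expected {N_AGES} values, got {arr.shape})"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("AgeSchedule contains non-finite values")
        object.__setattr__(self, "p", arr)

    @property
    def ages(self) -> np.ndarray:
        return np.arange(AGE_MIN, AGE_MAX + 1)

    def at(self, age):
        """Value at integer age(s); ages outside [20, 85] are rejected."""
        idx = np.asarray(age) - AGE_MIN
        if np.any(idx < 0) or np.any(idx > N_AGES - 1):
            raise InvalidInputError(f"age {age} outside [{AGE_MIN}, {AGE_MAX}]")
        return self.p[idx]

    @classmethod
    def constant(cls, value: float) -> "AgeSchedule":
        return cls(np.full(N_AGES, float(value)))

    @classmethod
    def from_mapping(cls, mapping) -> "AgeSchedule":
        missing = [a for a in range(AGE_MIN, AGE_MAX + 1) if a not in mapping]
        if missing:
            raise ValidationError(f"AgeSchedule mapping missing ages {missing[:5]}...")
        return cls(np.array([mapping[a] for a in range(AGE_MIN, AGE_MAX + 1)], float))

    def scaled(self, factor: float) -> "AgeSchedule":
        return AgeSchedule(self.p * float(factor))

    def __eq__(self, other):
        return isinstance(other, AgeSchedule) and np.array_equal(self.p, other.p)

    def __hash__(self):
        return hash(self.p.tobytes())


@dataclass
class HazardRatioSet:
    """Ovarian-cancer hazard ratios after prior surgery, plus the OS latency.

    Base-case values follow the population-based cohort literature:
    hysterectomy 0.79, tubal ligation 0.72, bilateral salpingectomy 0.35,
    hysterectomy + bilateral salpingo-oophorectomy 0.06.  The salpingectomy
    effect takes force ``latency_years_os`` years after surgery (base 5);
    fractional latencies are honoured by blending within the straddling year.
    """

    hr_hysterectomy: float = 0.79
    hr_tubal_ligation: float = 0.72
    hr_salpingectomy: float = 0.35
    hr_he_bso: float = 0.06
    latency_years_os: float = 5.0

    def validate(self) -> list:
        problems = []
        for name in ("hr_hysterectomy", "hr_tubal_ligation", "hr_salpingectomy", "hr_he_bso"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                problems.append(f"{name}={v} outside (0, 1]")
        if self.latency_years_os < 0:
            problems.append(f"latency_years_os={self.latency_years_os} negative")
        return problems


@dataclass
class UtilitySet:
    """Health-state utilities.

    The ovarian-cancer utility (base 0.61) is the prevalence-weighted mean of
    non-advanced (23%, 0.81) and advanced (77%, 0.55) disease and applies for
    ``oc_utility_years`` after diagnosis, after which survivors revert to the
    age-specific population utility.
    """

    population_utility: AgeSchedule = field(
        default_factory=lambda: AgeSchedule(0.95 - 0.0018 * np.arange(N_AGES))
    )
    u_oc: float = 0.61
    u_oc_early: float = 0.81
    u_oc_advanced: float = 0.55
    p_early: float = 0.23
    p_advanced: float = 0.77
    oc_utility_years: int = 10

    def validate(self) -> list:
        problems = []
        for name in ("u_oc", "u_oc_early", "u_oc_advanced"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name}={v} outside [0, 1]")
        if abs(self.p_early + self.p_advanced - 1.0) > 1e-9:
            problems.append(
                f"p_early + p_advanced = {self.p_early + self.p_advanced} != 1"
            )
        u = self.population_utility.p
        if np.any(u < 0) or np.any(u > 1):
            bad = int(np.argmax((u < 0) | (u > 1))) + AGE_MIN
            problems.append(f"population_utility outside [0, 1] at age {bad}")
        return problems


@dataclass
class CostSet:
    """Direct medical costs (euros) and discounting.

    OS cost is the extra operating-room time (13 min base) at the average
    German OR minute price; ovarian-cancer treatment comprises a one-time
    primary-therapy cost at diagnosis, annual follow-up (incl. maintenance
    therapy) for ``followup_years``, and a one-time palliative cost at death
    from ovarian cancer.  The cost-effectiveness benchmark is GDP per capita.
    """

    os_cost: float = 216.19
    os_minutes: float = 13.0
    or_minute_price: float = 16.63
    oc_primary: float = 30133.22
    oc_followup_annual: float = 36366.49
    followup_years: int = 5
    palliative: float = 12103.00
    discount_rate: float = 0.03
    gdp_per_capita: float = 47183.0

    def validate(self) -> list:
        problems = []
        for name in ("os_cost", "os_minutes", "or_minute_price", "oc_primary",
                     "oc_followup_annual", "palliative", "gdp_per_capita"):
            if getattr(self, name) < 0:
                problems.append(f"{name}={getattr(self, name)} negative")
        if not (0.0 <= self.discount_rate <= 1.0):
            problems.append(f"discount_rate={self.discount_rate} outside [0, 1]")
        expected = round(self.os_minutes * self.or_minute_price, 2)
        if abs(self.os_cost - expected) > 0.01 + 1e-9:
            problems.append(
                f"os_cost={self.os_cost} inconsistent with "
                f"os_minutes*or_minute_price={expected}"
            )
        return problems


@dataclass(frozen=True)
class Strategy:
    """An OS implementation strategy: which surgery categories trigger OS.

    I   - OS at any suitable abdominal surgery (gyn. + non-gyn.);
    II  - OS at any suitable gynecologic surgery;
    III - OS at hysterectomy or in lieu of tubal ligation (current practice);
    IV  - no OS (reference).

    ``age_minimum_other`` (base 40) applies to the other-gynecologic and
    non-gynecologic categories only.
    """

    code: str
    os_at: frozenset
    age_minimum_other: int = 40

    def __post_init__(self):
        bad = self.os_at - {"hysterectomy", "sterilization", "other_gyn", "nongyn"}
        if bad:
            raise InvalidInputError(f"unknown OS categories {sorted(bad)}")


STRATEGIES = {
    "I": Strategy("I", frozenset({"hysterectomy", "sterilization", "other_gyn", "nongyn"})),
    "II": Strategy("II", frozenset({"hysterectomy", "sterilization", "other_gyn"})),
    "III": Strategy("III", frozenset({"hysterectomy", "sterilization"})),
    "IV": Strategy("IV", frozenset()),
}


def get_strategy(code) -> Strategy:
    if isinstance(code, Strategy):
        return code
    try:
        return STRATEGIES[str(code)]
    except KeyError:
        raise InvalidInputError(f"unknown strategy {code!r}; expected I, II, III or IV")


#: Column order of the schedules CSV fixture (one row per age).
SCHEDULE_COLUMNS = (
    "background_mortality",
    "oc_incidence",
    "oc_mortality_post_dx",
    "hysterectomy",
    "he_bso",
    "sterilization_inpatient",
    "other_gyn",
    "nongyn",
    "population_utility",
)


@dataclass
class ParameterSet:
    """The full model parameterization.

    ``background_mortality`` is all-cause female mortality *net* of
    ovarian-cancer deaths (subtracted at source to avoid double counting);
    ``sterilization_inpatient`` is the raw inpatient schedule, multiplied by
    ``sterilization_multiplier`` (base 2.5, calibrated to a 5% lifetime
    sterilization proportion) before use.
    """

    background_mortality: AgeSchedule
    oc_incidence: AgeSchedule
    oc_mortality_post_dx: AgeSchedule
    surgery: dict  # category -> AgeSchedule; sterilization key is inpatient
    hr: HazardRatioSet = field(default_factory=HazardRatioSet)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    costs: CostSet = field(default_factory=CostSet)
    sterilization_multiplier: float = 2.5
    start_age: int = 20
    cycles: int = 65
    post_dx_excess_mortality_years: int = 10
    os_uptake: float = 1.0
    half_cycle_effects: bool = True
    half_cycle_costs: bool = True

    # -- derived -----------------------------------------------------------
    def sterilization_effective(self) -> AgeSchedule:
        """Inpatient sterilization schedule scaled by the calibration multiplier."""
        return self.surgery["sterilization"].scaled(self.sterilization_multiplier)

    def schedule_frame(self) -> pd.DataFrame:
        """All schedules as a tidy one-row-per-age table (fixture layout)."""
        data = {
            "age": np.arange(AGE_MIN, AGE_MAX + 1),
            "background_mortality": self.background_mortality.p,
            "oc_incidence": self.oc_incidence.p,
            "oc_mortality_post_dx": self.oc_mortality_post_dx.p,
            "hysterectomy": self.surgery["hysterectomy"].p,
            "he_bso": self.surgery["he_bso"].p,
            "sterilization_inpatient": self.surgery["sterilization"].p,
            "other_gyn": self.surgery["other_gyn"].p,
            "nongyn": self.surgery["nongyn"].p,
            "population_utility": self.utilities.population_utility.p,
        }
        return pd.DataFrame(data)

    def replace(self, **kwargs) -> "ParameterSet":
        """Deep copy with field overrides (nested fields via dotted access in
        :func:`ossim.sensitivity.set_parameter`)."""
        new = copy.deepcopy(self)
        for k, v in kwargs.items():
            if not hasattr(new, k):
                raise InvalidInputError(f"unknown ParameterSet field {k!r}")
            setattr(new, k, v)
        return new

    def content_hash(self) -> str:
        """Stable hash of the full parameterization (for run manifests)."""
        h = hashlib.sha256()
        h.update(self.schedule_frame().to_csv(index=False).encode())
        for obj in (self.hr, self.utilities, self.costs):
            for f in dataclasses.fields(obj):
                if f.name == "population_utility":
                    continue
                h.update(f"{f.name}={getattr(obj, f.name)!r};".encode())
        h.update(
            f"{self.sterilization_multiplier};{self.start_age};{self.cycles};"
            f"{self.post_dx_excess_mortality_years};{self.os_uptake};"
            f"{self.half_cycle_effects};{self.half_cycle_costs}".encode()
        )
        return h.hexdigest()

    # -- validation --------------------------------------------------------
    def validate(self) -> "ParameterSet":
        """Check every invariant; raise :class:`ValidationError` naming the
        offending cell(s) on failure.  Returns self for chaining."""
        problems = []
        problems += self.hr.validate()
        problems += self.utilities.validate()
        problems += self.costs.validate()

        expected_keys = {"hysterectomy", "he_bso", "sterilization", "other_gyn", "nongyn"}
        if set(self.surgery) != expected_keys:
            problems.append(
                f"surgery schedules must have keys {sorted(expected_keys)}, "
                f"got {sorted(self.surgery)}"
            )
            raise ValidationError(problems)

        prob_schedules = {
            "background_mortality": self.background_mortality,
            "oc_incidence": self.oc_incidence,
            "oc_mortality_post_dx": self.oc_mortality_post_dx,
            "hysterectomy": self.surgery["hysterectomy"],
            "he_bso": self.surgery["he_bso"],
            "sterilization_inpatient": self.surgery["sterilization"],
            "other_gyn": self.surgery["other_gyn"],
            "nongyn": self.surgery["nongyn"],
        }
        for name, sched in prob_schedules.items():
            p = sched.p
            bad = np.flatnonzero((p < 0) | (p > 1))
            for i in bad[:3]:
                problems.append(
                    f"probability outside [0, 1]: column {name!r}, age "
                    f"{AGE_MIN + int(i)}, value {p[i]!r}"
                )

        # Competing annual event probabilities must not exceed 1 at any age
        # (worst case: non-cancer state at baseline risk, all surgeries open).
        total = (
            self.background_mortality.p
            + self.oc_incidence.p
            + self.surgery["hysterectomy"].p
            + self.surgery["he_bso"].p
            + self.sterilization_effective().p
            + self.surgery["other_gyn"].p
            + self.surgery["nongyn"].p
        )
        for i in np.flatnonzero(total > 1.0 + 1e-12)[:3]:
            problems.append(
                f"competing event probabilities sum to {total[i]:.4f} > 1 at age "
                f"{AGE_MIN + int(i)}"
            )
        post_dx = self.background_mortality.p + self.oc_mortality_post_dx.p
        for i in np.flatnonzero(post_dx > 1.0 + 1e-12)[:3]:
            problems.append(
                f"background + post-diagnosis mortality sums to {post_dx[i]:.4f} > 1 "
                f"at age {AGE_MIN + int(i)}"
            )

        if not (0.0 <= self.os_uptake <= 1.0):
            problems.append(f"os_uptake={self.os_uptake} outside [0, 1]")
        if self.sterilization_multiplier < 0:
            problems.append(f"sterilization_multiplier={self.sterilization_multiplier} negative")
        if self.cycles < 1 or self.start_age != AGE_MIN:
            problems.append(
                f"start_age must be {AGE_MIN} and cycles >= 1 "
                f"(got start_age={self.start_age}, cycles={self.cycles})"
            )
        if self.start_age + self.cycles > AGE_MAX + 1 - 0:
            problems.append(
                f"start_age + cycles = {self.start_age + self.cycles} exceeds "
                f"age range end {AGE_MAX + 1}"
            )

        if problems:
            raise ValidationError(problems)
        return self


# ---------------------------------------------------------------------------
# Scalar operations
# ---------------------------------------------------------------------------

def annual_probability_from_counts(incidence_count, population_at_risk) -> float:
    """Annual transition probability from event counts, P = I / N0."""
    if population_at_risk <= 0:
        raise InvalidInputError(f"population_at_risk={population_at_risk} must be > 0")
    if incidence_count < 0 or incidence_count > population_at_risk:
        raise InvalidInputError(
            f"incidence_count={incidence_count} outside [0, population_at_risk]"
        )
    return incidence_count / population_at_risk


def os_cost_from_minutes(minutes, minute_price) -> float:
    """Cost of the extra OS operating-room time, rounded to cents."""
    if minutes < 0 or minute_price < 0:
        raise InvalidInputError("minutes and minute_price must be non-negative")
    return round(minutes * minute_price, 2)


def weighted_cancer_utility(p_early, u_early, p_advanced, u_advanced) -> float:
    """Stage-prevalence-weighted ovarian-cancer utility, rounded to 2 decimals."""
    if abs(p_early + p_advanced - 1.0) > 1e-9:
        raise InvalidInputError(f"weights sum to {p_early + p_advanced}, expected 1")
    for u in (u_early, u_advanced):
        if not (0.0 <= u <= 1.0):
            raise InvalidInputError(f"utility {u} outside [0, 1]")
    return round(p_early * u_early + p_advanced * u_advanced, 2)


def effective_hazard_ratio(state, years_since_os, hr: HazardRatioSet) -> float:
    """Ovarian-cancer HR for a health state given years since OS.

    Salpingectomy states carry the full effect only once the latency has
    elapsed; before that the pre-OS fallback applies (1.0, or the
    hysterectomy HR when the OS was concomitant with a hysterectomy).
    """
    state = HealthState(state)
    if state in ABSORBING_STATES or state is HealthState.OVARIAN_CANCER:
        raise InvalidInputError(f"state {state.value} carries no ovarian-cancer HR")
    if state in (HealthState.HEALTHY, HealthState.NONGYN_SURG, HealthState.OTHER_GYN_SURG):
        return 1.0
    if state is HealthState.HYSTERECTOMY:
        return hr.hr_hysterectomy
    if state is HealthState.TUBAL_LIGATION:
        return hr.hr_tubal_ligation
    if state is HealthState.HE_BSO:
        return hr.hr_he_bso
    # salpingectomy states
    fallback = 1.0 if state is HealthState.SALPINGECTOMY else hr.hr_hysterectomy
    if years_since_os is None:
        raise InvalidInputError("years_since_os required for salpingectomy states")
    if years_since_os >= hr.latency_years_os:
        return min(fallback, hr.hr_salpingectomy)
    return fallback


def lifetime_first_event_proportion(schedule: AgeSchedule, mortality: AgeSchedule) -> float:
    """Survival-weighted lifetime probability of ever experiencing the event.

    Within each year, death resolves before the event (the engines' fixed
    competing-risk order); event-free survivors carry forward.
    """
    alive = 1.0
    total = 0.0
    for i in range(N_AGES):
        surv = alive * (1.0 - mortality.p[i])
        total += surv * schedule.p[i]
        alive = surv * (1.0 - schedule.p[i])
    return total


def survival_weighted_mean_age(
    schedule: AgeSchedule, mortality: AgeSchedule, first_event: bool = True
):
    """Mean (and SD) age at event, weighting by survival (and, if
    ``first_event``, by not having had the event before)."""
    alive = 1.0
    w = np.zeros(N_AGES)
    for i in range(N_AGES):
        surv = alive * (1.0 - mortality.p[i])
        w[i] = surv * schedule.p[i]
        alive = surv * ((1.0 - schedule.p[i]) if first_event else 1.0)
    if w.sum() <= 0:
        return math.nan, math.nan
    ages = np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)
    mean = float(np.average(ages, weights=w))
    sd = float(math.sqrt(np.average((ages - mean) ** 2, weights=w)))
    return mean, sd


def calibrate_sterilization_multiplier(
    inpatient_schedule: AgeSchedule,
    target_lifetime_proportion: float,
    mortality: AgeSchedule,
    tol: float = 1e-3,
) -> float:
    """Scalar m such that m x inpatient schedule reaches the target lifetime
    sterilization proportion (survival-weighted), to within ``tol`` (0.1
    percentage points by default).  Monotone bisection on m.
    """
    if not (0.0 < target_lifetime_proportion < 1.0):
        raise InvalidInputError(
            f"target_lifetime_proportion={target_lifetime_proportion} outside (0, 1)"
        )
    pmax = float(inpatient_schedule.p.max())
    if pmax <= 0:
        raise InvalidInputError("inpatient schedule is identically zero")
    m_max = 1.0 / pmax  # beyond this, annual probabilities would exceed 1

    def prop(m):
        return lifetime_first_event_proportion(inpatient_schedule.scaled(m), mortality)

    if prop(m_max) < target_lifetime_proportion - tol:
        raise CalibrationError(
            f"target {target_lifetime_proportion} unreachable: proportion at "
            f"m_max={m_max:.3f} is {prop(m_max):.4f}"
        )
    lo, hi = 0.0, m_max
    while hi - lo > 1e-9 * m_max:
        mid = 0.5 * (lo + hi)
        if prop(mid) < target_lifetime_proportion:
            lo = mid
        else:
            hi = mid
    m = 0.5 * (lo + hi)
    if abs(prop(m) - target_lifetime_proportion) > tol:
        raise CalibrationError(
            f"bisection converged to m={m:.4f} but proportion "
            f"{prop(m):.5f} misses target {target_lifetime_proportion} by more than {tol}"
        )
    return m


# ---------------------------------------------------------------------------
# Fixture I/O (CSV schedules + YAML config)
# ---------------------------------------------------------------------------

def write_parameter_tables(params: ParameterSet, directory) -> Path:
    """Write ``schedules.csv`` and ``config.yaml`` under ``directory``.

    Floats are written with shortest round-trip repr so that
    :func:`load_parameter_tables` reproduces the ParameterSet bit-identically.
    Returns the config path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sched_path = directory / "schedules.csv"
    frame = params.schedule_frame()
    frame.to_csv(sched_path, index=False, float_format=lambda v: repr(float(v)))

    cfg = {
        "schedules": "schedules.csv",
        "hazard_ratios": {
            f.name: getattr(params.hr, f.name) for f in dataclasses.fields(params.hr)
        },
        "utilities": {
            f.name: getattr(params.utilities, f.name)
            for f in dataclasses.fields(params.utilities)
            if f.name != "population_utility"
        },
        "costs": {
            f.name: getattr(params.costs, f.name) for f in dataclasses.fields(params.costs)
        },
        "model": {
            "sterilization_multiplier": params.sterilization_multiplier,
            "start_age": params.start_age,
            "cycles": params.cycles,
            "post_dx_excess_mortality_years": params.post_dx_excess_mortality_years,
            "os_uptake": params.os_uptake,
            "half_cycle_effects": params.half_cycle_effects,
            "half_cycle_costs": params.half_cycle_costs,
        },
    }
    cfg_path = directory / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return cfg_path


def load_parameter_tables(config_path) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML config naming the
    schedules CSV and carrying the scalar parameters.

    Raises :class:`ValidationError` with cell-level diagnostics on any
    invariant violation (missing age rows, probabilities outside [0, 1],
    competing probabilities summing above 1, ...).
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise ValidationError(f"config file {config_path} does not exist")
    cfg = yaml.safe_load(config_path.read_text())
    if not isinstance(cfg, dict) or "schedules" not in cfg:
        raise ValidationError(f"config {config_path} must name a 'schedules' table")
    sched_path = Path(cfg["schedules"])
    if not sched_path.is_absolute():
        sched_path = config_path.parent / sched_path
    if not sched_path.exists():
        raise ValidationError(f"schedules table {sched_path} does not exist")

    frame = pd.read_csv(sched_path, float_precision="round_trip")
    problems = []
    if "age" not in frame.columns:
        raise ValidationError(f"{sched_path}: missing 'age' column")
    ages = frame["age"].to_numpy()
    expected = np.arange(AGE_MIN, AGE_MAX + 1)
    if len(ages) != N_AGES or not np.array_equal(np.sort(ages), expected):
        missing = sorted(set(expected) - set(ages.tolist()))
        extra = sorted(set(ages.tolist()) - set(expected))
        if missing:
            problems.append(f"{sched_path}: missing age rows {missing[:6]}")
        if extra:
            problems.append(f"{sched_path}: ages outside [{AGE_MIN}, {AGE_MAX}]: {extra[:6]}")
        if not missing and not extra:
            problems.append(f"{sched_path}: duplicated age rows")
        raise ValidationError(problems)
    frame = frame.sort_values("age").reset_index(drop=True)
    for col in SCHEDULE_COLUMNS:
        if col not in frame.columns:
            problems.append(f"{sched_path}: missing column {col!r}")
    if problems:
        raise ValidationError(problems)

    def sched(col):
        return AgeSchedule(frame[col].to_numpy(dtype=float))

    model = dict(cfg.get("model", {}))
    params = ParameterSet(
        background_mortality=sched("background_mortality"),
        oc_incidence=sched("oc_incidence"),
        oc_mortality_post_dx=sched("oc_mortality_post_dx"),
        surgery={
            "hysterectomy": sched("hysterectomy"),
            "he_bso": sched("he_bso"),
            "sterilization": sched("sterilization_inpatient"),
            "other_gyn": sched("other_gyn"),
            "nongyn": sched("nongyn"),
        },
        hr=HazardRatioSet(**cfg.get("hazard_ratios", {})),
        utilities=UtilitySet(
            population_utility=sched("population_utility"), **cfg.get("utilities", {})
        ),
        costs=CostSet(**cfg.get("costs", {})),
        **model,
    )
    params.validate()
    return params
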