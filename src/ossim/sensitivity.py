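"""One-way deterministic sensitivity analysis, threshold search, and PSA.

One-way sweeps and threshold bisection run on the noise-free cohort engine
by default (a fixed-seed paired microsimulation is available via
``engine="microsim"`` when Monte-Carlo SDs are wanted).  The probabilistic
sensitivity analysis samples parameter values from configurable
distributions; because the parametric families behind the published PSA are
not part of the base-case inputs, the defaults (log-normal on the
salpingectomy HR matched to its 95% CI 0.17-0.73 with median 0.35; uniform
OS cost on the 4-45 min range, i.e. 66.52-748.35 euros) are documented
assumptions and fully overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import InvalidInputError, ParameterSet, get_strategy
from .cohort import run_cohort
from .microsim import SimulationConfig, run_microsim
from .results import ResultsTable
from .economics import classify

#: Sweepable parameters with their default (paper-derived) bounds.
PARAM_BOUNDS = {
    "hr_salpingectomy": (0.17, 0.73),
    "latency_years_os": (0.0, 20.0),
    "os_cost": (66.52, 748.35),
    "oc_followup_annual": (2151.41, 2 * 36366.49),
    "oc_primary": (0.5 * 30133.22, 2 * 30133.22),
    "u_oc": (0.50, 0.82),
    "discount_rate": (0.0, 0.05),
    "hysterectomy_schedule_scale": (0.5, 1.5),
    "sterilization_multiplier": (1.0, 7.5),
    "oc_mortality_scale": (0.7, 1.3),
}

#: Parameters whose variation changes the no-OS reference arm too.
_REF_SENSITIVE = {
    "oc_followup_annual", "oc_primary", "u_oc", "discount_rate",
    "hysterectomy_schedule_scale", "sterilization_multiplier", "oc_mortality_scale",
}

_THRESHOLD_TOL = {
    "hr_salpingectomy": 0.005,
    "latency_years_os": 0.1,
    "os_cost": 0.5,
    "oc_followup_annual": 1.0,
    "oc_primary": 1.0,
    "u_oc": 0.005,
    "discount_rate": 0.0005,
    "hysterectomy_schedule_scale": 0.005,
    "sterilization_multiplier": 0.01,
    "oc_mortality_scale": 0.005,
}


def set_parameter(params: ParameterSet, name: str, value: float) -> ParameterSet:
    """Deep-copied ParameterSet with one named parameter overridden.

    Scale parameters (``hysterectomy_schedule_scale``, ``oc_mortality_scale``)
    are multiplicative factors applied to the supplied base schedules."""
    p = params.replace()
    if name == "hr_salpingectomy":
        p.hr.hr_salpingectomy = float(value)
    elif name == "latency_years_os":
        p.hr.latency_years_os = float(value)
    elif name == "os_cost":
        p.costs.os_cost = float(value)
        if p.costs.or_minute_price:
            p.costs.os_minutes = float(value) / p.costs.or_minute_price
    elif name == "oc_followup_annual":
        p.costs.oc_followup_annual = float(value)
    elif name == "oc_primary":
        p.costs.oc_primary = float(value)
    elif name == "u_oc":
        p.utilities.u_oc = float(value)
    elif name == "discount_rate":
        p.costs.discount_rate = float(value)
    elif name == "hysterectomy_schedule_scale":
        p.surgery["hysterectomy"] = params.surgery["hysterectomy"].scaled(value)
    elif name == "sterilization_multiplier":
        p.sterilization_multiplier = float(value)
    elif name == "oc_mortality_scale":
        p.oc_mortality_post_dx = params.oc_mortality_post_dx.scaled(value)
    else:
        raise InvalidInputError(
            f"unknown sweep parameter {name!r}; expected one of {sorted(PARAM_BOUNDS)}"
        )
    return p


def base_value(params: ParameterSet, name: str) -> float:
    return {
        "hr_salpingectomy": params.hr.hr_salpingectomy,
        "latency_years_os": params.hr.latency_years_os,
        "os_cost": params.costs.os_cost,
        "oc_followup_annual": params.costs.oc_followup_annual,
        "oc_primary": params.costs.oc_primary,
        "u_oc": params.utilities.u_oc,
        "discount_rate": params.costs.discount_rate,
        "hysterectomy_schedule_scale": 1.0,
        "sterilization_multiplier": params.sterilization_multiplier,
        "oc_mortality_scale": 1.0,
    }[name]


@dataclass
class SweepSpec:
    """A one-way sweep: parameter name, ordered grid, declared bounds."""

    parameter: str
    grid: tuple
    bounds: tuple | None = None

    def __post_init__(self):
        if self.parameter not in PARAM_BOUNDS:
            raise InvalidInputError(f"unknown sweep parameter {self.parameter!r}")
        if self.bounds is None:
            self.bounds = PARAM_BOUNDS[self.parameter]
        grid = tuple(float(g) for g in self.grid)
        if any(b > a for a, b in zip(grid[1:], grid)):
            raise InvalidInputError("sweep grid must be sorted ascending")
        lo, hi = self.bounds
        eps = 1e-9
        if any(g < lo - eps or g > hi + eps for g in grid):
            raise InvalidInputError(
                f"grid values outside declared bounds [{lo}, {hi}] for {self.parameter}"
            )
        self.grid = grid


def _evaluate(params, strategies, reference, engine, seed, n) -> ResultsTable:
    strategies = [get_strategy(s).code for s in strategies]
    if reference not in strategies:
        strategies = strategies + [reference]
    if engine == "cohort":
        outcomes = {s: run_cohort(params, s, validate=False) for s in strategies}
        return ResultsTable(outcomes, reference=reference)
    cfg = SimulationConfig(
        n_individuals=n, seed=seed, strategies=tuple(strategies),
        common_random_numbers=True, reference=reference,
    )
    return run_microsim(params, cfg, validate=False)


def one_way_sweep(
    spec: SweepSpec,
    params: ParameterSet,
    strategies=("I", "II", "III"),
    reference: str = "IV",
    engine: str = "cohort",
    include_base_case: bool = True,
    seed: int = 0,
    n: int = 100_000,
) -> pd.DataFrame:
    """Evaluate {prevented-case %, prevented-death %, ICER vs reference} for
    each strategy at every grid point (plus the base case)."""
    params.validate()
    values = list(spec.grid)
    base = base_value(params, spec.parameter)
    rows = []
    cases = [(v, False) for v in values]
    if include_base_case:
        cases.append((base, True))
    for value, is_base in cases:
        p = set_parameter(params, spec.parameter, value)
        table = _evaluate(p, strategies, reference, engine, seed, n)
        for s in strategies:
            code = get_strategy(s).code
            rows.append(
                {
                    "parameter": spec.parameter,
                    "value": value,
                    "base_case": is_base,
                    "strategy": code,
                    "prevented_cases_pct": table.prevented_cases_pct(code),
                    "prevented_deaths_pct": table.prevented_deaths_pct(code),
                    "icer_vs_ref": table.icer_vs_reference(code),
                }
            )
    return pd.DataFrame(rows).sort_values(["strategy", "value"]).reset_index(drop=True)


#: Named ICER predicates for threshold search.
def _predicate(name: str, gdp: float):
    thresholds = {"icer>0": 0.0, "icer>gdp": gdp, "icer>2gdp": 2.0 * gdp}
    if name not in thresholds:
        raise InvalidInputError(f"unknown predicate {name!r}; expected {sorted(thresholds)}")
    thr = thresholds[name]

    def pred(table: ResultsTable, code: str) -> bool:
        ref = table[table.reference]
        s = table[code]
        d_eff = s.qaly_disc - ref.qaly_disc
        d_cost = s.cost_total_pc - ref.cost_total_pc
        if d_eff <= 0:
            # no QALY gain: "exceeds the threshold" whenever it costs more
            return d_cost > 0
        return d_cost / d_eff > thr

    return pred


@dataclass
class ThresholdResult:
    parameter: str
    predicate: str
    strategy: str
    value: float | None  # None when the predicate does not change in bounds
    tolerance: float
    bounds: tuple


def find_parameter_threshold(
    parameter: str,
    predicate: str,
    params: ParameterSet,
    strategy,
    bounds: tuple | None = None,
    reference: str = "IV",
    tol: float | None = None,
) -> ThresholdResult:
    """Bisection (on the cohort engine) for the parameter value at which an
    ICER predicate flips, to the declared tolerance (HR +/-0.005, cost
    +/-0.5 euro, years +/-0.1).  Returns value None when the predicate truth
    does not change across the bounds."""
    params.validate()
    code = get_strategy(strategy).code
    if bounds is None:
        bounds = PARAM_BOUNDS[parameter]
    if tol is None:
        tol = _THRESHOLD_TOL.get(parameter, 1e-3)
    pred = _predicate(predicate, params.costs.gdp_per_capita)

    def holds(v) -> bool:
        p = set_parameter(params, parameter, v)
        table = _evaluate(p, (code,), reference, "cohort", 0, 0)
        return pred(table, code)

    lo, hi = float(bounds[0]), float(bounds[1])
    f_lo, f_hi = holds(lo), holds(hi)
    if f_lo == f_hi:
        return ThresholdResult(parameter, predicate, code, None, tol, bounds)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if holds(mid) == f_lo:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(parameter, predicate, code, 0.5 * (lo + hi), tol, bounds)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class DistributionSpec:
    """A sampling distribution for one sweepable parameter.

    Families: uniform(low, high); triangular(left, mode, right);
    beta(a, b[, loc, scale]); gamma(shape, scale[, loc]);
    lognormal(mu, sigma) of the underlying normal.  Samples are clipped to
    the parameter's validity range where needed (e.g. HRs to (0, 1])."""

    parameter: str
    family: str
    args: dict = field(default_factory=dict)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        a = self.args
        if self.family == "uniform":
            x = rng.uniform(a["low"], a["high"], size)
        elif self.family == "triangular":
            x = rng.triangular(a["left"], a["mode"], a["right"], size)
        elif self.family == "beta":
            x = a.get("loc", 0.0) + a.get("scale", 1.0) * rng.beta(a["a"], a["b"], size)
        elif self.family == "gamma":
            x = a.get("loc", 0.0) + rng.gamma(a["shape"], a["scale"], size)
        elif self.family == "lognormal":
            x = rng.lognormal(a["mu"], a["sigma"], size)
        else:
            raise InvalidInputError(f"unknown distribution family {self.family!r}")
        if self.parameter == "hr_salpingectomy":
            x = np.clip(x, 1e-6, 1.0)
        if self.parameter in ("os_cost", "oc_followup_annual", "oc_primary"):
            x = np.maximum(x, 0.0)
        if self.parameter == "u_oc":
            x = np.clip(x, 0.0, 1.0)
        return x


def default_psa_distributions() -> list:
    """Default PSA sampling: log-normal salpingectomy HR with median 0.35
    whose 2.5/97.5 percentiles match the 0.17-0.73 CI, and uniform OS cost
    over the 4-45 min OR-time range."""
    sigma = (math.log(0.73) - math.log(0.17)) / (2.0 * 1.959963984540054)
    return [
        DistributionSpec("hr_salpingectomy", "lognormal", {"mu": math.log(0.35), "sigma": sigma}),
        DistributionSpec("os_cost", "uniform", {"low": 66.52, "high": 748.35}),
    ]


@dataclass
class PSAResult:
    samples: pd.DataFrame  # one row per (sample, strategy)
    summary: pd.DataFrame  # one row per strategy
    seed: int
    n_samples: int


def run_psa(
    params: ParameterSet,
    dists=None,
    n_samples: int = 500,
    seed: int = 0,
    strategies=("I", "II", "III"),
    reference: str = "IV",
) -> PSAResult:
    """Monte-Carlo parameter sampling with a cohort-engine evaluation per
    sample; reproducible given the seed.

    Summary per strategy vs the reference: fraction of samples clinically
    effective (ovarian-cancer cases reduced), fractions with ICER below the
    1x and 2x GDP/C thresholds (cost-saving samples count as below), and
    percentiles of the prevented-case percentage.
    """
    if n_samples < 2:
        raise InvalidInputError("n_samples must be >= 2")
    params.validate()
    if dists is None:
        dists = default_psa_distributions()
    rng = np.random.default_rng(seed)
    draws = {d.parameter: d.sample(rng, n_samples) for d in dists}
    codes = [get_strategy(s).code for s in strategies]
    gdp = params.costs.gdp_per_capita
    ref_static = not (_REF_SENSITIVE & set(draws))
    ref_outcome = run_cohort(params, reference, validate=False) if ref_static else None

    rows = []
    for i in range(n_samples):
        p = params
        for name, vals in draws.items():
            p = set_parameter(p, name, vals[i])
        ref = ref_outcome if ref_static else run_cohort(p, reference, validate=False)
        for code in codes:
            s = run_cohort(p, code, validate=False)
            d_cost = s.cost_total_pc - ref.cost_total_pc
            d_eff = s.qaly_disc - ref.qaly_disc
            prevented = (
                100.0 * (ref.cases_pc - s.cases_pc) / ref.cases_pc
                if ref.cases_pc
                else math.nan
            )
            cls = classify(d_cost, d_eff, gdp)
            rows.append(
                {
                    "sample": i,
                    **{name: vals[i] for name, vals in draws.items()},
                    "strategy": code,
                    "prevented_cases_pct": prevented,
                    "delta_cost": d_cost,
                    "delta_qaly": d_eff,
                    "icer": d_cost / d_eff if d_eff else math.nan,
                    "dominance_class": cls,
                }
            )
    samples = pd.DataFrame(rows)

    summary_rows = []
    below_1x = {"cost-saving", "cost-effective-1xGDP"}
    below_2x = below_1x | {"cost-effective-2xGDP"}
    for code in codes:
        sub = samples[samples["strategy"] == code]
        pct = sub["prevented_cases_pct"]
        summary_rows.append(
            {
                "strategy": code,
                "frac_clinically_effective": float((pct > 0).mean()),
                "frac_icer_below_1xGDP": float(sub["dominance_class"].isin(below_1x).mean()),
                "frac_icer_below_2xGDP": float(sub["dominance_class"].isin(below_2x).mean()),
                "prevented_cases_pct_p2.5": float(pct.quantile(0.025)),
                "prevented_cases_pct_p25": float(pct.quantile(0.25)),
                "prevented_cases_pct_p50": float(pct.quantile(0.50)),
                "prevented_cases_pct_p75": float(pct.quantile(0.75)),
                "prevented_cases_pct_p97.5": float(pct.quantile(0.975)),
            }
        )
    summary = pd.DataFrame(summary_rows).set_index("strategy")
    return PSAResult(samples=samples, summary=summary, seed=seed, n_samples=n_samples)
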