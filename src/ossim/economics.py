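"""Discounting, ICER computation, threshold classification, breakeven OS cost.

Sign conventions: incremental quantities are strategy minus reference
(reference = no-OS strategy IV unless stated).  A negative ICER arising from
lower costs and more QALYs is reported as the negative number (as in the
base case), not collapsed to "dominant" — the dominance class carries that
information separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import InvalidInputError, ParameterSet, get_strategy
from .cohort import run_cohort, TransitionModel
from .microsim import SimulationConfig, run_microsim


def discount_stream(values, rate: float, t_start: int = 0) -> float:
    """Present value of per-cycle amounts: sum of v_t / (1+rate)^t.

    ``values[0]`` is booked at cycle ``t_start`` (default 0, the engines'
    convention: cycle t runs from model year t to t+1 and is discounted by
    1/(1+r)^t).  At rate 0 this is the plain sum.
    """
    if rate < 0:
        raise InvalidInputError(f"rate={rate} must be >= 0")
    v = np.asarray(values, dtype=float)
    t = t_start + np.arange(v.size)
    return float(np.sum(v / (1.0 + rate) ** t))


@dataclass
class CEResult:
    """An incremental cost-effectiveness comparison."""

    delta_cost: float  # euros per capita
    delta_effect: float  # QALYs (or LYs) per capita
    icer: float  # euros per effect unit; NaN if delta_effect == 0
    dominance_class: str  # see classify()

    @property
    def icer_defined(self) -> bool:
        return math.isfinite(self.icer)


def classify(delta_cost: float, delta_effect: float, gdp_per_capita: float) -> str:
    """Dominance class against 1x and 2x GDP-per-capita thresholds."""
    if delta_effect > 0:
        if delta_cost <= 0:
            return "cost-saving"  # dominant
        ratio = delta_cost / delta_effect
        if ratio <= gdp_per_capita:
            return "cost-effective-1xGDP"
        if ratio <= 2.0 * gdp_per_capita:
            return "cost-effective-2xGDP"
        return "not-cost-effective"
    if delta_effect < 0:
        if delta_cost >= 0:
            return "dominated"
        # less effect, less cost: cost-effective only if savings per QALY
        # forgone exceed the 1x threshold
        ratio = delta_cost / delta_effect  # positive
        return "cost-effective-1xGDP" if ratio >= gdp_per_capita else "not-cost-effective"
    # zero effect difference: classified by cost alone
    if delta_cost < 0:
        return "cost-saving"
    if delta_cost > 0:
        return "dominated"
    return "equivalent"


def icer(cost_a, effect_a, cost_b, effect_b, gdp_per_capita: float = 47183.0) -> CEResult:
    """Incremental cost-effectiveness of option a versus option b.

    ``icer`` is NaN when the effect difference is zero (class from cost sign
    alone)."""
    d_cost = cost_a - cost_b
    d_eff = effect_a - effect_b
    ratio = d_cost / d_eff if d_eff != 0 else math.nan
    return CEResult(d_cost, d_eff, ratio, classify(d_cost, d_eff, gdp_per_capita))


def _incremental_cost(params: ParameterSet, strategy, reference, engine, seed, n):
    """Discounted incremental lifetime cost per capita vs the reference."""
    if engine == "cohort":
        a = run_cohort(params, strategy, validate=False)
        b = run_cohort(params, reference, validate=False)
    elif engine == "microsim":
        cfg = SimulationConfig(
            n_individuals=n, seed=seed,
            strategies=(get_strategy(strategy).code, get_strategy(reference).code),
            common_random_numbers=True, reference=get_strategy(reference).code,
        )
        table = run_microsim(params, cfg, validate=False)
        a, b = table[get_strategy(strategy).code], table[get_strategy(reference).code]
    else:
        raise InvalidInputError(f"unknown engine {engine!r}")
    return a.cost_total_pc - b.cost_total_pc


@dataclass
class BreakevenResult:
    strategy: str
    breakeven_cost: float | None  # euros; None if no sign change in bounds
    breakeven_minutes: float | None  # via the OR minute price
    tolerance: float


def breakeven_os_cost(
    params: ParameterSet,
    strategy,
    engine: str = "cohort",
    reference: str = "IV",
    upper: float = 10_000.0,
    tol: float = 0.5,
    seed: int = 0,
    n: int = 100_000,
) -> BreakevenResult:
    """OS cost at which the incremental lifetime cost vs the reference
    crosses zero, by bisection to +/- ``tol`` euros.

    The incremental cost is affine in the OS cost (slope = expected
    discounted salpingectomies per capita), so the crossing is unique.  If
    OS can never save money (non-negative incremental cost at zero OS cost)
    the breakeven is 0; if no sign change occurs on [0, upper] no breakeven
    is reported.
    """
    strategy = get_strategy(strategy)
    params.validate()

    def delta(c):
        p = params.replace()
        p.costs.os_cost = c
        p.costs.os_minutes = (
            c / p.costs.or_minute_price if p.costs.or_minute_price else 0.0
        )
        return _incremental_cost(p, strategy, reference, engine, seed, n)

    minutes = lambda c: (
        c / params.costs.or_minute_price if params.costs.or_minute_price else None
    )
    lo, hi = 0.0, float(upper)
    d_lo, d_hi = delta(lo), delta(hi)
    if d_lo >= 0.0:
        return BreakevenResult(strategy.code, 0.0, 0.0, tol)
    if d_hi < 0.0:
        return BreakevenResult(strategy.code, None, None, tol)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if delta(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    return BreakevenResult(strategy.code, c, minutes(c), tol)


def expected_discounted_os_per_capita(params: ParameterSet, strategy) -> float:
    """Slope of the incremental-cost-vs-OS-cost line: expected discounted
    number of salpingectomies per capita under the strategy."""
    tm = TransitionModel(params, strategy)
    space = tm.space
    disc = (1.0 + params.costs.discount_rate) ** -np.arange(params.cycles, dtype=float)
    m = np.zeros(space.n_states)
    m[space.healthy] = 1.0
    flat = tm.targets.ravel()
    total = 0.0
    for t in range(params.cycles):
        flows = m[:, None] * tm.probs[t]
        total += disc[t] * flows[tm.os_flag].sum()
        m = np.bincount(flat, weights=flows.ravel(), minlength=space.n_states)
    return float(total)
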