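"""Individual-level Monte-Carlo microsimulation of the OS lifetime model.

The microsimulation realizes the same expanded chain as the cohort engine
(:class:`ossim.cohort.TransitionModel` is shared verbatim), so its sample
means converge to the cohort engine's exact expectations.  One uniform
variate per (individual, cycle) is drawn from a counter-based Philox stream
keyed by the seed; with common random numbers the identical draw matrix is
replayed for every strategy, so paired strategy contrasts difference out
most Monte-Carlo noise and individual trajectories are bit-reproducible.

Within a cycle the single uniform is mapped to the fixed competing-event
partition (background death, OC death, OC incidence, surgery by category,
stay), which is exactly the cohort operator's probability row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ParameterSet, get_strategy
from .cohort import TransitionModel
from .results import ResultsTable, StrategyOutcome


@dataclass
class SimulationConfig:
    """Configuration of a microsimulation run."""

    n_individuals: int = 100_000
    seed: int = 0
    strategies: tuple = ("I", "II", "III", "IV")
    common_random_numbers: bool = True
    reference: str = "IV"

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


def draw_uniforms(seed: int, n: int, cycles: int, stream: int = 0) -> np.ndarray:
    """(n, cycles) uniforms from a counter-based Philox generator."""
    rng = np.random.Generator(np.random.Philox(key=[seed, stream]))
    return rng.random((n, cycles))


def _simulate(tm: TransitionModel, params: ParameterSet, draws: np.ndarray,
              record_states: bool = False) -> dict:
    """Vectorized core: advance every individual through all cycles.

    Returns per-individual arrays; a total function of the draws."""
    space = tm.space
    n, T = draws.shape
    assert T == params.cycles
    costs = params.costs
    disc = (1.0 + costs.discount_rate) ** -np.arange(T, dtype=float)
    hce = params.half_cycle_effects
    hcc = params.half_cycle_costs

    state = np.full(n, space.healthy, dtype=np.int64)
    zeros = lambda: np.zeros(n)
    ly_u, ly_d = zeros(), zeros()
    qaly_u, qaly_d = zeros(), zeros()
    cost_os_u, cost_os_d = zeros(), zeros()
    cost_oc_u, cost_oc_d = zeros(), zeros()
    os_count = np.zeros(n, dtype=np.int32)
    age_os = np.full(n, -1, dtype=np.int16)
    age_dx = np.full(n, -1, dtype=np.int16)
    traj = np.empty((n, T + 1), dtype=np.int16) if record_states else None
    if record_states:
        traj[:, 0] = state

    for t in range(T):
        u = draws[:, t]
        rows = tm.cum_probs[t][state]  # (n, K)
        j = (u[:, None] > rows).sum(axis=1)
        j = np.minimum(j, tm.K - 1)
        new_state = tm.targets[state, j]

        os_e = tm.os_flag[state, j]
        prim = tm.primary_flag[state, j]
        pall = tm.palliative_flag[state, j]
        age = params.start_age + t
        os_count += os_e
        age_os[os_e & (age_os < 0)] = age
        age_dx[prim] = age

        a0 = tm.alive_vec[state]
        a1 = tm.alive_vec[new_state]
        u0 = tm.utility_table[state, t]
        u1 = tm.utility_table[new_state, t + 1]
        f0 = tm.followup_vec[state]
        f1 = tm.followup_vec[new_state]
        ly_t = 0.5 * (a0 + a1) if hce else a0
        q_t = 0.5 * (u0 + u1) if hce else u0
        fu_t = 0.5 * (f0 + f1) if hcc else f0
        ly_u += ly_t
        ly_d += disc[t] * ly_t
        qaly_u += q_t
        qaly_d += disc[t] * q_t
        cost_oc_u += fu_t
        cost_oc_d += disc[t] * fu_t

        os_cost_t = costs.os_cost * os_e
        oc_cost_t = costs.oc_primary * prim + costs.palliative * pall
        cost_os_u += os_cost_t
        cost_os_d += disc[t] * os_cost_t
        cost_oc_u += oc_cost_t
        cost_oc_d += disc[t] * oc_cost_t

        state = new_state
        if record_states:
            traj[:, t + 1] = state

    if hce:
        ly_u -= 0.5
        ly_d -= 0.5 * disc[0]
        u_entry = tm.utility_table[space.healthy, 0]
        qaly_u -= 0.5 * u_entry
        qaly_d -= 0.5 * disc[0] * u_entry

    out = {
        "final_state": state,
        "ly_undisc": ly_u, "ly_disc": ly_d,
        "qaly_undisc": qaly_u, "qaly_disc": qaly_d,
        "cost_os_undisc": cost_os_u, "cost_os_disc": cost_os_d,
        "cost_oc_undisc": cost_oc_u, "cost_oc_disc": cost_oc_d,
        "os_count": os_count, "age_os": age_os, "age_dx": age_dx,
        "ever_oc": age_dx >= 0,
        "died_oc": state == space.death_oc,
        "died_other": state == space.death_other,
    }
    if record_states:
        out["states"] = traj
    return out


def _aggregate(strategy_code: str, arrays: dict) -> StrategyOutcome:
    n = len(arrays["final_state"])

    def msd(key):
        a = arrays[key]
        return float(a.mean()), float(a.std())

    ly_u, sd_ly_u = msd("ly_undisc")
    ly_d, sd_ly_d = msd("ly_disc")
    q_u, sd_q_u = msd("qaly_undisc")
    q_d, sd_q_d = msd("qaly_disc")
    cos, sd_cos = msd("cost_os_disc")
    coc, sd_coc = msd("cost_oc_disc")
    total_sd = float((arrays["cost_os_disc"] + arrays["cost_oc_disc"]).std())

    def age_stats(key):
        a = arrays[key]
        a = a[a >= 0]
        if a.size == 0:
            return math.nan, math.nan
        return float(a.mean()), float(a.std())

    mean_os, sd_os = age_stats("age_os")
    mean_dx, sd_dx = age_stats("age_dx")

    return StrategyOutcome(
        strategy=strategy_code,
        engine="microsim",
        n=n,
        cases_pc=float(arrays["ever_oc"].mean()),
        oc_deaths_pc=float(arrays["died_oc"].mean()),
        other_deaths_pc=float(arrays["died_other"].mean()),
        survivors_pc=float(
            1.0 - arrays["died_oc"].mean() - arrays["died_other"].mean()
        ),
        os_events_pc=float(arrays["os_count"].mean()),
        mean_age_os=mean_os, sd_age_os=sd_os,
        mean_age_dx=mean_dx, sd_age_dx=sd_dx,
        ly_undisc=ly_u, ly_disc=ly_d, qaly_undisc=q_u, qaly_disc=q_d,
        sd_ly_undisc=sd_ly_u, sd_ly_disc=sd_ly_d,
        sd_qaly_undisc=sd_q_u, sd_qaly_disc=sd_q_d,
        cost_os_pc=cos, cost_oc_pc=coc,
        sd_cost_os_pc=sd_cos, sd_cost_oc_pc=sd_coc, sd_cost_total_pc=total_sd,
        cost_os_pc_undisc=float(arrays["cost_os_undisc"].mean()),
        cost_oc_pc_undisc=float(arrays["cost_oc_undisc"].mean()),
    )


@dataclass
class IndividualTrajectory:
    """One simulated woman's path through the expanded chain."""

    states: np.ndarray  # expanded-state index at each cycle boundary
    state_names: list
    age_os: int  # -1 if never
    age_dx: int  # -1 if never
    death_cause: str  # "oc", "other" or "alive"
    accumulators: dict = field(default_factory=dict)


def simulate_individual(draws: np.ndarray, params: ParameterSet, strategy,
                        tm: TransitionModel | None = None) -> IndividualTrajectory:
    """Simulate a single woman from an explicit per-cycle draw stream.

    With identical draws across strategies this supports paired-path
    differencing (the common-random-numbers discipline at n = 1)."""
    strategy = get_strategy(strategy)
    if tm is None:
        tm = TransitionModel(params, strategy)
    draws = np.asarray(draws, dtype=float).reshape(1, -1)
    res = _simulate(tm, params, draws, record_states=True)
    states = res["states"][0]
    space = tm.space
    final = states[-1]
    cause = "oc" if final == space.death_oc else (
        "other" if final == space.death_other else "alive"
    )
    acc = {
        k: float(res[k][0])
        for k in ("ly_undisc", "ly_disc", "qaly_undisc", "qaly_disc",
                  "cost_os_undisc", "cost_os_disc", "cost_oc_undisc", "cost_oc_disc")
    }
    return IndividualTrajectory(
        states=states,
        state_names=[space.states[i].name for i in states],
        age_os=int(res["age_os"][0]),
        age_dx=int(res["age_dx"][0]),
        death_cause=cause,
        accumulators=acc,
    )


def run_microsim(
    params: ParameterSet,
    config: SimulationConfig | None = None,
    return_individuals: bool = False,
    validate: bool = True,
    **config_kwargs,
):
    """Run the microsimulation for each configured strategy.

    Returns a :class:`ResultsTable` (and, with ``return_individuals``, the
    per-individual arrays keyed by strategy).  Identical seed and
    configuration give bit-identical results.
    """
    if config is None:
        config = SimulationConfig(**config_kwargs)
    elif config_kwargs:
        raise TypeError("pass either a SimulationConfig or keyword arguments")
    if validate:
        params.validate()

    outcomes = {}
    individuals = {}
    shared_draws = None
    if config.common_random_numbers:
        shared_draws = draw_uniforms(config.seed, config.n_individuals, params.cycles)
    for k, strat in enumerate(config.strategies):
        code = get_strategy(strat).code
        tm = TransitionModel(params, code)
        draws = (
            shared_draws
            if shared_draws is not None
            else draw_uniforms(config.seed, config.n_individuals, params.cycles, stream=k + 1)
        )
        arrays = _simulate(tm, params, draws)
        outcomes[code] = _aggregate(code, arrays)
        if return_individuals:
            individuals[code] = arrays
    table = ResultsTable(outcomes, reference=config.reference)
    if return_individuals:
        return table, individuals
    return table


def convergence_scan(
    ns,
    params: ParameterSet,
    seed: int = 0,
    strategy: str = "I",
    reference: str = "IV",
    rel_se_tolerance: float = 0.05,
) -> pd.DataFrame:
    """Prevented-case fraction (strategy vs reference, paired draws) at
    increasing cohort sizes, with its Monte-Carlo standard error.

    The variance of the per-capita outcomes decreases ~1/n; the returned
    frame flags the first n at which the relative SE of the prevented-case
    fraction falls below ``rel_se_tolerance``.
    """
    params.validate()
    rows = []
    for n in ns:
        cfg = SimulationConfig(
            n_individuals=int(n), seed=seed, strategies=(strategy, reference),
            common_random_numbers=True, reference=reference,
        )
        table, ind = run_microsim(params, cfg, return_individuals=True, validate=False)
        d = ind[reference]["ever_oc"].astype(float) - ind[strategy]["ever_oc"].astype(float)
        p_ref = ind[reference]["ever_oc"].mean()
        prevented = d.mean() / p_ref if p_ref > 0 else math.nan
        se_d = d.std() / math.sqrt(n)
        se_frac = se_d / p_ref if p_ref > 0 else math.nan
        rows.append(
            {
                "n": int(n),
                "prevented_cases_pct": 100.0 * prevented,
                "se_prevented_fraction": se_frac,
                "rel_se": se_frac / prevented if prevented else math.nan,
                "variance_prevented_fraction": se_frac ** 2,
                "converged": bool(prevented and se_frac / prevented < rel_se_tolerance),
            }
        )
    frame = pd.DataFrame(rows)
    return frame
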