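"""Deterministic cohort engine: exact expectations of the OS lifetime model.

History dependence (years since salpingectomy, years since ovarian-cancer
diagnosis) is removed by expanding the health states into tunnel states:

* OS-latency tunnels ``SALP(k, f)`` / ``HESALP(k, f)`` for k = 1..ceil(L)-1
  years since OS, carrying the pre-OS fallback hazard ratio ``f`` explicitly
  (1.0, or the hysterectomy/tubal-ligation HR when the OS followed one of
  those surgeries), then an "effective" state once the latency has elapsed;
* post-diagnosis tunnels ``OC(d)`` for d = 1..10 years since diagnosis,
  after which survivors move to a post-cancer survivor state with background
  mortality and population utility only.

The resulting memoryless chain is propagated as a mass distribution over 65
annual cycles, which makes this engine the exact oracle for the Monte-Carlo
microsimulation (both engines share the same ``TransitionModel``).

Within-cycle competing events are resolved in a fixed order: background
death, ovarian-cancer death (post-diagnosis states), ovarian-cancer
incidence at the state-modified hazard, then surgery (HE+BSO > hysterectomy
> sterilization > other-gyn > non-gyn).  A transition triggered by surgery
is allowed only if it strictly improves the (long-run HR, current HR) pair —
the risk ratchet — and OS is performed (and billed) only on allowed
transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import (
    AGE_MIN,
    AGE_MAX,
    HealthState,
    ParameterSet,
    ValidationError,
    get_strategy,
)
from .results import ResultsTable, StrategyOutcome

_EPS = 1e-12


@dataclass(frozen=True)
class XState:
    """One expanded state: base health state plus history clocks."""

    idx: int
    base: HealthState
    clock: int | None = None  # years since OS (latency tunnels; None once effective)
    fallback: float | None = None  # pre-OS fallback HR (salpingectomy states)
    dx_year: int | None = None  # years since ovarian-cancer diagnosis

    @property
    def name(self) -> str:
        bits = [self.base.value]
        if self.fallback is not None:
            bits.append(f"f={self.fallback:g}")
        if self.clock is not None:
            bits.append(f"k={self.clock}")
        if self.dx_year is not None:
            bits.append(f"dx={self.dx_year}")
        return "/".join(bits)


class StateSpace:
    """Expanded state space for a given ParameterSet (strategy-independent)."""

    def __init__(self, params: ParameterSet):
        hr = params.hr
        L = float(hr.latency_years_os)
        self.latency = L
        self.n_tunnel = max(0, math.ceil(L) - 1)
        D = int(params.post_dx_excess_mortality_years)
        self.dx_years = D

        # fallback HR values reachable on each salpingectomy base state
        def dedupe(vals):
            out = []
            for v in vals:
                if not any(abs(v - w) <= _EPS for w in out):
                    out.append(v)
            return tuple(out)

        self.salp_fallbacks = dedupe((1.0, hr.hr_tubal_ligation))
        self.hesalp_fallbacks = dedupe(
            (hr.hr_hysterectomy, min(hr.hr_tubal_ligation, hr.hr_hysterectomy))
        )

        self.states: list[XState] = []

        def add(**kw):
            st = XState(idx=len(self.states), **kw)
            self.states.append(st)
            return st.idx

        self.healthy = add(base=HealthState.HEALTHY)
        self.nongyn_surg = add(base=HealthState.NONGYN_SURG)
        self.other_gyn_surg = add(base=HealthState.OTHER_GYN_SURG)
        self.tubal_ligation = add(base=HealthState.TUBAL_LIGATION)
        self.hysterectomy = add(base=HealthState.HYSTERECTOMY)
        self.he_bso = add(base=HealthState.HE_BSO)

        self._salp = {}  # (clock or None, fallback value) -> idx
        for base, fbs, store in (
            (HealthState.SALPINGECTOMY, self.salp_fallbacks, "_salp_idx"),
            (HealthState.HE_SALPINGECTOMY, self.hesalp_fallbacks, "_hesalp_idx"),
        ):
            table = {}
            for f in fbs:
                for k in range(1, self.n_tunnel + 1):
                    table[(k, f)] = add(base=base, clock=k, fallback=f)
                table[(None, f)] = add(base=base, clock=None, fallback=f)
            setattr(self, store, table)

        self.oc = [add(base=HealthState.OVARIAN_CANCER, dx_year=d) for d in range(1, D + 1)]
        self.oc_survivor = add(base=HealthState.OVARIAN_CANCER, dx_year=D + 1)
        self.death_other = add(base=HealthState.DEATH_OTHER)
        self.death_oc = add(base=HealthState.DEATH_OC)

        self.n_states = len(self.states)
        self._build_attributes(params)

    # -- lookups -----------------------------------------------------------
    def salp_state(self, base, clock, fallback: float) -> int:
        """Index of a salpingectomy state, snapping the fallback to the
        enumerated value set (exact by construction)."""
        base = HealthState(base)
        table = self._salp_idx if base is HealthState.SALPINGECTOMY else self._hesalp_idx
        fbs = (
            self.salp_fallbacks
            if base is HealthState.SALPINGECTOMY
            else self.hesalp_fallbacks
        )
        for f in fbs:
            if abs(f - fallback) <= _EPS:
                if clock is not None and clock > self.n_tunnel:
                    clock = None
                return table[(clock, f)]
        raise ValidationError(f"fallback {fallback} not representable for {base}")

    def os_entry(self, base: HealthState, fallback: float) -> int:
        """State occupied one year after a new OS (clock = 1)."""
        clock = 1 if self.n_tunnel >= 1 else None
        return self.salp_state(base, clock, fallback)

    # -- attributes --------------------------------------------------------
    def _build_attributes(self, params: ParameterSet):
        hr = params.hr
        S = self.n_states
        self.alive = np.ones(S, bool)
        self.alive[[self.death_other, self.death_oc]] = False
        self.in_oc_tunnel = np.zeros(S, bool)
        for i in self.oc:
            self.in_oc_tunnel[i] = True
        self.is_cancer = self.in_oc_tunnel.copy()
        self.is_cancer[self.oc_survivor] = True

        h_cur = np.full(S, np.nan)
        h_lr = np.full(S, np.nan)
        has_uterus = np.zeros(S, bool)
        has_tubes = np.zeros(S, bool)
        for st in self.states:
            i = st.idx
            b = st.base
            if b in (HealthState.HEALTHY, HealthState.NONGYN_SURG, HealthState.OTHER_GYN_SURG):
                h_cur[i] = h_lr[i] = 1.0
                has_uterus[i] = has_tubes[i] = True
            elif b is HealthState.TUBAL_LIGATION:
                h_cur[i] = h_lr[i] = hr.hr_tubal_ligation
                has_uterus[i] = has_tubes[i] = True
            elif b is HealthState.HYSTERECTOMY:
                h_cur[i] = h_lr[i] = hr.hr_hysterectomy
                has_tubes[i] = True
            elif b is HealthState.HE_BSO:
                h_cur[i] = h_lr[i] = hr.hr_he_bso
            elif b in (HealthState.SALPINGECTOMY, HealthState.HE_SALPINGECTOMY):
                f = st.fallback
                target = min(f, hr.hr_salpingectomy)
                if st.clock is None:
                    h_cur[i] = target
                else:
                    # fraction of the coming year with the OS effect in force
                    w = min(1.0, max(0.0, st.clock + 1 - self.latency))
                    h_cur[i] = f + (target - f) * w
                h_lr[i] = target
                has_uterus[i] = b is HealthState.SALPINGECTOMY
        self.h_cur = h_cur
        self.h_lr = h_lr
        self.has_uterus = has_uterus
        self.has_tubes = has_tubes

        # default successor when no event occurs (clock advance)
        adv = np.arange(S)
        for st in self.states:
            if st.base in (HealthState.SALPINGECTOMY, HealthState.HE_SALPINGECTOMY):
                if st.clock is not None:
                    adv[st.idx] = self.salp_state(st.base, st.clock + 1, st.fallback)
            elif st.dx_year is not None and st.dx_year <= self.dx_years:
                adv[st.idx] = (
                    self.oc[st.dx_year] if st.dx_year < self.dx_years else self.oc_survivor
                )
        self.advance = adv


def expand_states(params: ParameterSet) -> StateSpace:
    """Expanded state space for ``params`` (tunnel depth from the OS latency
    and the post-diagnosis mortality horizon)."""
    return StateSpace(params)


def _improves(new_lr, new_cur, old_lr, old_cur) -> bool:
    """The risk ratchet: strict lexicographic improvement of (long-run HR,
    current HR)."""
    if new_lr < old_lr - _EPS:
        return True
    if new_lr > old_lr + _EPS:
        return False
    return new_cur < old_cur - _EPS


@dataclass
class _Edge:
    kind: str  # schedule key
    scale: float
    target: int
    amin: int = AGE_MIN
    amax: int = AGE_MAX
    os: bool = False
    primary: bool = False
    palliative: bool = False


class TransitionModel:
    """Per-cycle transition operator of the expanded chain for one strategy.

    ``probs[t, s, j]`` is the probability of outcome j from state s during
    cycle t (last column = stay/clock-advance); ``targets[s, j]`` the
    destination state; boolean flags mark salpingectomy, diagnosis and
    ovarian-cancer-death transitions for event accounting.  Every row sums
    to 1 within 1e-12 (checked at construction).
    """

    def __init__(self, params: ParameterSet, strategy):
        self.params = params
        self.strategy = strategy = get_strategy(strategy)
        self.space = space = StateSpace(params)
        T = params.cycles
        self.cycle_ages = params.start_age + np.arange(T)

        edges = [self._state_edges(s) for s in space.states]
        K = max(len(e) for e in edges) + 1  # + stay column
        S = space.n_states
        self.K = K
        self.targets = np.tile(space.advance[:, None], (1, K)).astype(np.int64)
        self.os_flag = np.zeros((S, K), bool)
        self.primary_flag = np.zeros((S, K), bool)
        self.palliative_flag = np.zeros((S, K), bool)
        probs = np.zeros((T, S, K))

        scheds = self._cycle_schedules(params)
        for s, es in enumerate(edges):
            for j, e in enumerate(es):
                self.targets[s, j] = e.target
                self.os_flag[s, j] = e.os
                self.primary_flag[s, j] = e.primary
                self.palliative_flag[s, j] = e.palliative
                window = (self.cycle_ages >= e.amin) & (self.cycle_ages <= e.amax)
                probs[:, s, j] = scheds[e.kind] * e.scale * window
        stay = 1.0 - probs[:, :, :-1].sum(axis=2)
        if stay.min() < -1e-9:
            t, s = np.unravel_index(np.argmin(stay), stay.shape)
            raise ValidationError(
                f"transition row for state {space.states[s].name!r} at age "
                f"{params.start_age + t} sums to {1 - stay[t, s]:.6f} > 1"
            )
        probs[:, :, -1] = np.clip(stay, 0.0, None)
        if not np.allclose(probs.sum(axis=2), 1.0, atol=1e-12):
            raise ValidationError("transition rows do not sum to 1")
        self.probs = probs
        self.cum_probs = np.cumsum(probs, axis=2)

        self._build_reward_tables(params)

    @staticmethod
    def _cycle_schedules(params: ParameterSet) -> dict:
        t0 = params.start_age - AGE_MIN
        sl = slice(t0, t0 + params.cycles)
        return {
            "bg": params.background_mortality.p[sl],
            "ocd": params.oc_mortality_post_dx.p[sl],
            "inc": params.oc_incidence.p[sl],
            "he_bso": params.surgery["he_bso"].p[sl],
            "hysterectomy": params.surgery["hysterectomy"].p[sl],
            "sterilization": params.sterilization_effective().p[sl],
            "other_gyn": params.surgery["other_gyn"].p[sl],
            "nongyn": params.surgery["nongyn"].p[sl],
        }

    # -- edge construction -------------------------------------------------
    def _state_edges(self, st: XState) -> list:
        space, params, strat = self.space, self.params, self.strategy
        hr = params.hr
        i = st.idx
        if not space.alive[i]:
            return []
        edges = [_Edge("bg", 1.0, space.death_other)]
        if space.in_oc_tunnel[i]:
            edges.append(_Edge("ocd", 1.0, space.death_oc, palliative=True))
            return edges
        if st.idx == space.oc_survivor:
            return edges

        # ovarian-cancer incidence at the state-modified hazard
        edges.append(_Edge("inc", space.h_cur[i], space.oc[0], primary=True))

        old = (space.h_lr[i], space.h_cur[i])
        uptake = params.os_uptake

        def allowed(new_lr, new_cur):
            return _improves(new_lr, new_cur, *old)

        # HE+BSO (requires intact uterus; removes the organs at risk)
        if space.has_uterus[i] and allowed(hr.hr_he_bso, hr.hr_he_bso):
            edges.append(_Edge("he_bso", 1.0, space.he_bso))

        # hysterectomy
        if space.has_uterus[i]:
            if st.base is HealthState.SALPINGECTOMY:
                # tubes already removed: plain hysterectomy, fallback tightens
                f = min(st.fallback, hr.hr_hysterectomy)
                tgt = space.salp_state(
                    HealthState.HE_SALPINGECTOMY,
                    None if st.clock is None else st.clock + 1,
                    f,
                )
                new = (space.h_lr[tgt], space.h_cur[tgt])
                if allowed(*new):
                    edges.append(_Edge("hysterectomy", 1.0, tgt))
            else:
                os_done = False
                if "hysterectomy" in strat.os_at and uptake > 0:
                    f = min(space.h_cur[i], hr.hr_hysterectomy)
                    tgt = space.os_entry(HealthState.HE_SALPINGECTOMY, f)
                    if allowed(space.h_lr[tgt], space.h_cur[tgt]):
                        edges.append(_Edge("hysterectomy", uptake, tgt, os=True))
                        os_done = True
                share = 1.0 - uptake if os_done else 1.0
                if share > 0 and allowed(hr.hr_hysterectomy, hr.hr_hysterectomy):
                    edges.append(_Edge("hysterectomy", share, space.hysterectomy))

        # sterilization (tubes intact, uterus intact, not already ligated)
        if st.base in (
            HealthState.HEALTHY,
            HealthState.NONGYN_SURG,
            HealthState.OTHER_GYN_SURG,
        ):
            os_done = False
            if "sterilization" in strat.os_at and uptake > 0:
                tgt = space.os_entry(HealthState.SALPINGECTOMY, 1.0)
                if allowed(space.h_lr[tgt], space.h_cur[tgt]):
                    edges.append(_Edge("sterilization", uptake, tgt, os=True))
                    os_done = True
            share = 1.0 - uptake if os_done else 1.0
            if share > 0 and allowed(hr.hr_tubal_ligation, hr.hr_tubal_ligation):
                edges.append(_Edge("sterilization", share, space.tubal_ligation))

        # other-gyn / non-gyn abdominal surgery: occasion for OS (from age
        # floor) if the strategy includes the category; otherwise neutral.
        for cat, book_state in (
            ("other_gyn", space.other_gyn_surg),
            ("nongyn", space.nongyn_surg),
        ):
            amin_os = strat.age_minimum_other
            os_added = False
            if cat in strat.os_at and space.has_tubes[i] and uptake > 0:
                if st.base is HealthState.HYSTERECTOMY:
                    tgt = space.os_entry(
                        HealthState.HE_SALPINGECTOMY, min(space.h_cur[i], hr.hr_hysterectomy)
                    )
                else:
                    tgt = space.os_entry(HealthState.SALPINGECTOMY, space.h_cur[i])
                if allowed(space.h_lr[tgt], space.h_cur[tgt]):
                    edges.append(_Edge(cat, uptake, tgt, amin=amin_os, os=True))
                    os_added = True
            # bookkeeping: first surgery without OS moves HEALTHY to the
            # corresponding surgery state (risk-neutral)
            if i == space.healthy:
                if os_added:
                    if uptake < 1.0:
                        edges.append(_Edge(cat, 1.0 - uptake, book_state, amin=amin_os))
                    if amin_os > AGE_MIN:
                        edges.append(_Edge(cat, 1.0, book_state, amax=amin_os - 1))
                else:
                    edges.append(_Edge(cat, 1.0, book_state))
        return edges

    # -- reward tables -----------------------------------------------------
    def _build_reward_tables(self, params: ParameterSet):
        space = self.space
        T = params.cycles
        S = space.n_states
        boundary_ages = params.start_age + np.arange(T + 1)
        pop_u = params.utilities.population_utility.at(boundary_ages)  # (T+1,)

        u_tab = np.zeros((S, T + 1))
        fu_vec = np.zeros(S)
        for st in space.states:
            i = st.idx
            if not space.alive[i]:
                continue
            if st.dx_year is not None and st.dx_year <= params.utilities.oc_utility_years:
                u_tab[i, :] = params.utilities.u_oc
            else:
                u_tab[i, :] = pop_u
            if st.dx_year is not None and st.dx_year <= min(
                params.costs.followup_years, space.dx_years
            ):
                fu_vec[i] = params.costs.oc_followup_annual
        self.utility_table = u_tab
        self.followup_vec = fu_vec
        self.alive_vec = space.alive.astype(float)


def build_transition_model(params: ParameterSet, strategy) -> TransitionModel:
    return TransitionModel(params, strategy)


def run_cohort(
    params: ParameterSet,
    strategy,
    validate: bool = True,
    tm: TransitionModel | None = None,
    return_distribution: bool = False,
) -> StrategyOutcome:
    """Propagate the full cohort and return exact expected outcomes.

    Occupancy rewards (life years, QALYs, follow-up cost) use the half-cycle
    convention: trapezoidal weighting of the state values at consecutive
    cycle boundaries with a half-cycle deducted at model entry, so an
    event-free lifetime yields 64.5 undiscounted life years over 65 cycles.
    One-time costs (OS, primary treatment, palliative care) are booked at the
    event cycle with that cycle's discount factor 1/(1+r)^t.
    """
    strategy = get_strategy(strategy)
    if validate:
        params.validate()
    if tm is None:
        tm = TransitionModel(params, strategy)
    space = tm.space
    S = space.n_states
    T = params.cycles
    costs = params.costs
    disc = (1.0 + costs.discount_rate) ** -np.arange(T, dtype=float)

    m = np.zeros(S)
    m[space.healthy] = 1.0
    masses = [m.copy()] if return_distribution else None

    flat_targets = tm.targets.ravel()
    acc = {k: 0.0 for k in (
        "ly_u", "ly_d", "qaly_u", "qaly_d", "fu_u", "fu_d",
        "cost_os_d", "cost_os_u", "cost_onetime_oc_d", "cost_onetime_oc_u",
        "cases", "oc_deaths", "os_events",
        "age_os_w", "age_os_s", "age_os_s2", "age_dx_w", "age_dx_s", "age_dx_s2",
    )}

    for t in range(T):
        P = tm.probs[t]
        flows = m[:, None] * P
        new_m = np.bincount(flat_targets, weights=flows.ravel(), minlength=S)
        total = new_m.sum()
        if abs(total - 1.0) > 1e-10:
            raise ValidationError(f"mass not conserved at cycle {t}: {total!r}")

        os_t = flows[tm.os_flag].sum()
        cases_t = flows[tm.primary_flag].sum()
        ocd_t = flows[tm.palliative_flag].sum()
        age = params.start_age + t
        acc["os_events"] += os_t
        acc["cases"] += cases_t
        acc["oc_deaths"] += ocd_t
        acc["age_os_w"] += os_t
        acc["age_os_s"] += os_t * age
        acc["age_os_s2"] += os_t * age * age
        acc["age_dx_w"] += cases_t
        acc["age_dx_s"] += cases_t * age
        acc["age_dx_s2"] += cases_t * age * age

        A0 = m @ tm.alive_vec
        A1 = new_m @ tm.alive_vec
        U0 = m @ tm.utility_table[:, t]
        U1 = new_m @ tm.utility_table[:, t + 1]
        F0 = m @ tm.followup_vec
        F1 = new_m @ tm.followup_vec
        ly_t = 0.5 * (A0 + A1) if params.half_cycle_effects else A0
        q_t = 0.5 * (U0 + U1) if params.half_cycle_effects else U0
        fu_t = 0.5 * (F0 + F1) if params.half_cycle_costs else F0
        acc["ly_u"] += ly_t
        acc["ly_d"] += disc[t] * ly_t
        acc["qaly_u"] += q_t
        acc["qaly_d"] += disc[t] * q_t
        acc["fu_u"] += fu_t
        acc["fu_d"] += disc[t] * fu_t

        os_cost_t = os_t * costs.os_cost
        oc_cost_t = cases_t * costs.oc_primary + ocd_t * costs.palliative
        acc["cost_os_u"] += os_cost_t
        acc["cost_os_d"] += disc[t] * os_cost_t
        acc["cost_onetime_oc_u"] += oc_cost_t
        acc["cost_onetime_oc_d"] += disc[t] * oc_cost_t

        m = new_m
        if return_distribution:
            masses.append(m.copy())

    if params.half_cycle_effects:
        acc["ly_u"] -= 0.5
        acc["ly_d"] -= 0.5 * disc[0]
        u0 = tm.utility_table[space.healthy, 0]
        acc["qaly_u"] -= 0.5 * u0
        acc["qaly_d"] -= 0.5 * disc[0] * u0

    def wmean_sd(w, s, s2):
        if w <= 0:
            return math.nan, math.nan
        mean = s / w
        var = max(0.0, s2 / w - mean * mean)
        return mean, math.sqrt(var)

    mean_os, sd_os = wmean_sd(acc["age_os_w"], acc["age_os_s"], acc["age_os_s2"])
    mean_dx, sd_dx = wmean_sd(acc["age_dx_w"], acc["age_dx_s"], acc["age_dx_s2"])

    out = StrategyOutcome(
        strategy=strategy.code,
        engine="cohort",
        n=None,
        cases_pc=acc["cases"],
        oc_deaths_pc=float(m[space.death_oc]),
        other_deaths_pc=float(m[space.death_other]),
        survivors_pc=float(m @ tm.alive_vec),
        os_events_pc=acc["os_events"],
        mean_age_os=mean_os,
        sd_age_os=sd_os,
        mean_age_dx=mean_dx,
        sd_age_dx=sd_dx,
        ly_undisc=acc["ly_u"],
        ly_disc=acc["ly_d"],
        qaly_undisc=acc["qaly_u"],
        qaly_disc=acc["qaly_d"],
        cost_os_pc=acc["cost_os_d"],
        cost_oc_pc=acc["cost_onetime_oc_d"] + acc["fu_d"],
        cost_os_pc_undisc=acc["cost_os_u"],
        cost_oc_pc_undisc=acc["cost_onetime_oc_u"] + acc["fu_u"],
    )
    if return_distribution:
        out.mass_history = np.array(masses)  # type: ignore[attr-defined]
    return out


def run_cohort_table(
    params: ParameterSet, strategies=("I", "II", "III", "IV"), reference: str = "IV"
) -> ResultsTable:
    """Run the cohort engine for several strategies and bundle the results."""
    params.validate()
    outcomes = {
        get_strategy(s).code: run_cohort(params, s, validate=False) for s in strategies
    }
    return ResultsTable(outcomes, reference=reference)
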