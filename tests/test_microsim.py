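"""Microsimulation: determinism, single-path hand computations, accounting,
common-random-numbers pairing, and agreement with the cohort oracle."""

import math

import numpy as np
import pytest

from ossim import (
    SimulationConfig,
    TransitionModel,
    convergence_scan,
    run_cohort,
    run_microsim,
    simulate_individual,
)
from ossim.microsim import _simulate, draw_uniforms

from conftest import age_indicator, make_params


class TestDeterminism:
    def test_same_seed_bit_identical(self, base_params):
        cfg = SimulationConfig(n_individuals=5_000, seed=7, strategies=("II", "IV"))
        a = run_microsim(base_params, cfg).comparison()
        b = run_microsim(base_params, cfg).comparison()
        assert a.equals(b)

    def test_different_seeds_differ(self, base_params):
        a = run_microsim(base_params, n_individuals=5_000, seed=1, strategies=("IV",))
        b = run_microsim(base_params, n_individuals=5_000, seed=2, strategies=("IV",))
        assert a["IV"].cases_pc != b["IV"].cases_pc


class TestSinglePaths:
    def test_event_free_draws_give_64_5_life_years(self, base_params):
        # draws near 1 always select the stay column (events partition first)
        traj = simulate_individual(np.full(65, 0.999999), base_params, "IV")
        assert traj.death_cause == "alive"
        assert traj.accumulators["ly_undisc"] == pytest.approx(64.5, abs=1e-12)
        assert traj.age_os == -1 and traj.age_dx == -1

    def test_forced_hysterectomy_at_45_under_strategy_iii(self):
        params = make_params(hysterectomy=age_indicator(45))
        draws = np.full(65, 0.5)  # hits the (certain) hysterectomy at cycle 25
        traj = simulate_individual(draws, params, "III")
        assert traj.age_os == 45
        assert "HE_SALPINGECTOMY" in traj.state_names[26]
        assert traj.accumulators["cost_os_disc"] == pytest.approx(
            216.19 * 1.03 ** -25, rel=1e-12
        )
        assert traj.accumulators["cost_os_undisc"] == pytest.approx(216.19)

    def test_paired_sterilization_path_iii_vs_iv(self):
        # identical draws; sterilization at age 30: III performs OS (cost,
        # HR 0.35 after latency), IV ligates (HR 0.72, no cost)
        params = make_params(sterilization=age_indicator(30))
        draws = np.full(65, 0.5)
        t3 = simulate_individual(draws, params, "III")
        t4 = simulate_individual(draws, params, "IV")
        assert t3.age_os == 30 and t4.age_os == -1
        assert "SALPINGECTOMY" in t3.state_names[11]
        assert "TUBAL_LIGATION" in t4.state_names[11]
        assert t3.accumulators["cost_os_undisc"] == pytest.approx(216.19)
        assert t4.accumulators["cost_os_undisc"] == 0.0
        # same survival with these draws: effects identical, costs differ
        assert t3.accumulators["ly_undisc"] == t4.accumulators["ly_undisc"]

    def test_latency_gates_the_hazard_ratio_on_paths(self, base_params):
        tm = TransitionModel(base_params, "III")
        space = tm.space
        entry = space.os_entry("SALPINGECTOMY", 1.0)
        st = space.states[entry]
        assert st.clock == 1
        assert space.h_cur[entry] == pytest.approx(1.0)  # still latent
        effective = space.salp_state("SALPINGECTOMY", None, 1.0)
        assert space.h_cur[effective] == pytest.approx(0.35)


class TestAccounting:
    def test_death_counts_plus_survivors_equal_n(self, base_params):
        table, ind = run_microsim(
            base_params, n_individuals=20_000, seed=3, strategies=("I", "IV"),
            return_individuals=True,
        )
        for code in ("I", "IV"):
            a = ind[code]
            n = len(a["final_state"])
            assert a["died_oc"].sum() + a["died_other"].sum() + (
                n - a["died_oc"].sum() - a["died_other"].sum()
            ) == n
            out = table[code]
            assert out.oc_deaths_pc + out.other_deaths_pc + out.survivors_pc == (
                pytest.approx(1.0, abs=1e-12)
            )

    def test_os_cost_change_leaves_clinical_outcomes_bit_identical(self, base_params):
        p2 = base_params.replace()
        p2.costs.os_cost = 500.0
        p2.costs.os_minutes = 500.0 / p2.costs.or_minute_price
        cfg = SimulationConfig(n_individuals=10_000, seed=5, strategies=("I",))
        a = run_microsim(base_params, cfg)["I"]
        b = run_microsim(p2, cfg)["I"]
        for attr in ("cases_pc", "oc_deaths_pc", "os_events_pc", "ly_disc",
                     "qaly_disc", "mean_age_os", "mean_age_dx", "cost_oc_pc"):
            assert getattr(a, attr) == getattr(b, attr)
        assert b.cost_os_pc > a.cost_os_pc


class TestCommonRandomNumbers:
    def test_paired_variance_smaller_than_unpaired(self, base_params):
        n = 40_000
        cfg = SimulationConfig(
            n_individuals=n, seed=11, strategies=("I", "IV"),
            common_random_numbers=True,
        )
        _, paired = run_microsim(base_params, cfg, return_individuals=True)
        d = paired["IV"]["ever_oc"].astype(float) - paired["I"]["ever_oc"].astype(float)
        var_paired = d.var()
        var_unpaired = paired["IV"]["ever_oc"].astype(float).var() + paired["I"][
            "ever_oc"
        ].astype(float).var()
        assert var_paired < var_unpaired

    def test_no_effect_limit_matches_reference_exactly(self, base_params):
        # HR 1 and free OS: OS can confer no risk reduction, so with common
        # draws the case histories coincide with no-OS wherever OS is the
        # only difference
        p = base_params.replace()
        p.hr.hr_salpingectomy = 1.0
        p.costs.os_cost = 0.0
        p.costs.os_minutes = 0.0
        cfg = SimulationConfig(n_individuals=20_000, seed=2, strategies=("I", "IV"))
        table = run_microsim(p, cfg)
        assert table["I"].cases_pc == table["IV"].cases_pc
        assert table["I"].oc_deaths_pc == table["IV"].oc_deaths_pc


class TestOracleEquivalence:
    def test_sample_means_within_three_monte_carlo_ses(self, base_params):
        n = 30_000
        cfg = SimulationConfig(n_individuals=n, seed=17, strategies=("I", "IV"))
        table = run_microsim(base_params, cfg)
        for code in ("I", "IV"):
            micro = table[code]
            exact = run_cohort(base_params, code, validate=False)
            p = exact.cases_pc
            se_cases = math.sqrt(p * (1 - p) / n)
            assert abs(micro.cases_pc - p) <= 3 * se_cases
            for mean_attr, sd_attr in (
                ("ly_disc", "sd_ly_disc"),
                ("qaly_disc", "sd_qaly_disc"),
            ):
                se = micro.se(sd_attr)
                assert abs(getattr(micro, mean_attr) - getattr(exact, mean_attr)) <= 3 * se
            se_cost = micro.sd_cost_total_pc / math.sqrt(n)
            assert abs(micro.cost_total_pc - exact.cost_total_pc) <= 3 * se_cost


class TestConvergence:
    def test_variance_decreases_roughly_like_one_over_n(self, base_params):
        frame = convergence_scan(
            [2_000, 8_000, 32_000], base_params, seed=4, rel_se_tolerance=0.5
        )
        v = frame["variance_prevented_fraction"].to_numpy()
        assert v[0] > v[1] > v[2]
        # 16-fold n increase: variance ratio within a factor ~2 of 16
        assert 6 < v[0] / v[2] < 40


class TestRatchet:
    def test_effective_hr_non_increasing_along_trajectories(self, base_params):
        tm = TransitionModel(base_params, "I")
        draws = draw_uniforms(seed=23, n=3_000, cycles=base_params.cycles)
        res = _simulate(tm, base_params, draws, record_states=True)
        h = tm.space.h_cur[res["states"]]  # NaN once cancer/death reached
        diffs = np.diff(h, axis=1)
        assert np.nanmax(diffs) <= 1e-12
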