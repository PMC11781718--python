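"""Unit and property tests for model inputs and scalar operations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ossim import (
    AgeSchedule,
    CalibrationError,
    HazardRatioSet,
    HealthState,
    InvalidInputError,
    STRATEGIES,
    ValidationError,
    annual_probability_from_counts,
    calibrate_sterilization_multiplier,
    effective_hazard_ratio,
    lifetime_first_event_proportion,
    load_parameter_tables,
    os_cost_from_minutes,
    weighted_cancer_utility,
    write_parameter_tables,
)
from ossim.params import N_AGES

from conftest import make_params


class TestAnnualProbability:
    @pytest.mark.parametrize(
        "count,pop,expected",
        [(0, 10_000, 0.0), (10_000, 10_000, 1.0), (137, 52_340, 137 / 52_340)],
    )
    def test_direct_division(self, count, pop, expected):
        assert annual_probability_from_counts(count, pop) == pytest.approx(expected)

    @pytest.mark.parametrize("count,pop", [(1, 0), (1, -5), (-1, 100), (101, 100)])
    def test_invalid_inputs(self, count, pop):
        with pytest.raises(InvalidInputError):
            annual_probability_from_counts(count, pop)


class TestOsCost:
    @pytest.mark.parametrize(
        "minutes,price,expected",
        [(13, 16.63, 216.19), (45, 16.63, 748.35), (4, 16.63, 66.52), (0, 16.63, 0.0)],
    )
    def test_minute_price(self, minutes, price, expected):
        assert os_cost_from_minutes(minutes, price) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            os_cost_from_minutes(-1, 16.63)
        with pytest.raises(InvalidInputError):
            os_cost_from_minutes(10, -0.5)

    @given(
        a=st.floats(0, 120, allow_nan=False),
        b=st.floats(0, 120, allow_nan=False),
        price=st.floats(0, 50, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_linear_in_minutes_up_to_cent_rounding(self, a, b, price):
        whole = os_cost_from_minutes(a + b, price)
        parts = os_cost_from_minutes(a, price) + os_cost_from_minutes(b, price)
        assert abs(whole - parts) <= 0.01 + 1e-9


class TestCancerUtility:
    def test_base_case_stage_weighting(self):
        assert weighted_cancer_utility(0.23, 0.81, 0.77, 0.55) == 0.61

    def test_degenerate_weight(self):
        assert weighted_cancer_utility(1.0, 0.81, 0.0, 0.55) == 0.81

    def test_hand_arithmetic(self):
        assert weighted_cancer_utility(0.5, 0.8, 0.5, 0.6) == 0.70

    @given(
        p=st.floats(0, 1, allow_nan=False),
        u1=st.floats(0, 1, allow_nan=False),
        u2=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_swap_invariance(self, p, u1, u2):
        assert weighted_cancer_utility(p, u1, 1 - p, u2) == pytest.approx(
            weighted_cancer_utility(1 - p, u2, p, u1), abs=1e-9
        )

    def test_weights_must_sum_to_one(self):
        with pytest.raises(InvalidInputError):
            weighted_cancer_utility(0.3, 0.8, 0.3, 0.5)


class TestEffectiveHazardRatio:
    hr = HazardRatioSet()

    @pytest.mark.parametrize(
        "state,years,expected",
        [
            (HealthState.SALPINGECTOMY, 6, 0.35),
            (HealthState.SALPINGECTOMY, 5, 0.35),
            (HealthState.SALPINGECTOMY, 2, 1.0),
            (HealthState.HE_SALPINGECTOMY, 2, 0.79),
            (HealthState.HE_SALPINGECTOMY, 7, 0.35),
            (HealthState.HEALTHY, None, 1.0),
            (HealthState.NONGYN_SURG, None, 1.0),
            (HealthState.OTHER_GYN_SURG, None, 1.0),
            (HealthState.HYSTERECTOMY, None, 0.79),
            (HealthState.TUBAL_LIGATION, None, 0.72),
            (HealthState.HE_BSO, None, 0.06),
        ],
    )
    def test_state_hr_with_latency(self, state, years, expected):
        assert effective_hazard_ratio(state, years, self.hr) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "state",
        [HealthState.OVARIAN_CANCER, HealthState.DEATH_OTHER, HealthState.DEATH_OC],
    )
    def test_cancer_and_absorbing_states_rejected(self, state):
        with pytest.raises(InvalidInputError):
            effective_hazard_ratio(state, 3, self.hr)


class TestSterilizationCalibration:
    def test_identity_when_target_already_met(self):
        sched = AgeSchedule.constant(0.002)
        mort = AgeSchedule.constant(0.001)
        target = lifetime_first_event_proportion(sched, mort)
        m = calibrate_sterilization_multiplier(sched, target, mort)
        assert m == pytest.approx(1.0, abs=1e-4)

    def test_flat_schedule_doubling_oracle(self):
        # brute-force oracle: target computed from the doubled schedule
        sched = AgeSchedule.constant(0.001)
        mort = AgeSchedule.constant(0.0)
        target = lifetime_first_event_proportion(AgeSchedule.constant(0.002), mort)
        m = calibrate_sterilization_multiplier(sched, target, mort)
        assert m == pytest.approx(2.0, rel=1e-3)

    @pytest.mark.parametrize("m_true", [0.5, 1.7, 3.0])
    def test_round_trip_recovery(self, m_true, base_params):
        inpatient = base_params.surgery["sterilization"]
        mort = base_params.background_mortality
        target = lifetime_first_event_proportion(inpatient.scaled(m_true), mort)
        m = calibrate_sterilization_multiplier(inpatient, target, mort)
        assert m == pytest.approx(m_true, rel=1e-3)

    def test_unreachable_target_raises(self):
        sched = AgeSchedule.constant(0.5)
        with pytest.raises(CalibrationError):
            calibrate_sterilization_multiplier(sched, 0.999999, AgeSchedule.constant(0.3))


class TestAgeSchedule:
    def test_requires_full_age_coverage(self):
        with pytest.raises(ValidationError):
            AgeSchedule(np.zeros(50))

    def test_out_of_range_age_rejected(self):
        s = AgeSchedule.constant(0.1)
        with pytest.raises(InvalidInputError):
            s.at(19)
        with pytest.raises(InvalidInputError):
            s.at(86)
        assert s.at(85) == 0.1


class TestStrategies:
    def test_nested_category_sets(self):
        # I contains II contains III contains IV (empty)
        assert STRATEGIES["I"].os_at >= STRATEGIES["II"].os_at
        assert STRATEGIES["II"].os_at >= STRATEGIES["III"].os_at
        assert STRATEGIES["III"].os_at >= STRATEGIES["IV"].os_at
        assert STRATEGIES["IV"].os_at == frozenset()


class TestValidation:
    def test_probability_above_one_names_cell(self):
        p = make_params()
        p.oc_incidence = AgeSchedule(
            np.where(np.arange(N_AGES) == 33, 1.2, 0.0)
        )
        with pytest.raises(ValidationError, match="age 53") as exc:
            p.validate()
        assert "oc_incidence" in str(exc.value)

    def test_competing_probabilities_capped(self):
        with pytest.raises(ValidationError, match="sum"):
            make_params(bg=0.3, inc=0.3, hysterectomy=0.3, nongyn=0.3)

    def test_os_cost_minute_consistency(self):
        p = make_params()
        p.costs.os_cost = 999.0  # no longer 13 min x 16.63
        with pytest.raises(ValidationError, match="os_cost"):
            p.validate()


class TestFixtureIO:
    def test_missing_age_rows_reported(self, tmp_path, base_params):
        cfg = write_parameter_tables(base_params, tmp_path)
        sched = tmp_path / "schedules.csv"
        lines = sched.read_text().splitlines()
        sched.write_text("\n".join(lines[:-3]) + "\n")  # drop ages 83-85
        with pytest.raises(ValidationError, match="missing age rows"):
            load_parameter_tables(cfg)

    def test_missing_column_reported(self, tmp_path, base_params):
        cfg = write_parameter_tables(base_params, tmp_path)
        sched = tmp_path / "schedules.csv"
        frame = sched.read_text().splitlines()
        header = frame[0].replace("nongyn", "nongyn_x")
        sched.write_text("\n".join([header] + frame[1:]))
        with pytest.raises(ValidationError, match="nongyn"):
            load_parameter_tables(cfg)

    def test_nonexistent_config(self, tmp_path):
        with pytest.raises(ValidationError):
            load_parameter_tables(tmp_path / "nope.yaml")
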