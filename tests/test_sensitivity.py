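"""One-way sweeps, threshold bisection, and probabilistic sensitivity analysis."""

import math

import numpy as np
import pytest

from ossim import (
    DistributionSpec,
    SweepSpec,
    find_parameter_threshold,
    one_way_sweep,
    run_cohort_table,
    run_psa,
    set_parameter,
)
from ossim.params import InvalidInputError


class TestSetParameter:
    def test_unknown_parameter_rejected(self, base_params):
        with pytest.raises(InvalidInputError):
            set_parameter(base_params, "not_a_parameter", 1.0)

    def test_override_does_not_mutate_base(self, base_params):
        p = set_parameter(base_params, "hr_salpingectomy", 0.5)
        assert p.hr.hr_salpingectomy == 0.5
        assert base_params.hr.hr_salpingectomy == 0.35

    def test_os_cost_override_keeps_minute_consistency(self, base_params):
        p = set_parameter(base_params, "os_cost", 400.0)
        p.validate()


class TestSweepSpec:
    def test_unsorted_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            SweepSpec("os_cost", (300.0, 100.0))

    def test_out_of_bounds_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            SweepSpec("hr_salpingectomy", (0.05, 0.5))


class TestOneWaySweep:
    def test_base_value_grid_reproduces_base_case(self, base_params):
        base_table = run_cohort_table(base_params, ("I", "IV"))
        frame = one_way_sweep(
            SweepSpec("os_cost", (base_params.costs.os_cost,)),
            base_params,
            strategies=("I",),
            include_base_case=False,
        )
        row = frame.iloc[0]
        assert row["prevented_cases_pct"] == pytest.approx(
            base_table.prevented_cases_pct("I"), rel=1e-12
        )
        assert row["icer_vs_ref"] == pytest.approx(
            base_table.icer_vs_reference("I"), rel=1e-12
        )

    def test_icer_strictly_increasing_along_os_cost_grid(self, base_params):
        frame = one_way_sweep(
            SweepSpec("os_cost", (100.0, 216.19, 400.0, 700.0)),
            base_params,
            strategies=("I",),
            include_base_case=False,
        )
        icers = frame.sort_values("value")["icer_vs_ref"].to_numpy()
        assert np.all(np.diff(icers) > 0)

    def test_weak_risk_reduction_collapses_prevented_fraction(self, base_params):
        frame = one_way_sweep(
            SweepSpec("hr_salpingectomy", (0.2, 0.73)),
            base_params,
            strategies=("I", "III"),
            include_base_case=False,
        )
        strong = frame[(frame.value == 0.2) & (frame.strategy == "I")].iloc[0]
        weak = frame[(frame.value == 0.73) & (frame.strategy == "I")].iloc[0]
        assert weak["prevented_cases_pct"] < 0.45 * strong["prevented_cases_pct"]
        # strategy III relies on sterilization OS, which the ratchet skips
        # entirely once the salpingectomy HR exceeds the tubal-ligation HR
        weak3 = frame[(frame.value == 0.73) & (frame.strategy == "III")].iloc[0]
        assert weak3["prevented_cases_pct"] < weak["prevented_cases_pct"]


class TestThresholdFinder:
    def test_threshold_agrees_with_sweep_bracket(self, base_params):
        res = find_parameter_threshold("os_cost", "icer>0", base_params, "I")
        assert res.value is not None
        frame = one_way_sweep(
            SweepSpec("os_cost", (res.value - 5.0, res.value + 5.0),
                      bounds=(0.0, 10_000.0)),
            base_params,
            strategies=("I",),
            include_base_case=False,
        )
        below, above = frame.sort_values("value")["icer_vs_ref"].to_numpy()
        assert below < 0 < above

    def test_predicate_never_true_reports_no_threshold(self, base_params):
        # the ICER never exceeds 2x GDP/C anywhere on the HR bounds for
        # strategy I in this base case
        res = find_parameter_threshold(
            "hr_salpingectomy", "icer>2gdp", base_params, "I", bounds=(0.17, 0.60)
        )
        assert res.value is None

    def test_latency_threshold_within_bounds(self, base_params):
        res = find_parameter_threshold(
            "latency_years_os", "icer>0", base_params, "I", bounds=(0.0, 30.0),
            tol=0.1,
        )
        assert res.value is not None and 5.0 < res.value < 30.0


class TestPSA:
    def test_point_mass_distributions_reproduce_base_classification(self, base_params):
        dists = [
            DistributionSpec("hr_salpingectomy", "uniform", {"low": 0.35, "high": 0.35}),
            DistributionSpec("os_cost", "uniform", {"low": 216.19, "high": 216.19}),
        ]
        res = run_psa(base_params, dists, n_samples=4, seed=0, strategies=("I",))
        assert set(res.summary["frac_clinically_effective"]) == {1.0}
        assert set(res.summary["frac_icer_below_1xGDP"]) == {1.0}
        base = run_cohort_table(base_params, ("I", "IV"))
        sample = res.samples.iloc[0]
        assert sample["prevented_cases_pct"] == pytest.approx(
            base.prevented_cases_pct("I"), rel=1e-9
        )

    def test_reproducible_and_threshold_fractions_monotone(self, base_params):
        a = run_psa(base_params, n_samples=40, seed=9, strategies=("I", "III"))
        b = run_psa(base_params, n_samples=40, seed=9, strategies=("I", "III"))
        assert a.samples.equals(b.samples)
        for _, row in a.summary.iterrows():
            assert (
                row["frac_icer_below_1xGDP"]
                <= row["frac_icer_below_2xGDP"]
                <= 1.0
            )
            assert 0.0 <= row["frac_clinically_effective"] <= 1.0

    def test_default_hr_distribution_spans_the_ci(self, base_params):
        res = run_psa(base_params, n_samples=60, seed=3, strategies=("I",))
        hr = res.samples["hr_salpingectomy"]
        assert 0.1 < hr.median() < 0.6
        assert hr.max() <= 1.0

    def test_requires_at_least_two_samples(self, base_params):
        with pytest.raises(InvalidInputError):
            run_psa(base_params, n_samples=1)
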