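"""Per-strategy outcome aggregates and strategy-comparison tables.

``StrategyOutcome`` mirrors the quantities of the base-case results table:
ovarian-cancer cases and deaths, salpingectomies, mean ages at OS and at
diagnosis, per-capita (quality-adjusted) life years discounted and
undiscounted, per-capita cost components, and (via ``ResultsTable``)
prevented fractions, savings, CER and ICER against the reference strategy.

Cohort-engine outcomes are exact expectations (per-capita, ``n`` is None,
SDs are NaN); microsimulation outcomes carry Monte-Carlo SDs and standard
errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd


@dataclass
class StrategyOutcome:
    """Aggregate outcomes of one strategy run (per capita unless noted)."""

    strategy: str
    engine: str  # "cohort" or "microsim"
    n: int | None = None  # simulated individuals (None for cohort engine)

    cases_pc: float = 0.0  # ovarian-cancer diagnoses per capita
    oc_deaths_pc: float = 0.0
    other_deaths_pc: float = 0.0
    survivors_pc: float = 0.0  # alive at end of horizon
    os_events_pc: float = 0.0  # salpingectomies performed per capita

    mean_age_os: float = math.nan
    sd_age_os: float = math.nan
    mean_age_dx: float = math.nan
    sd_age_dx: float = math.nan

    ly_undisc: float = 0.0
    ly_disc: float = 0.0
    qaly_undisc: float = 0.0
    qaly_disc: float = 0.0
    sd_ly_undisc: float = math.nan
    sd_ly_disc: float = math.nan
    sd_qaly_undisc: float = math.nan
    sd_qaly_disc: float = math.nan

    # discounted cost components (euros per capita)
    cost_os_pc: float = 0.0
    cost_oc_pc: float = 0.0  # primary + follow-up + palliative
    sd_cost_os_pc: float = math.nan
    sd_cost_oc_pc: float = math.nan
    sd_cost_total_pc: float = math.nan
    # undiscounted totals (not part of the headline table, kept for checks)
    cost_os_pc_undisc: float = 0.0
    cost_oc_pc_undisc: float = 0.0

    @property
    def cost_total_pc(self) -> float:
        return self.cost_os_pc + self.cost_oc_pc

    @property
    def lifetime_risk_denominator(self) -> float:
        """x in the '1 : x' lifetime ovarian-cancer risk."""
        return 1.0 / self.cases_pc if self.cases_pc > 0 else math.inf

    def se(self, sd_attr: str) -> float:
        """Monte-Carlo standard error of a mean from its population SD."""
        sd = getattr(self, sd_attr)
        if self.n is None or not math.isfinite(sd):
            return math.nan
        return sd / math.sqrt(self.n)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["cost_total_pc"] = self.cost_total_pc
        d["lifetime_risk_denominator"] = self.lifetime_risk_denominator
        return d


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (used for the national extrapolation block)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ResultsTable:
    """Outcomes for a set of strategies plus derived comparisons vs a reference."""

    outcomes: dict  # strategy code -> StrategyOutcome
    reference: str = "IV"

    def __getitem__(self, code) -> StrategyOutcome:
        return self.outcomes[code]

    def __contains__(self, code):
        return code in self.outcomes

    @property
    def strategies(self):
        return list(self.outcomes)

    def prevented_cases_pct(self, code) -> float:
        ref = self.outcomes[self.reference]
        if ref.cases_pc == 0:
            return math.nan
        return 100.0 * (ref.cases_pc - self.outcomes[code].cases_pc) / ref.cases_pc

    def prevented_deaths_pct(self, code) -> float:
        ref = self.outcomes[self.reference]
        if ref.oc_deaths_pc == 0:
            return math.nan
        return 100.0 * (ref.oc_deaths_pc - self.outcomes[code].oc_deaths_pc) / ref.oc_deaths_pc

    def salpingectomies_per_prevented_case(self, code) -> float:
        """Number of salpingectomies needed to prevent one ovarian-cancer case.

        Undefined (NaN) when no cases are prevented; never raises."""
        ref = self.outcomes[self.reference]
        prevented = ref.cases_pc - self.outcomes[code].cases_pc
        s = self.outcomes[code]
        if prevented <= 0 or s.os_events_pc == 0:
            return math.nan
        return s.os_events_pc / prevented

    def icer_vs_reference(self, code, effect: str = "qaly_disc") -> float:
        """Incremental cost per incremental (discounted) effect unit vs the
        reference; NaN when the effect difference is zero."""
        ref = self.outcomes[self.reference]
        s = self.outcomes[code]
        d_eff = getattr(s, effect) - getattr(ref, effect)
        d_cost = s.cost_total_pc - ref.cost_total_pc
        if d_eff == 0:
            return math.nan
        return d_cost / d_eff

    def comparison(self) -> pd.DataFrame:
        """Tidy one-row-per-strategy comparison table."""
        rows = []
        ref = self.outcomes[self.reference]
        for code, s in self.outcomes.items():
            is_ref = code == self.reference
            row = s.to_dict()
            row.update(
                prevented_cases_pct=math.nan if is_ref else self.prevented_cases_pct(code),
                prevented_deaths_pct=math.nan if is_ref else self.prevented_deaths_pct(code),
                salpingectomies_per_prevented_case=(
                    math.nan if is_ref else self.salpingectomies_per_prevented_case(code)
                ),
                ly_gained_undisc=s.ly_undisc - ref.ly_undisc,
                ly_gained_disc=s.ly_disc - ref.ly_disc,
                qaly_gained_undisc=s.qaly_undisc - ref.qaly_undisc,
                qaly_gained_disc=s.qaly_disc - ref.qaly_disc,
                savings_pc=ref.cost_total_pc - s.cost_total_pc,
                savings_pct=(
                    100.0 * (ref.cost_total_pc - s.cost_total_pc) / ref.cost_total_pc
                    if ref.cost_total_pc
                    else math.nan
                ),
                cer=(s.cost_total_pc / s.qaly_disc if s.qaly_disc else math.nan),
                icer_vs_ref=math.nan if is_ref else self.icer_vs_reference(code),
                icer_ly_vs_ref=(
                    math.nan if is_ref else self.icer_vs_reference(code, "ly_disc")
                ),
            )
            rows.append(row)
        return pd.DataFrame(rows).set_index("strategy")

    def national_extrapolation(
        self, annual_cases: float = 7180.0, annual_deaths: float = 5265.0
    ) -> pd.DataFrame:
        """Prevented annual national cases/deaths: unrounded prevented fraction
        times the national annual count, rounded half-up."""
        rows = []
        for code in self.outcomes:
            if code == self.reference:
                continue
            pc = self.prevented_cases_pct(code)
            pd_ = self.prevented_deaths_pct(code)
            rows.append(
                {
                    "strategy": code,
                    "prevented_cases_pct": pc,
                    "prevented_deaths_pct": pd_,
                    "preventable_annual_cases": round_half_up(pc / 100.0 * annual_cases),
                    "preventable_annual_deaths": round_half_up(pd_ / 100.0 * annual_deaths),
                }
            )
        return pd.DataFrame(rows).set_index("strategy")

    def report_frame(self) -> pd.DataFrame:
        """Headline comparison with strategies as columns (base-case table shape)."""
        comp = self.comparison()
        rows = [
            "cases_pc", "prevented_cases_pct", "lifetime_risk_denominator",
            "oc_deaths_pc", "prevented_deaths_pct", "mean_age_dx", "sd_age_dx",
            "os_events_pc", "salpingectomies_per_prevented_case",
            "mean_age_os", "sd_age_os",
            "ly_undisc", "ly_gained_undisc", "ly_disc", "ly_gained_disc",
            "qaly_undisc", "qaly_gained_undisc", "qaly_disc", "qaly_gained_disc",
            "cost_os_pc", "cost_oc_pc", "cost_total_pc", "savings_pc", "savings_pct",
            "cer", "icer_vs_ref",
        ]
        return comp[rows].T

    def to_csv(self, path) -> None:
        self.comparison().to_csv(path)
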