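"""Decision-tree cohort evaluation: expected discounted lifetime cost and QALYs.

Each resuscitated patient is assigned a strategy and lands in one of three
mutually exclusive states fixed at 6 months — good neurologic outcome
(CPC 1-2), poor outcome (CPC 3-4), or dead — with probabilities derived from
the strategy's mortality and good-outcome-given-survival parameters.  The
hospital episode (ICU, floor, cooling, sedation, ICD, rehabilitation) accrues
undiscounted in year 0; recurring post-hospital costs and utilities accrue
annually over the outcome-specific life expectancy, discounted at the shared
annual rate with accrual at cycle start and a fractional final cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .parameters import ModelConfig, SharedParams, StrategyParams

__all__ = [
    "OutcomeDistribution",
    "StrategyResult",
    "outcome_distribution",
    "discounted_duration",
    "hospital_cost",
    "posthospital_cost",
    "lifetime_qaly",
    "evaluate_strategy",
    "evaluate_all",
    "calibrate_f_vent",
]

Outcome = Literal["good", "poor", "dead"]
_OUTCOMES = ("good", "poor", "dead")


@dataclass(frozen=True)
class OutcomeDistribution:
    """Probabilities of the three terminal states for one strategy."""

    p_good: float
    p_poor: float
    p_dead: float

    def __post_init__(self) -> None:
        for name in ("p_good", "p_poor", "p_dead"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.p_good + self.p_poor + self.p_dead - 1.0) > 1e-9:
            raise ValueError("outcome probabilities must sum to 1")


@dataclass(frozen=True)
class StrategyResult:
    """Expected discounted lifetime cost (USD) and QALYs for one strategy."""

    name: str
    expected_cost: float
    expected_qaly: float


def outcome_distribution(
    strategy: StrategyParams,
    p_death: float | None = None,
    p_good_given_survival: float | None = None,
) -> OutcomeDistribution:
    """Terminal-state probabilities; base-case values unless overridden."""
    d = strategy.p_death.base if p_death is None else p_death
    g = (
        strategy.p_good_given_survival.base
        if p_good_given_survival is None
        else p_good_given_survival
    )
    if not 0.0 <= d <= 1.0 or not 0.0 <= g <= 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    return OutcomeDistribution(
        p_good=(1.0 - d) * g, p_poor=(1.0 - d) * (1.0 - g), p_dead=d
    )


def discounted_duration(years, rate):
    """Discounted person-years of an annuity of `years` at annual `rate`.

    Annual cycles accrued at cycle start with a fractional final cycle:
    sum over t = 0..ceil(years)-1 of min(1, years - t) * (1 + rate)^-t.
    Closed form with n = floor(years), x = 1/(1+rate):
    (1 - x^n)/(1 - x) + (years - n) * x^n.  Equals `years` at rate 0.
    Accepts scalars or numpy arrays in `years`.
    """
    y = np.asarray(years, dtype=float)
    r = np.asarray(rate, dtype=float)
    if np.any(y < 0):
        raise ValueError("years must be non-negative")
    if np.any(r < 0):
        raise ValueError("rate must be non-negative")
    x = 1.0 / (1.0 + r)
    n = np.floor(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        geom = (1.0 - x**n) / (1.0 - x)
    # x == 1.0 covers rate 0 and rates below float resolution
    out = np.where(x == 1.0, y, geom + (y - n) * x**n)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# core arithmetic on plain value mappings (scalars or aligned numpy arrays);
# the probabilistic sensitivity analysis reuses these with sampled arrays.
# ---------------------------------------------------------------------------

def _hospital_cost(sv: Mapping, shv: Mapping, outcome: Outcome):
    fixed = sv["cooling_cost"] + sv["sedation_cost"]
    if outcome == "dead":
        # non-survivors: short ICU stay only, no floor or post-hospital care
        return fixed + sv["icu_days_nonsurvivor"] * shv["c_icu_day"]
    return (
        fixed
        + sv["icu_days_survivor"] * shv["c_icu_day"]
        + sv["floor_days"] * shv["c_floor_day"]
    )


def _posthospital_cost(shv: Mapping, outcome: Outcome):
    rate = shv["discount_rate"]
    if outcome == "dead":
        return 0.0
    if outcome == "good":
        annual = (
            shv["outpatient_annual_good"]
            + shv["transport_annual_good"]
            + shv["caregiver_clinic_annual"]
        )
        return (
            shv["icd_cost"]
            + shv["rehab_daily"] * shv["rehab_days"]
            + annual * discounted_duration(shv["le_good"], rate)
        )
    daily = shv["f_vent"] * shv["vent_daily"] + (1.0 - shv["f_vent"]) * shv["ltc_daily"]
    annual = (
        365.0 * daily
        + shv["outpatient_annual_poor"]
        + shv["transport_annual_poor"]
        + shv["opportunity_cost_annual_poor"]
    )
    return annual * discounted_duration(shv["le_poor"], rate)


def _lifetime_qaly(shv: Mapping, outcome: Outcome):
    rate = shv["discount_rate"]
    if outcome == "dead":
        return 0.0
    if outcome == "good":
        return shv["u_good"] * discounted_duration(shv["le_good"], rate)
    return shv["u_poor"] * discounted_duration(shv["le_poor"], rate)


def _evaluate_values(name: str, sv: Mapping, shv: Mapping):
    """Expected (cost, qaly) from value mappings; vectorizes over arrays."""
    d = sv["p_death"]
    g = sv["p_good_given_survival"]
    p = {"good": (1 - d) * g, "poor": (1 - d) * (1 - g), "dead": d}
    cost = sum(
        p[o] * (_hospital_cost(sv, shv, o) + _posthospital_cost(shv, o))
        for o in _OUTCOMES
    )
    qaly = sum(p[o] * _lifetime_qaly(shv, o) for o in _OUTCOMES)
    return cost, qaly


def _bases(block) -> dict[str, float]:
    return {f: p.base for f, p in block.params()}


# ---------------------------------------------------------------------------
# public surface on the dataclasses
# ---------------------------------------------------------------------------

def hospital_cost(
    strategy: StrategyParams, shared: SharedParams, outcome: Outcome
) -> float:
    """Year-0 (undiscounted) hospital-episode cost for one outcome branch."""
    return float(_hospital_cost(_bases(strategy), _bases(shared), outcome))


def posthospital_cost(shared: SharedParams, outcome: Outcome) -> float:
    """Discounted post-hospital cost stream for one outcome branch.

    Good outcome: one-time ICD and rehabilitation in year 0 plus annual
    outpatient/transport/caregiver costs over the good-outcome life
    expectancy.  Poor outcome: annual institutional care (f_vent of days at
    the chronic-ventilator rate, the rest at the long-term-care rate) plus
    outpatient, transport and caregiver opportunity costs over the
    poor-outcome life expectancy.  Dead: zero.
    """
    return float(_posthospital_cost(_bases(shared), outcome))


def lifetime_qaly(shared: SharedParams, outcome: Outcome) -> float:
    """Discounted QALYs: utility times discounted life expectancy."""
    return float(_lifetime_qaly(_bases(shared), outcome))


def evaluate_strategy(
    strategy: StrategyParams, shared: SharedParams
) -> StrategyResult:
    """Probability-weighted expected discounted cost and QALYs."""
    cost, qaly = _evaluate_values(strategy.name, _bases(strategy), _bases(shared))
    return StrategyResult(strategy.name, float(cost), float(qaly))


def evaluate_all(config: ModelConfig) -> list[StrategyResult]:
    """Evaluate every strategy, preserving config order."""
    return [evaluate_strategy(s, config.shared) for s in config.strategies]


def calibrate_f_vent(
    config: ModelConfig,
    target_cost: float,
    strategy_name: str = "Conventional Care",
) -> ModelConfig:
    """Solve the poor-outcome ventilator/long-term-care mix fraction so the
    named strategy's expected cost equals ``target_cost``.

    Expected cost is affine in f_vent, so the solve is exact.  Returns a new
    config with shared.f_vent fixed at the solution; raises ``ValueError``
    if no f_vent in [0, 1] reaches the target.
    """
    strat = config.strategy(strategy_name)
    shv0 = dict(_bases(config.shared), f_vent=0.0)
    shv1 = dict(_bases(config.shared), f_vent=1.0)
    c0, _ = _evaluate_values(strat.name, _bases(strat), shv0)
    c1, _ = _evaluate_values(strat.name, _bases(strat), shv1)
    if c1 == c0:
        raise ValueError("expected cost does not depend on f_vent here")
    f = (target_cost - c0) / (c1 - c0)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"calibration infeasible: f_vent = {f:.4f} outside [0, 1]")
    from .parameters import Param

    return config.with_param("shared/f_vent", Param.fixed("f_vent", f, "rate"))
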