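"""Random structurally-valid configs and brute-force oracles.

The generator exists to exercise code paths, not to mimic epidemiology:
base values are drawn uniformly within per-kind bounds and range half-widths
from a scaled uniform, with orderings (utility/life-expectancy of good vs
poor outcome, survivor vs non-survivor ICU days) enforced by construction.
The oracles re-derive frontier membership and strategy expectations by
routes independent of the main implementation, for use in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_model import StrategyResult
from .parameters import ModelConfig, Param, SharedParams, StrategyParams

__all__ = ["GeneratorSpec", "random_config", "brute_force_frontier", "branch_oracle"]

DEFAULT_BOUNDS = {
    "probability": (0.01, 0.99),
    "cost_usd": (0.0, 60_000.0),
    "utility": (0.05, 0.95),
    "duration_days": (0.5, 40.0),
    "duration_years": (0.25, 12.0),
    "rate": (0.0, 0.08),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Controls for the random-config generator."""

    seed: int = 0
    n_strategies: int = 4
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    width_frac: float = 0.3  # max range half-width as fraction of kind span

    def __post_init__(self) -> None:
        if self.n_strategies < 2:
            raise ValueError("n_strategies must be >= 2")
        if not 0.0 <= self.width_frac <= 1.0:
            raise ValueError("width_frac must lie in [0, 1]")
        for kind, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"infeasible bounds for kind {kind!r}")


def _draw(rng: np.random.Generator, id: str, kind: str, spec: GeneratorSpec,
          base: float | None = None) -> Param:
    lo_k, hi_k = spec.bounds[kind]
    if base is None:
        base = rng.uniform(lo_k, hi_k)
    span = (hi_k - lo_k) * spec.width_frac
    low = max(lo_k, base - rng.uniform(0.0, span))
    high = min(hi_k, base + rng.uniform(0.0, span))
    return Param(id, float(base), float(low), float(high), kind)


def random_config(spec: GeneratorSpec) -> ModelConfig:
    """A ModelConfig passing ``validate`` with probability one, reproducible
    under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    strategies = []
    for i in range(spec.n_strategies):
        icu_a = rng.uniform(*spec.bounds["duration_days"], size=2)
        icu_surv, icu_non = float(icu_a.max()), float(icu_a.min())
        strategies.append(
            StrategyParams(
                name=f"S{i + 1}",
                p_death=_draw(rng, "p_death", "probability", spec),
                p_good_given_survival=_draw(
                    rng, "p_good_given_survival", "probability", spec
                ),
                cooling_cost=_draw(rng, "cooling_cost", "cost_usd", spec),
                sedation_cost=_draw(rng, "sedation_cost", "cost_usd", spec),
                icu_days_survivor=_draw(
                    rng, "icu_days_survivor", "duration_days", spec, base=icu_surv
                ),
                icu_days_nonsurvivor=_draw(
                    rng, "icu_days_nonsurvivor", "duration_days", spec, base=icu_non
                ),
                floor_days=_draw(rng, "floor_days", "duration_days", spec),
            )
        )
    u = np.sort(rng.uniform(*spec.bounds["utility"], size=2))
    le = np.sort(rng.uniform(*spec.bounds["duration_years"], size=2))
    shared = SharedParams(
        c_icu_day=_draw(rng, "c_icu_day", "cost_usd", spec),
        c_floor_day=_draw(rng, "c_floor_day", "cost_usd", spec),
        icd_cost=_draw(rng, "icd_cost", "cost_usd", spec),
        rehab_daily=_draw(rng, "rehab_daily", "cost_usd", spec),
        rehab_days=_draw(rng, "rehab_days", "duration_days", spec),
        transport_annual_good=_draw(rng, "transport_annual_good", "cost_usd", spec),
        caregiver_clinic_annual=_draw(
            rng, "caregiver_clinic_annual", "cost_usd", spec
        ),
        outpatient_annual_good=_draw(rng, "outpatient_annual_good", "cost_usd", spec),
        outpatient_annual_poor=_draw(rng, "outpatient_annual_poor", "cost_usd", spec),
        vent_daily=_draw(rng, "vent_daily", "cost_usd", spec),
        ltc_daily=_draw(rng, "ltc_daily", "cost_usd", spec),
        opportunity_cost_annual_poor=_draw(
            rng, "opportunity_cost_annual_poor", "cost_usd", spec
        ),
        transport_annual_poor=_draw(rng, "transport_annual_poor", "cost_usd", spec),
        f_vent=Param("f_vent", float(rng.uniform()), 0.0, 1.0, "rate"),
        le_good=_draw(rng, "le_good", "duration_years", spec, base=float(le[1])),
        le_poor=_draw(rng, "le_poor", "duration_years", spec, base=float(le[0])),
        u_good=_draw(rng, "u_good", "utility", spec, base=float(u[1])),
        u_poor=_draw(rng, "u_poor", "utility", spec, base=float(u[0])),
        discount_rate=_draw(rng, "discount_rate", "rate", spec),
    )
    return ModelConfig(
        strategies=tuple(strategies), shared=shared, wtp_default=100_000.0
    )


def brute_force_frontier(results, wtp_grid=None, lambda_max=None) -> set[str]:
    """Frontier membership by exhaustive NMB-argmax over a WTP grid.

    A strategy is on the frontier iff it attains the maximal net monetary
    benefit (ties: lowest cost, then highest QALYs, then input order) for at
    least one grid threshold.  When no grid is given, one is built from the
    pairwise incremental ratios with evaluation points just below and above
    every knot, so no preference interval can be straddled.
    """
    results = list(results)
    if wtp_grid is None:
        knots = []
        for i, a in enumerate(results):
            for b in results[i + 1 :]:
                dq = b.expected_qaly - a.expected_qaly
                dc = b.expected_cost - a.expected_cost
                if dq != 0 and dc / dq > 0:
                    knots.append(dc / dq)
        lmax = lambda_max or (2.0 * max(knots, default=0.0) + 1.0)
        grid = {0.0, lmax}
        for k in knots:
            eps = max(abs(k), 1.0) * 1e-7
            grid.update((max(0.0, k - eps), k, k + eps))
        wtp_grid = sorted(grid)
    wtp_grid = list(np.asarray(wtp_grid, float))
    if not wtp_grid:
        raise ValueError("wtp grid must be non-empty")

    members: set[str] = set()
    for lam in wtp_grid:
        nmb = [lam * r.expected_qaly - r.expected_cost for r in results]
        best = max(nmb)
        cand = [i for i, v in enumerate(nmb) if v >= best - 1e-9]
        cand.sort(
            key=lambda i: (
                results[i].expected_cost,
                -results[i].expected_qaly,
                i,
            )
        )
        members.add(results[cand[0]].name)
    return members


def branch_oracle(strategy: StrategyParams, shared: SharedParams) -> StrategyResult:
    """Expected cost/QALYs by literal leaf-by-leaf enumeration.

    Deliberately shares no code with ``cohort_model.evaluate_strategy``:
    discount factors come from an explicit per-year loop and the three
    decision-tree leaves are written out one by one.
    """
    b = lambda p: p.base  # noqa: E731

    def annuity(years: float, rate: float) -> float:
        total, t = 0.0, 0
        while t < years:
            total += min(1.0, years - t) / (1.0 + rate) ** t
            t += 1
        return total

    rate = b(shared.discount_rate)
    ann_good = annuity(b(shared.le_good), rate)
    ann_poor = annuity(b(shared.le_poor), rate)

    # leaf 1: good neurologic outcome
    p_good = (1.0 - b(strategy.p_death)) * b(strategy.p_good_given_survival)
    cost_good = (
        b(strategy.cooling_cost)
        + b(strategy.sedation_cost)
        + b(strategy.icu_days_survivor) * b(shared.c_icu_day)
        + b(strategy.floor_days) * b(shared.c_floor_day)
        + b(shared.icd_cost)
        + b(shared.rehab_daily) * b(shared.rehab_days)
        + (
            b(shared.outpatient_annual_good)
            + b(shared.transport_annual_good)
            + b(shared.caregiver_clinic_annual)
        )
        * ann_good
    )
    qaly_good = b(shared.u_good) * ann_good

    # leaf 2: poor neurologic outcome
    p_poor = (1.0 - b(strategy.p_death)) * (1.0 - b(strategy.p_good_given_survival))
    daily_inst = b(shared.f_vent) * b(shared.vent_daily) + (
        1.0 - b(shared.f_vent)
    ) * b(shared.ltc_daily)
    cost_poor = (
        b(strategy.cooling_cost)
        + b(strategy.sedation_cost)
        + b(strategy.icu_days_survivor) * b(shared.c_icu_day)
        + b(strategy.floor_days) * b(shared.c_floor_day)
        + (
            365.0 * daily_inst
            + b(shared.outpatient_annual_poor)
            + b(shared.transport_annual_poor)
            + b(shared.opportunity_cost_annual_poor)
        )
        * ann_poor
    )
    qaly_poor = b(shared.u_poor) * ann_poor

    # leaf 3: death
    p_dead = b(strategy.p_death)
    cost_dead = (
        b(strategy.cooling_cost)
        + b(strategy.sedation_cost)
        + b(strategy.icu_days_nonsurvivor) * b(shared.c_icu_day)
    )

    return StrategyResult(
        name=strategy.name,
        expected_cost=p_good * cost_good + p_poor * cost_poor + p_dead * cost_dead,
        expected_qaly=p_good * qaly_good + p_poor * qaly_poor,
    )
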