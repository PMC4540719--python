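"""ICERs, strict and extended dominance, and net monetary benefit.

The efficiency frontier is built by the standard iterative procedure: sort
strategies by expected cost, drop strictly dominated ones (no cheaper-or-equal
strategy is at least as effective), then repeatedly drop entries whose
incremental ICER is not below that of the next more effective option
(extended dominance), leaving strictly increasing ICERs along the frontier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .cohort_model import StrategyResult

__all__ = [
    "TIE_TOL",
    "IcerResult",
    "FrontierEntry",
    "FrontierReport",
    "icer",
    "efficiency_frontier",
    "net_monetary_benefit",
    "preferred_strategy",
]

#: absolute tolerance below which cost/QALY differences count as ties
TIE_TOL = 1e-9

IcerKind = Literal["ratio", "to_dominates", "from_dominates", "discordant"]


@dataclass(frozen=True)
class IcerResult:
    """Outcome of a pairwise incremental comparison.

    kind "ratio": `value` is delta cost / delta QALY (USD per QALY).
    kind "to_dominates"/"from_dominates": one strategy is at least as cheap
    and at least as effective; `value` is None.
    kind "discordant": both cheaper and less effective — the ratio is
    reported but its orientation is flagged (a willingness-to-accept, not a
    buying price).
    """

    kind: IcerKind
    value: float | None
    delta_cost: float
    delta_qaly: float


def icer(from_result: StrategyResult, to_result: StrategyResult) -> IcerResult:
    """Incremental comparison of `to_result` against `from_result`."""
    dc = to_result.expected_cost - from_result.expected_cost
    dq = to_result.expected_qaly - from_result.expected_qaly
    if abs(dc) <= TIE_TOL and abs(dq) <= TIE_TOL:
        raise ValueError(
            f"strategies {from_result.name!r} and {to_result.name!r} are "
            "indistinguishable (equal cost and QALYs)"
        )
    if dq >= -TIE_TOL and dc <= TIE_TOL:
        return IcerResult("to_dominates", None, dc, dq)
    if dq <= TIE_TOL and dc >= -TIE_TOL:
        return IcerResult("from_dominates", None, dc, dq)
    kind = "ratio" if (dq > 0 and dc > 0) else "discordant"
    return IcerResult(kind, dc / dq, dc, dq)


@dataclass(frozen=True)
class FrontierEntry:
    name: str
    expected_cost: float
    expected_qaly: float
    status: Literal["on_frontier", "dominated", "extended_dominated"]
    icer_vs_previous: float | None = None
    dominated_by: str | None = None


@dataclass(frozen=True)
class FrontierReport:
    """Dominance status of every strategy plus the cheapest frontier member."""

    entries: tuple[FrontierEntry, ...]
    reference: str

    def entry(self, name: str) -> FrontierEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def frontier(self) -> list[FrontierEntry]:
        return [e for e in self.entries if e.status == "on_frontier"]


def efficiency_frontier(results: Sequence[StrategyResult]) -> FrontierReport:
    """Classify strategies as on-frontier, dominated, or extended-dominated."""
    if len(results) < 2:
        raise ValueError("at least 2 strategies are required")

    # stable order: cost ascending, then QALYs descending, then input order
    order = sorted(
        range(len(results)),
        key=lambda i: (results[i].expected_cost, -results[i].expected_qaly, i),
    )
    status: dict[int, str] = {}
    dominated_by: dict[int, str] = {}

    # strict dominance (ties resolved toward the earlier input entry)
    for pos, i in enumerate(order):
        ri = results[i]
        for j in order[:pos]:
            rj = results[j]
            if (
                rj.expected_cost <= ri.expected_cost + TIE_TOL
                and rj.expected_qaly >= ri.expected_qaly - TIE_TOL
            ):
                status[i] = "dominated"
                dominated_by[i] = rj.name
                break

    # extended dominance: iteratively drop entries whose ICER to the previous
    # surviving entry is >= the next entry's ICER
    surviving = [i for i in order if i not in status]
    changed = True
    while changed:
        changed = False
        for k in range(1, len(surviving) - 1):
            a, b, c = surviving[k - 1], surviving[k], surviving[k + 1]
            icer_ab = _ratio(results[a], results[b])
            icer_bc = _ratio(results[b], results[c])
            if icer_ab >= icer_bc - TIE_TOL:
                status[b] = "extended_dominated"
                dominated_by[b] = results[c].name
                surviving.pop(k)
                changed = True
                break

    icers: dict[int, float] = {}
    for prev, cur in zip(surviving, surviving[1:]):
        icers[cur] = _ratio(results[prev], results[cur])

    entries = tuple(
        FrontierEntry(
            name=results[i].name,
            expected_cost=results[i].expected_cost,
            expected_qaly=results[i].expected_qaly,
            status=status.get(i, "on_frontier"),
            icer_vs_previous=icers.get(i),
            dominated_by=dominated_by.get(i),
        )
        for i in order
    )
    return FrontierReport(entries=entries, reference=results[surviving[0]].name)


def _ratio(cheap: StrategyResult, costly: StrategyResult) -> float:
    dq = costly.expected_qaly - cheap.expected_qaly
    dc = costly.expected_cost - cheap.expected_cost
    if dq <= TIE_TOL:
        return float("inf")
    return dc / dq


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """NMB = wtp * expected QALYs - expected cost (USD)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * result.expected_qaly - result.expected_cost


def preferred_strategy(results: Sequence[StrategyResult], wtp: float) -> str:
    """Strategy with maximal net monetary benefit at the given threshold.

    Ties (within TIE_TOL) break toward lower cost, then higher QALYs, then
    input order.
    """
    if not results:
        raise ValueError("at least one strategy is required")
    nmbs = [net_monetary_benefit(r, wtp) for r in results]
    best = max(nmbs)
    cand = [i for i, v in enumerate(nmbs) if v >= best - TIE_TOL]
    cmin = min(results[i].expected_cost for i in cand)
    cand = [i for i in cand if results[i].expected_cost <= cmin + TIE_TOL]
    qmax = max(results[i].expected_qaly for i in cand)
    cand = [i for i in cand if results[i].expected_qaly >= qmax - TIE_TOL]
    return results[cand[0]].name
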