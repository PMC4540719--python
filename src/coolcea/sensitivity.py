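"""Deterministic sensitivity analyses: one-way sweeps, tornado, two-way maps.

Parameters are addressed by hierarchical ids (``"<strategy name>/<field>"``
or ``"shared/<field>"``); a bare field name works when unique.  The model is
affine in every cost and utility input, so one-way curves of cost/QALY
outputs are straight lines for those parameters; preferred-strategy curves
are piecewise constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_model import StrategyResult, evaluate_all
from .economics import FrontierReport, efficiency_frontier, net_monetary_benefit, preferred_strategy
from .parameters import ModelConfig

__all__ = [
    "OneWayCurve",
    "TornadoEntry",
    "PreferenceMap",
    "one_way",
    "tornado",
    "two_way",
    "utility_sweep",
]


@dataclass(frozen=True)
class OneWayCurve:
    """Model outputs re-evaluated along a grid of one parameter."""

    param_id: str
    wtp: float
    grid: np.ndarray
    results: tuple[tuple[StrategyResult, ...], ...]
    frontiers: tuple[FrontierReport, ...]
    preferred: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (grid value, strategy)."""
        rows = []
        for x, res, pref in zip(self.grid, self.results, self.preferred):
            for r in res:
                rows.append(
                    {
                        "param": self.param_id,
                        "value": float(x),
                        "strategy": r.name,
                        "cost": r.expected_cost,
                        "qaly": r.expected_qaly,
                        "preferred": r.name == pref,
                    }
                )
        return pd.DataFrame(rows)


def one_way(
    config: ModelConfig,
    param_id: str,
    n_points: int = 21,
    wtp: float | None = None,
    bounds: tuple[float, float] | None = None,
) -> OneWayCurve:
    """Sweep one parameter across its range, re-evaluating the full model.

    The grid is evenly spaced from the parameter's low to high (or explicit
    ``bounds``); every other parameter stays at base.
    """
    full_id = config.resolve(param_id)
    if n_points < 1 or (n_points < 2 and bounds is not None):
        raise ValueError("n_points must be >= 2 (or 1 for a degenerate grid)")
    p = config.get_param(full_id)
    lo, hi = bounds if bounds is not None else (p.low, p.high)
    if lo > hi:
        raise ValueError("lower bound exceeds upper bound")
    wtp = config.wtp_default if wtp is None else wtp
    grid = np.array([p.base]) if n_points == 1 else np.linspace(lo, hi, n_points)

    results, frontiers, preferred = [], [], []
    for x in grid:
        res = evaluate_all(config.with_value(full_id, float(x)))
        results.append(tuple(res))
        frontiers.append(efficiency_frontier(res))
        preferred.append(preferred_strategy(res, wtp))
    return OneWayCurve(
        param_id=full_id,
        wtp=wtp,
        grid=grid,
        results=tuple(results),
        frontiers=tuple(frontiers),
        preferred=tuple(preferred),
    )


@dataclass(frozen=True)
class TornadoEntry:
    """Swing of the maximal net monetary benefit over one parameter's range."""

    param_id: str
    nb_at_low: float
    nb_at_high: float
    reversal: bool  # preferred strategy differs between the two extremes

    @property
    def bar_width(self) -> float:
        return abs(self.nb_at_high - self.nb_at_low)


def tornado(config: ModelConfig, wtp: float | None = None) -> list[TornadoEntry]:
    """One bar per uncertain parameter, widest (most influential) first.

    The measure is the maximal NMB across strategies with the parameter at
    its low versus its high, all others at base.  Parameters with degenerate
    ranges are skipped.  Ties in width break by parameter id.
    """
    wtp = config.wtp_default if wtp is None else wtp
    entries = []
    for pid in config.param_ids():
        p = config.get_param(pid)
        if p.is_fixed:
            continue
        nbs, prefs = [], []
        for x in (p.low, p.high):
            res = evaluate_all(config.with_value(pid, x))
            nbs.append(max(net_monetary_benefit(r, wtp) for r in res))
            prefs.append(preferred_strategy(res, wtp))
        entries.append(
            TornadoEntry(
                param_id=pid,
                nb_at_low=nbs[0],
                nb_at_high=nbs[1],
                reversal=prefs[0] != prefs[1],
            )
        )
    entries.sort(key=lambda e: (-e.bar_width, e.param_id))
    return entries


@dataclass(frozen=True)
class PreferenceMap:
    """Preferred strategy over a grid of two simultaneously varied params."""

    param_x: str
    param_y: str
    wtp: float
    x_grid: np.ndarray
    y_grid: np.ndarray
    preferred: tuple[tuple[str, ...], ...]  # indexed [iy][ix]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "param_x": self.param_x,
                "x": float(x),
                "param_y": self.param_y,
                "y": float(y),
                "preferred": self.preferred[iy][ix],
            }
            for iy, y in enumerate(self.y_grid)
            for ix, x in enumerate(self.x_grid)
        ]
        return pd.DataFrame(rows)


def two_way(
    config: ModelConfig,
    param_x: str,
    param_y: str,
    n_x: int = 41,
    n_y: int = 41,
    wtp: float | None = None,
) -> PreferenceMap:
    """Preferred strategy at every point of a rectangular parameter grid."""
    fx, fy = config.resolve(param_x), config.resolve(param_y)
    if fx == fy:
        raise ValueError("the two parameters must be distinct")
    wtp = config.wtp_default if wtp is None else wtp
    px, py = config.get_param(fx), config.get_param(fy)
    xg = np.array([px.base]) if n_x == 1 else np.linspace(px.low, px.high, n_x)
    yg = np.array([py.base]) if n_y == 1 else np.linspace(py.low, py.high, n_y)
    cells = []
    for y in yg:
        cfg_y = config.with_value(fy, float(y))
        row = []
        for x in xg:
            res = evaluate_all(cfg_y.with_value(fx, float(x)))
            row.append(preferred_strategy(res, wtp))
        cells.append(tuple(row))
    return PreferenceMap(
        param_x=fx, param_y=fy, wtp=wtp, x_grid=xg, y_grid=yg,
        preferred=tuple(cells),
    )


def utility_sweep(
    config: ModelConfig,
    low: float = 0.2,
    high: float = 0.6,
    n: int = 21,
    wtp: float | None = None,
) -> OneWayCurve:
    """One-way sweep of the poor-outcome utility over an explicit range.

    Unlike :func:`one_way` on ``shared/u_poor``, the bounds may exceed the
    parameter's own printed range (utilities still must lie in [0, 1]).
    """
    if n == 1:
        return one_way(config, "shared/u_poor", n_points=1, wtp=wtp)
    if not (0.0 <= low < high <= 1.0):
        raise ValueError("require 0 <= low < high <= 1")
    return one_way(config, "shared/u_poor", n_points=n, wtp=wtp, bounds=(low, high))
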