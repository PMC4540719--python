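"""Probabilistic sensitivity analysis and acceptability curves.

Each uncertain parameter gets a parametric distribution by method of
moments: the mean is pinned to the base-case value and the concentration is
solved so the printed (low, high) range carries 95% central mass — beta for
probabilities and utilities, gamma for costs and durations.  The discount
rate (and any other rate-kind parameter) is held fixed; rates are varied
deterministically only.  Monte-Carlo draws are independent across
parameters and fully reproducible under a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .cohort_model import _bases, _evaluate_values
from .economics import TIE_TOL
from .parameters import ModelConfig, Param

__all__ = [
    "DistributionSpec",
    "PSAResult",
    "CEAC",
    "fit_distribution",
    "run_psa",
    "ceac",
    "acceptability_at",
    "default_wtp_grid",
]

log = logging.getLogger(__name__)

#: central interval mass the (low, high) range is assumed to carry
INTERVAL_MASS = 0.95
#: solver tolerance on the interval-mass equation
FIT_TOL = 1e-6


@dataclass(frozen=True)
class DistributionSpec:
    """Fitted sampling distribution for one parameter.

    family "beta": a, b are the usual shape parameters.
    family "gamma": a is the shape, b the scale (mean = a*b).
    family "logitnormal": a is mu, b sigma on the logit scale (fallback when
    the beta moment match is infeasible; median matched instead of mean).
    family "fixed": degenerate at the base value (a = base, b unused).
    """

    param_id: str
    family: str  # beta | gamma | logitnormal | fixed
    a: float
    b: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(size, self.a)
        if self.family == "beta":
            return rng.beta(self.a, self.b, size)
        if self.family == "gamma":
            return rng.gamma(self.a, self.b, size)
        if self.family == "logitnormal":
            return special.expit(rng.normal(self.a, self.b, size))
        raise ValueError(f"unknown family {self.family!r}")

    def mean(self) -> float:
        if self.family == "fixed":
            return self.a
        if self.family == "beta":
            return self.a / (self.a + self.b)
        if self.family == "gamma":
            return self.a * self.b
        # logit-normal has no closed-form mean; report the matched median
        return float(special.expit(self.a))


def _solve_concentration(mass, lo, hi):
    """Find log-concentration k with interval mass = INTERVAL_MASS.

    `mass(k)` must be increasing in k (true when lo < mean < hi strictly).
    """
    f = lambda logk: mass(np.exp(logk)) - INTERVAL_MASS
    a, b = -10.0, 40.0
    if f(a) > 0 or f(b) < 0:
        raise ValueError("interval mass target not bracketed")
    return float(np.exp(optimize.brentq(f, a, b, xtol=1e-12, rtol=8.9e-16)))


def fit_distribution(param: Param, param_id: str | None = None) -> DistributionSpec:
    """Method-of-moments fit treating (low, high) as a 95% central interval."""
    pid = param_id or param.id
    if param.is_fixed or param.kind == "rate":
        return DistributionSpec(pid, "fixed", param.base, 0.0)
    m, lo, hi = param.base, param.low, param.high
    if param.kind in ("probability", "utility"):
        try:
            if not lo < m < hi:
                raise ValueError("base on the interval boundary")
            k = _solve_concentration(
                lambda k: stats.beta.cdf(hi, m * k, (1 - m) * k)
                - stats.beta.cdf(lo, m * k, (1 - m) * k),
                lo,
                hi,
            )
            return DistributionSpec(pid, "beta", m * k, (1 - m) * k)
        except ValueError:
            # beta moment match infeasible: logit-normal with matched median
            mu = float(special.logit(m))
            z = stats.norm.ppf(0.5 + INTERVAL_MASS / 2)
            sigma = max(
                abs(special.logit(hi) - mu), abs(special.logit(lo) - mu)
            ) / z
            log.warning(
                "beta fit infeasible for %s; falling back to logit-normal", pid
            )
            return DistributionSpec(pid, "logitnormal", mu, float(sigma))
    # costs and durations: gamma with mean pinned at base
    if not lo < m < hi:
        raise ValueError(
            f"{pid}: gamma moment match needs low < base < high strictly"
        )
    k = _solve_concentration(
        lambda k: stats.gamma.cdf(hi, k, scale=m / k)
        - stats.gamma.cdf(lo, k, scale=m / k),
        lo,
        hi,
    )
    return DistributionSpec(pid, "gamma", k, m / k)


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo cost/QALY draws for every strategy.

    costs and qalys are (n_iterations, n_strategies) arrays aligned with
    `strategy_names` (config order).
    """

    n_iterations: int
    seed: int | None
    strategy_names: tuple[str, ...]
    costs: np.ndarray
    qalys: np.ndarray
    specs: dict[str, DistributionSpec]


def fit_all(config: ModelConfig) -> dict[str, DistributionSpec]:
    """Fitted distribution for every parameter, keyed by hierarchical id."""
    return {
        pid: fit_distribution(config.get_param(pid), pid)
        for pid in config.param_ids()
    }


def run_psa(
    config: ModelConfig,
    n_iterations: int = 10_000,
    seed: int | None = None,
    specs: dict[str, DistributionSpec] | None = None,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty.

    One seeded generator draws every non-fixed parameter independently, in
    the deterministic order of ``config.param_ids()``; all strategies are
    evaluated on each joint draw.  Identical (config, n, seed) gives a
    bit-identical result.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if specs is None:
        specs = fit_all(config)
    rng = np.random.default_rng(seed)
    draws = {
        pid: specs[pid].sample(rng, n_iterations) for pid in config.param_ids()
    }
    shv = {
        f: draws[f"shared/{f}"] for f, _ in config.shared.params()
    }
    costs = np.empty((n_iterations, len(config.strategies)))
    qalys = np.empty_like(costs)
    for j, s in enumerate(config.strategies):
        sv = {f: draws[f"{s.name}/{f}"] for f, _ in s.params()}
        c, q = _evaluate_values(s.name, sv, shv)
        costs[:, j] = c
        qalys[:, j] = q
    return PSAResult(
        n_iterations=n_iterations,
        seed=seed,
        strategy_names=tuple(s.name for s in config.strategies),
        costs=costs,
        qalys=qalys,
        specs=specs,
    )


@dataclass(frozen=True)
class CEAC:
    """Cost-effectiveness acceptability curves over a WTP grid.

    probabilities is (len(wtp_grid), n_strategies); each row sums to 1.
    """

    wtp_grid: np.ndarray
    strategy_names: tuple[str, ...]
    probabilities: np.ndarray

    def at(self, wtp: float) -> dict[str, float]:
        i = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        if abs(self.wtp_grid[i] - wtp) > 1e-9:
            raise KeyError(f"wtp {wtp} not on the grid")
        return dict(zip(self.strategy_names, self.probabilities[i]))

    def to_frame(self):
        import pandas as pd

        rows = [
            {"wtp": float(w), "strategy": s, "probability": float(p)}
            for w, row in zip(self.wtp_grid, self.probabilities)
            for s, p in zip(self.strategy_names, row)
        ]
        return pd.DataFrame(rows)


def default_wtp_grid() -> np.ndarray:
    """$0 to $200,000 per QALY in $5,000 steps."""
    return np.arange(0.0, 200_001.0, 5_000.0)


def _winners(costs: np.ndarray, qalys: np.ndarray, wtp: float) -> np.ndarray:
    """Per-iteration index of the maximal-NMB strategy (ties: lowest cost,
    then highest QALYs, then config order — same rule as preferred_strategy)."""
    nmb = wtp * qalys - costs
    best = nmb.max(axis=1, keepdims=True)
    cand = nmb >= best - TIE_TOL
    c = np.where(cand, costs, np.inf)
    cand &= c <= c.min(axis=1, keepdims=True) + TIE_TOL
    q = np.where(cand, qalys, -np.inf)
    cand &= q >= q.max(axis=1, keepdims=True) - TIE_TOL
    return cand.argmax(axis=1)  # first True


def ceac(psa: PSAResult, wtp_grid=None) -> CEAC:
    """Fraction of iterations each strategy attains the maximal NMB."""
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    if grid.size == 0:
        raise ValueError("wtp grid must be non-empty")
    if np.any(grid < 0):
        raise ValueError("willingness-to-pay values must be non-negative")
    n_s = len(psa.strategy_names)
    probs = np.empty((grid.size, n_s))
    for i, w in enumerate(grid):
        idx = _winners(psa.costs, psa.qalys, float(w))
        probs[i] = np.bincount(idx, minlength=n_s) / psa.n_iterations
    return CEAC(wtp_grid=grid, strategy_names=psa.strategy_names, probabilities=probs)


def acceptability_at(psa: PSAResult, wtp: float) -> dict[str, float]:
    """Single-point acceptability: probability each strategy is preferred."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    curve = ceac(psa, np.array([wtp]))
    return dict(zip(curve.strategy_names, curve.probabilities[0]))
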