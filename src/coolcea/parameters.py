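"""Model parameter space: uncertain scalars, strategy/shared blocks, config I/O.

The model compares therapeutic-hypothermia strategies after out-of-hospital
cardiac arrest (cooling blankets, iced-saline peritoneal lavage, V-V ECMO)
against conventional supportive care.  Every uncertain input is a
:class:`Param` carrying a base-case value and a (low, high) range; the
built-in base case packages the literature-derived values used throughout
the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "Param",
    "StrategyParams",
    "SharedParams",
    "ModelConfig",
    "ConfigError",
    "AmbiguousParamError",
    "base_case_config",
    "load_config",
    "save_config",
    "validate",
    "F_VENT_DEFAULT",
]

KINDS = {
    "probability",
    "cost_usd",
    "utility",
    "duration_days",
    "duration_years",
    "rate",
}

#: Fraction of a poor-outcome survivor's institutional days costed at the
#: chronic-ventilator daily rate (the remainder at the long-term-care rate).
#: Calibrated once so the conventional-care arm's expected lifetime cost
#: equals the published $118,340 total; see cohort_model.calibrate_f_vent.
F_VENT_DEFAULT = 0.6194618151648111


class ConfigError(ValueError):
    """A config file violates the schema or a model invariant."""


class AmbiguousParamError(KeyError):
    """A bare parameter id matched more than one scope."""


@dataclass(frozen=True)
class Param:
    """One uncertain scalar input: base-case value plus a (low, high) range."""

    id: str
    base: float
    low: float
    high: float
    kind: str

    @classmethod
    def fixed(cls, id: str, value: float, kind: str) -> "Param":
        """A degenerate parameter with no uncertainty (low = base = high)."""
        return cls(id, value, value, value, kind)

    @property
    def is_fixed(self) -> bool:
        return self.high == self.low

    def violations(self, prefix: str = "") -> list[str]:
        path = f"{prefix}{self.id}"
        out = []
        if self.kind not in KINDS:
            out.append(f"{path}: unknown kind {self.kind!r}")
            return out
        if not self.low <= self.base <= self.high:
            out.append(
                f"{path}: range rule low <= base <= high violated "
                f"({self.low} / {self.base} / {self.high})"
            )
        if self.kind in ("probability", "utility", "rate"):
            if self.low < 0 or self.high > 1:
                out.append(f"{path}: {self.kind} values must lie in [0, 1]")
        else:
            if self.low < 0:
                out.append(f"{path}: {self.kind} values must be non-negative")
        return out


# field name -> kind, for each block
STRATEGY_FIELD_KINDS = {
    "p_death": "probability",
    "p_good_given_survival": "probability",
    "cooling_cost": "cost_usd",
    "sedation_cost": "cost_usd",
    "icu_days_survivor": "duration_days",
    "icu_days_nonsurvivor": "duration_days",
    "floor_days": "duration_days",
}

SHARED_FIELD_KINDS = {
    "c_icu_day": "cost_usd",
    "c_floor_day": "cost_usd",
    "icd_cost": "cost_usd",
    "rehab_daily": "cost_usd",
    "rehab_days": "duration_days",
    "transport_annual_good": "cost_usd",
    "caregiver_clinic_annual": "cost_usd",
    "outpatient_annual_good": "cost_usd",
    "outpatient_annual_poor": "cost_usd",
    "vent_daily": "cost_usd",
    "ltc_daily": "cost_usd",
    "opportunity_cost_annual_poor": "cost_usd",
    "transport_annual_poor": "cost_usd",
    "f_vent": "rate",
    "le_good": "duration_years",
    "le_poor": "duration_years",
    "u_good": "utility",
    "u_poor": "utility",
    "discount_rate": "rate",
}


@dataclass(frozen=True)
class StrategyParams:
    """Per-strategy inputs: survival/outcome probabilities and episode costs."""

    name: str
    p_death: Param
    p_good_given_survival: Param
    cooling_cost: Param
    sedation_cost: Param
    icu_days_survivor: Param
    icu_days_nonsurvivor: Param
    floor_days: Param

    def params(self) -> Iterator[tuple[str, Param]]:
        for f in STRATEGY_FIELD_KINDS:
            yield f, getattr(self, f)

    def violations(self) -> list[str]:
        out = []
        for f, p in self.params():
            out.extend(p.violations(prefix=f"{self.name}/"))
        if self.icu_days_nonsurvivor.base > self.icu_days_survivor.base:
            out.append(
                f"{self.name}/icu_days_nonsurvivor: base exceeds "
                "icu_days_survivor base"
            )
        return out


@dataclass(frozen=True)
class SharedParams:
    """Inputs common to all strategies: daily costs, post-hospital cost
    streams, life expectancies, utilities, and the discount rate."""

    c_icu_day: Param
    c_floor_day: Param
    icd_cost: Param
    rehab_daily: Param
    rehab_days: Param
    transport_annual_good: Param
    caregiver_clinic_annual: Param
    outpatient_annual_good: Param
    outpatient_annual_poor: Param
    vent_daily: Param
    ltc_daily: Param
    opportunity_cost_annual_poor: Param
    transport_annual_poor: Param
    f_vent: Param
    le_good: Param
    le_poor: Param
    u_good: Param
    u_poor: Param
    discount_rate: Param

    def params(self) -> Iterator[tuple[str, Param]]:
        for f in SHARED_FIELD_KINDS:
            yield f, getattr(self, f)

    def violations(self) -> list[str]:
        out = []
        for f, p in self.params():
            out.extend(p.violations(prefix="shared/"))
        if self.u_good.base <= self.u_poor.base:
            out.append("shared/u_good: base must exceed u_poor base")
        if self.le_good.base <= self.le_poor.base:
            out.append("shared/le_good: base must exceed le_poor base")
        return out


@dataclass(frozen=True)
class ModelConfig:
    """The full model parameterization: an ordered set of strategies plus the
    shared block and a default willingness-to-pay threshold ($/QALY)."""

    strategies: tuple[StrategyParams, ...]
    shared: SharedParams
    wtp_default: float = 100_000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategies", tuple(self.strategies))

    # -- parameter addressing -------------------------------------------------
    # hierarchical ids: "<strategy name>/<field>" or "shared/<field>"; a bare
    # field name resolves iff it is unique across scopes.

    def strategy(self, name: str) -> StrategyParams:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"unknown strategy {name!r}")

    def param_ids(self) -> list[str]:
        ids = [f"{s.name}/{f}" for s in self.strategies for f in STRATEGY_FIELD_KINDS]
        ids += [f"shared/{f}" for f in SHARED_FIELD_KINDS]
        return ids

    def resolve(self, param_id: str) -> str:
        """Return the full ``scope/field`` id for ``param_id``."""
        if "/" in param_id:
            scope, fld = param_id.split("/", 1)
            if scope == "shared":
                if fld not in SHARED_FIELD_KINDS:
                    raise KeyError(f"unknown shared parameter {fld!r}")
            else:
                self.strategy(scope)
                if fld not in STRATEGY_FIELD_KINDS:
                    raise KeyError(f"unknown strategy parameter {fld!r}")
            return f"{scope}/{fld}"
        matches = [i for i in self.param_ids() if i.split("/", 1)[1] == param_id]
        if not matches:
            raise KeyError(f"unknown parameter {param_id!r}")
        if len(matches) > 1:
            raise AmbiguousParamError(
                f"parameter id {param_id!r} is ambiguous: {', '.join(matches)}"
            )
        return matches[0]

    def get_param(self, param_id: str) -> Param:
        scope, fld = self.resolve(param_id).split("/", 1)
        block = self.shared if scope == "shared" else self.strategy(scope)
        return getattr(block, fld)

    def with_param(self, param_id: str, param: Param) -> "ModelConfig":
        scope, fld = self.resolve(param_id).split("/", 1)
        if scope == "shared":
            return replace(self, shared=replace(self.shared, **{fld: param}))
        strategies = tuple(
            replace(s, **{fld: param}) if s.name == scope else s
            for s in self.strategies
        )
        return replace(self, strategies=strategies)

    def with_value(self, param_id: str, value: float) -> "ModelConfig":
        """Override a parameter's base value (range left untouched except to
        contain the new base, which keeps Param invariants satisfied)."""
        p = self.get_param(param_id)
        new = replace(
            p, base=value, low=min(p.low, value), high=max(p.high, value)
        )
        return self.with_param(param_id, new)

    def violations(self) -> list[str]:
        out = []
        if len(self.strategies) < 2:
            out.append("strategies: at least 2 strategies required")
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            out.append("strategies: names must be unique")
        for s in self.strategies:
            out.extend(s.violations())
        out.extend(self.shared.violations())
        if self.wtp_default < 0:
            out.append("wtp_default: must be non-negative")
        return out


def validate(config: ModelConfig) -> list[str]:
    """Return all invariant violations (empty list means the config is valid).

    Each entry names the offending field and the rule it breaks.
    """
    return config.violations()


# ---------------------------------------------------------------------------
# built-in base case
# ---------------------------------------------------------------------------

def _p(id: str, kind: str, base: float, low: float, high: float) -> Param:
    return Param(id, base, low, high, kind)


def base_case_config() -> ModelConfig:
    """The packaged base case for post-arrest cooling after ROSC.

    Survival and neurologic-outcome probabilities, cooling and hospital
    costs, post-hospital cost streams, life expectancies, utilities and the
    3% discount rate are the literature-derived values of the source
    cost-effectiveness analysis.  Conventional care has cooling and sedation
    costs fixed at zero and 3 survivor ICU days (cooled strategies: 5, the
    extra 2 covering the 48 h cooling/rewarming period).
    """

    def strategy(name, p_death, p_good, cool, icu_surv):
        cooled = cool is not None
        return StrategyParams(
            name=name,
            p_death=_p("p_death", "probability", *p_death),
            p_good_given_survival=_p("p_good_given_survival", "probability", *p_good),
            cooling_cost=(
                _p("cooling_cost", "cost_usd", *cool)
                if cooled
                else Param.fixed("cooling_cost", 0.0, "cost_usd")
            ),
            sedation_cost=(
                _p("sedation_cost", "cost_usd", 1197, 854, 1708)
                if cooled
                else Param.fixed("sedation_cost", 0.0, "cost_usd")
            ),
            icu_days_survivor=_p("icu_days_survivor", "duration_days", *icu_surv),
            icu_days_nonsurvivor=_p("icu_days_nonsurvivor", "duration_days", 1, 0.5, 3),
            floor_days=_p("floor_days", "duration_days", 18, 10, 36),
        )

    strategies = (
        strategy("Conventional Care", (0.54, 0.47, 0.61), (0.69, 0.60, 0.77),
                 None, (3, 1, 5)),
        strategy("Cooling Blankets", (0.50, 0.45, 0.54), (0.86, 0.80, 0.90),
                 (6729, 4526, 8951), (5, 2, 7)),
        strategy("Peritoneal Lavage", (0.31, 0.13, 0.56), (0.86, 0.80, 0.90),
                 (9284, 8234, 9784), (5, 2, 7)),
        strategy("V-V ECMO", (0.50, 0.20, 0.80), (0.75, 0.28, 0.97),
                 (39038, 19519, 58557), (5, 2, 7)),
    )
    shared = SharedParams(
        c_icu_day=_p("c_icu_day", "cost_usd", 4973, 3730, 6216),
        c_floor_day=_p("c_floor_day", "cost_usd", 2365, 1774, 2956),
        icd_cost=_p("icd_cost", "cost_usd", 35868, 26901, 44835),
        rehab_daily=_p("rehab_daily", "cost_usd", 1443, 1082, 1804),
        rehab_days=_p("rehab_days", "duration_days", 30, 10, 90),
        transport_annual_good=_p("transport_annual_good", "cost_usd", 22, 17, 28),
        caregiver_clinic_annual=_p("caregiver_clinic_annual", "cost_usd", 175, 131, 219),
        outpatient_annual_good=_p("outpatient_annual_good", "cost_usd", 1305, 1180, 1430),
        outpatient_annual_poor=_p("outpatient_annual_poor", "cost_usd", 2345, 2140, 2550),
        vent_daily=_p("vent_daily", "cost_usd", 1582, 1187, 1978),
        ltc_daily=_p("ltc_daily", "cost_usd", 257, 193, 321),
        opportunity_cost_annual_poor=_p(
            "opportunity_cost_annual_poor", "cost_usd", 36410, 27308, 45513
        ),
        transport_annual_poor=_p("transport_annual_poor", "cost_usd", 44, 33, 55),
        f_vent=Param.fixed("f_vent", F_VENT_DEFAULT, "rate"),
        le_good=_p("le_good", "duration_years", 5.5, 4, 10),
        le_poor=_p("le_poor", "duration_years", 1.0, 0.25, 3.0),
        u_good=_p("u_good", "utility", 0.76, 0.55, 0.97),
        u_poor=_p("u_poor", "utility", 0.35, 0.20, 0.50),
        discount_rate=_p("discount_rate", "rate", 0.03, 0.0, 0.05),
    )
    return ModelConfig(strategies=strategies, shared=shared, wtp_default=100_000.0)


def base_case_path() -> Path:
    """Path of the packaged base-case config file (diff/edit friendly)."""
    return Path(str(resources.files("coolcea").joinpath("data/base_case.yaml")))


# ---------------------------------------------------------------------------
# config file I/O (YAML; all Params as {base, low, high})
# ---------------------------------------------------------------------------

def _param_to_dict(p: Param) -> dict:
    return {"base": p.base, "low": p.low, "high": p.high}


def _block_to_dict(block) -> dict:
    out = {}
    if isinstance(block, StrategyParams):
        out["name"] = block.name
    for f, p in block.params():
        out[f] = _param_to_dict(p)
    return out


def config_to_dict(config: ModelConfig) -> dict:
    return {
        "strategies": [_block_to_dict(s) for s in config.strategies],
        "shared": _block_to_dict(config.shared),
        "wtp_default": config.wtp_default,
    }


def save_config(config: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def _parse_param(raw, fld: str, kind: str, where: str) -> Param:
    if not isinstance(raw, dict):
        raise ConfigError(f"{where}/{fld}: expected a mapping {{base, low, high}}")
    unknown = set(raw) - {"base", "low", "high"}
    if unknown:
        raise ConfigError(f"{where}/{fld}: unknown keys {sorted(unknown)}")
    missing = {"base", "low", "high"} - set(raw)
    if missing:
        raise ConfigError(f"{where}/{fld}: missing keys {sorted(missing)}")
    try:
        vals = {k: float(raw[k]) for k in ("base", "low", "high")}
    except (TypeError, ValueError):
        raise ConfigError(f"{where}/{fld}: values must be numeric") from None
    return Param(fld, vals["base"], vals["low"], vals["high"], kind)


def _parse_block(raw: dict, cls, kinds: dict, where: str):
    if not isinstance(raw, dict):
        raise ConfigError(f"{where}: expected a mapping")
    allowed = set(kinds) | ({"name"} if cls is StrategyParams else set())
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    kwargs = {}
    if cls is StrategyParams:
        if "name" not in raw or not isinstance(raw["name"], str):
            raise ConfigError(f"{where}/name: required string field")
        kwargs["name"] = raw["name"]
        where = raw["name"]
    for fld, kind in kinds.items():
        if fld not in raw:
            raise ConfigError(f"{where}/{fld}: required field missing")
        kwargs[fld] = _parse_param(raw[fld], fld, kind, where)
    return cls(**kwargs)


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a model config from a YAML file.

    Raises :class:`ConfigError` naming the offending field on any schema or
    invariant violation, ``FileNotFoundError`` if the file is absent.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - {"strategies", "shared", "wtp_default"}
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    for key in ("strategies", "shared"):
        if key not in raw:
            raise ConfigError(f"{key}: required section missing")
    if not isinstance(raw["strategies"], list):
        raise ConfigError("strategies: expected a list")
    strategies = tuple(
        _parse_block(s, StrategyParams, STRATEGY_FIELD_KINDS, f"strategies[{i}]")
        for i, s in enumerate(raw["strategies"])
    )
    shared = _parse_block(raw["shared"], SharedParams, SHARED_FIELD_KINDS, "shared")
    wtp = float(raw.get("wtp_default", 100_000.0))
    config = ModelConfig(strategies=strategies, shared=shared, wtp_default=wtp)
    problems = validate(config)
    if problems:
        raise ConfigError("; ".join(problems))
    return config
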