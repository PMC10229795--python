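"""Model inputs: settings, cost items, utilities and per-population bundles.

Every input of the decision model lives here as a typed, validated object
with JSON round-tripping, and the published CHOICE-01 analysis inputs ship as
editable JSON fixtures under ``pscea/data/``.

Costs are stored in US dollars (the source tables are already converted at
$1 = RMB 7.2363); :func:`convert_currency` is provided for users entering
RMB prices.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path

from .weibull import WeibullParams

ARMS = ("toripalimab", "placebo")
POPULATIONS = ("ITT", "squamous", "non_squamous")
STATES = ("PFS", "PD")
DISTRIBUTIONS = ("gamma", "beta", "fixed")
APPLICATIONS = ("per_cycle", "one_off")

_FIXTURE_FILES = {
    "ITT": "choice01_itt.json",
    "squamous": "choice01_squamous.json",
    "non_squamous": "choice01_non_squamous.json",
}


class ValidationError(ValueError):
    """A parameter failed a structural or range check; names the field."""


class RangeError(ValidationError):
    """A numeric parameter is outside its admissible range."""


class EnumerationError(ValidationError):
    """A label is not one of the admissible values."""


def _check_enum(value: str, allowed: tuple, fieldname: str) -> None:
    if value not in allowed:
        raise EnumerationError(f"{fieldname}={value!r} not in {allowed}")


# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class ModelSettings:
    """Global model settings.

    Defaults are the published analysis conditions: 3-week cycles over a
    10-year horizon with half-cycle correction, 3 %/year discounting, a
    willingness-to-pay of $37,653/QALY (3x China's 2021 GDP per capita),
    1,000 PSA iterations and +/-30 % one-way ranges.
    """

    cycle_days: float = 21.0
    horizon_years: float = 10.0
    discount_annual: float = 0.03
    half_cycle_correction: bool = True
    wtp_per_qaly: float = 37653.0
    rmb_per_usd: float = 7.2363
    psa_iterations: int = 1000
    dsa_range_fraction: float = 0.30
    pd_cost_uptake: float = 1.0
    sd_rule: str = "range95"  # sd = range/3.92; alternative "range4" = range/4

    def __post_init__(self) -> None:
        if self.cycle_days <= 0:
            raise RangeError(f"cycle_days must be > 0, got {self.cycle_days}")
        if not 0 <= self.discount_annual < 1:
            raise RangeError(f"discount_annual must be in [0, 1), got {self.discount_annual}")
        if self.horizon_years <= 0:
            raise RangeError(f"horizon_years must be > 0, got {self.horizon_years}")
        if self.wtp_per_qaly <= 0:
            raise RangeError(f"wtp_per_qaly must be > 0, got {self.wtp_per_qaly}")
        if self.rmb_per_usd <= 0:
            raise RangeError(f"rmb_per_usd must be > 0, got {self.rmb_per_usd}")
        if self.psa_iterations < 1:
            raise RangeError(f"psa_iterations must be >= 1, got {self.psa_iterations}")
        if self.pd_cost_uptake < 0:
            raise RangeError(f"pd_cost_uptake must be >= 0, got {self.pd_cost_uptake}")
        _check_enum(self.sd_rule, ("range95", "range4"), "sd_rule")

    @property
    def n_cycles(self) -> int:
        """Number of model cycles: ceil(horizon in days / cycle_days) (174 at defaults)."""
        return int(math.ceil(self.horizon_years * 365.25 / self.cycle_days))

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25


@dataclass(frozen=True)
class CostItem:
    """One cost parameter and its application rule.

    ``base_value`` is USD per application; ``interval_days`` is the charging
    interval for recurring (``per_cycle``) items — an item with value v and
    interval d accrues at rate v/d per day of (half-cycle-corrected) state
    occupancy.  The packaged fixture uses interval_days = 30.4375 (monthly
    accrual, the rule back-calculated from the published cost table); set it
    to 21 to charge once per 3-week model cycle instead.  ``group`` ties items
    that represent a single priced parameter (e.g. hospitalization applied in
    both states) to one sensitivity-analysis bar and one PSA draw.
    """

    name: str
    base_value: float
    low: float
    high: float
    distribution: str = "gamma"
    application: str = "per_cycle"
    state: str = "PFS"
    arm: str = "both"
    start_cycle: int = 0
    stop_cycle: int | None = None
    interval_days: float | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.base_value < 0:
            raise RangeError(f"cost {self.name!r}: base_value must be >= 0, got {self.base_value}")
        if not self.low <= self.base_value <= self.high:
            raise RangeError(
                f"cost {self.name!r}: require low <= base <= high, got "
                f"({self.low}, {self.base_value}, {self.high})"
            )
        if self.low < 0:
            raise RangeError(f"cost {self.name!r}: low must be >= 0, got {self.low}")
        _check_enum(self.distribution, DISTRIBUTIONS, f"cost {self.name!r}: distribution")
        _check_enum(self.application, APPLICATIONS, f"cost {self.name!r}: application")
        _check_enum(self.state, STATES, f"cost {self.name!r}: state")
        _check_enum(self.arm, ARMS + ("both",), f"cost {self.name!r}: arm")
        if self.start_cycle < 0:
            raise RangeError(f"cost {self.name!r}: start_cycle must be >= 0")
        if self.stop_cycle is not None and self.start_cycle > self.stop_cycle:
            raise RangeError(f"cost {self.name!r}: start_cycle > stop_cycle")
        if self.interval_days is not None and self.interval_days <= 0:
            raise RangeError(f"cost {self.name!r}: interval_days must be > 0")

    @property
    def psa_group(self) -> str:
        return self.group if self.group is not None else self.name

    def applies_to(self, arm: str) -> bool:
        return self.arm in (arm, "both")


@dataclass(frozen=True)
class UtilityParam:
    """A health-state utility with its sampling range and distribution."""

    value: float
    low: float
    high: float
    distribution: str = "beta"

    def __post_init__(self) -> None:
        if not 0 <= self.value <= 1:
            raise RangeError(f"utility value must be in [0, 1], got {self.value}")
        if not self.low <= self.value <= self.high:
            raise RangeError(
                f"utility: require low <= value <= high, got "
                f"({self.low}, {self.value}, {self.high})"
            )
        _check_enum(self.distribution, DISTRIBUTIONS, "utility distribution")


@dataclass(frozen=True)
class UtilitySet:
    """Per-state utilities (per year of occupancy); death is fixed at 0."""

    pfs: UtilityParam
    pd: UtilityParam
    death: float = 0.0

    def __post_init__(self) -> None:
        if self.death != 0.0:
            raise ValidationError(f"u_death must be 0, got {self.death}")
        if self.pd.value > self.pfs.value:
            raise ValidationError(
                f"require u_pd <= u_pfs, got u_pd={self.pd.value} > u_pfs={self.pfs.value}"
            )


@dataclass(frozen=True)
class ArmSurvival:
    """The OS and PFS Weibull models for one arm."""

    os: WeibullParams
    pfs: WeibullParams


@dataclass(frozen=True)
class PopulationSpec:
    """Everything needed to run both arms for one patient population."""

    population: str
    survival: dict  # arm -> ArmSurvival
    costs: tuple
    utilities: UtilitySet

    def __post_init__(self) -> None:
        _check_enum(self.population, POPULATIONS, "population")
        for arm in ARMS:
            if arm not in self.survival:
                raise ValidationError(f"missing survival models for arm {arm!r}")
        object.__setattr__(self, "costs", tuple(self.costs))

    def costs_for(self, arm: str) -> tuple:
        _check_enum(arm, ARMS, "arm")
        return tuple(c for c in self.costs if c.applies_to(arm))

    def with_survival_from(self, other: "PopulationSpec") -> "PopulationSpec":
        """Copy of this spec using ``other``'s survival models."""
        return replace(self, survival=dict(other.survival))


# --------------------------------------------------------------------------- #
def convert_currency(amount_rmb: float, rmb_per_usd: float = 7.2363) -> float:
    """Convert an RMB amount to USD at the analysis exchange rate."""
    if amount_rmb < 0:
        raise RangeError(f"amount must be >= 0, got {amount_rmb}")
    return amount_rmb / rmb_per_usd


# ------------------------- JSON (de)serialisation -------------------------- #
_SETTINGS_KEYS = set(ModelSettings.__dataclass_fields__)
_COST_KEYS = set(CostItem.__dataclass_fields__)
_UTILITY_KEYS = set(UtilityParam.__dataclass_fields__)


def _reject_unknown(mapping: dict, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValidationError(f"unknown key(s) {sorted(unknown)} in {context}")


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ValidationError(f"missing field {key!r} in {context}")
    return mapping[key]


def _survival_from_dict(d: dict, context: str) -> WeibullParams:
    _reject_unknown(d, {"intercept", "log_scale", "shape", "rate", "time_unit"}, context)
    unit = d.get("time_unit", "months")
    if "intercept" in d and "log_scale" in d:
        return WeibullParams.from_aft(d["intercept"], d["log_scale"], time_unit=unit)
    if "shape" in d and "rate" in d:
        return WeibullParams.from_shape_rate(d["shape"], d["rate"], time_unit=unit)
    raise ValidationError(
        f"{context}: need either (intercept, log_scale) or (shape, rate)"
    )


def _survival_to_dict(p: WeibullParams) -> dict:
    if p.intercept is not None and p.log_scale is not None:
        return {"intercept": p.intercept, "log_scale": p.log_scale, "time_unit": p.time_unit}
    return {"shape": p.shape, "rate": p.rate, "time_unit": p.time_unit}


def spec_from_dict(doc: dict, context: str = "config") -> tuple:
    """Parse a config document into ``(PopulationSpec, ModelSettings)``."""
    _reject_unknown(doc, {"population", "settings", "survival", "costs", "utilities"}, context)
    population = _require(doc, "population", context)

    settings_doc = dict(doc.get("settings", {}))
    _reject_unknown(settings_doc, _SETTINGS_KEYS, f"{context}.settings")
    settings = ModelSettings(**settings_doc)

    surv_doc = _require(doc, "survival", context)
    survival = {}
    for arm in ARMS:
        arm_doc = _require(surv_doc, arm, f"{context}.survival")
        _reject_unknown(arm_doc, {"os", "pfs"}, f"{context}.survival.{arm}")
        survival[arm] = ArmSurvival(
            os=_survival_from_dict(_require(arm_doc, "os", f"{context}.survival.{arm}"),
                                   f"{context}.survival.{arm}.os"),
            pfs=_survival_from_dict(_require(arm_doc, "pfs", f"{context}.survival.{arm}"),
                                    f"{context}.survival.{arm}.pfs"),
        )

    cost_docs = _require(doc, "costs", context)
    costs = []
    for i, cdoc in enumerate(cost_docs):
        _reject_unknown(cdoc, _COST_KEYS, f"{context}.costs[{i}]")
        if "name" not in cdoc or "base_value" not in cdoc:
            raise ValidationError(f"missing field 'name'/'base_value' in {context}.costs[{i}]")
        costs.append(CostItem(**cdoc))

    util_doc = _require(doc, "utilities", context)
    _reject_unknown(util_doc, {"pfs", "pd", "death"}, f"{context}.utilities")
    utils = {}
    for state in ("pfs", "pd"):
        u = _require(util_doc, state, f"{context}.utilities")
        _reject_unknown(u, _UTILITY_KEYS, f"{context}.utilities.{state}")
        utils[state] = UtilityParam(**u)
    utilities = UtilitySet(pfs=utils["pfs"], pd=utils["pd"], death=util_doc.get("death", 0.0))

    spec = PopulationSpec(
        population=population, survival=survival, costs=tuple(costs), utilities=utilities
    )
    return spec, settings


def spec_to_dict(spec: PopulationSpec, settings: ModelSettings) -> dict:
    return {
        "population": spec.population,
        "settings": asdict(settings),
        "survival": {
            arm: {"os": _survival_to_dict(s.os), "pfs": _survival_to_dict(s.pfs)}
            for arm, s in spec.survival.items()
        },
        "costs": [asdict(c) for c in spec.costs],
        "utilities": {
            "pfs": asdict(spec.utilities.pfs),
            "pd": asdict(spec.utilities.pd),
            "death": spec.utilities.death,
        },
    }


def load_parameters(path) -> tuple:
    """Load and validate a JSON config; returns ``(PopulationSpec, ModelSettings)``."""
    path = Path(path)
    with path.open() as fh:
        doc = json.load(fh)
    return spec_from_dict(doc, context=str(path))


def save_parameters(spec: PopulationSpec, settings: ModelSettings, path) -> None:
    """Write a config that :func:`load_parameters` round-trips exactly."""
    path = Path(path)
    with path.open("w") as fh:
        json.dump(spec_to_dict(spec, settings), fh, indent=2)
        fh.write("\n")


# ------------------------------ fixtures ----------------------------------- #
def builtin_choice01(population: str) -> tuple:
    """The packaged CHOICE-01 inputs for one population.

    Returns ``(PopulationSpec, ModelSettings)`` with that population's own
    published OS/PFS Weibull models (all twelve models across the three
    fixtures) and the published cost/utility table.
    """
    if population not in _FIXTURE_FILES:
        raise EnumerationError(
            f"unknown population {population!r}; expected one of {POPULATIONS}"
        )
    ref = resources.files("pscea.data") / _FIXTURE_FILES[population]
    doc = json.loads(ref.read_text())
    return spec_from_dict(doc, context=f"builtin:{population}")


def published_analysis(population: str) -> tuple:
    """The configuration that reproduces the published base case.

    The published squamous and non-squamous results were generated with the
    ITT survival models (only the chemotherapy price differs between the
    published populations); this helper returns the population's cost table
    combined with the ITT OS/PFS curves.  For the ITT population it is
    identical to :func:`builtin_choice01`.
    """
    spec, settings = builtin_choice01(population)
    if population != "ITT":
        itt_spec, _ = builtin_choice01("ITT")
        spec = spec.with_survival_from(itt_spec)
    return spec, settings


def parameter_table(spec: PopulationSpec):
    """Cost/utility parameters as a DataFrame (CSV-exportable)."""
    import pandas as pd

    rows = [
        {
            "parameter": c.name,
            "kind": "cost",
            "value": c.base_value,
            "low": c.low,
            "high": c.high,
            "distribution": c.distribution,
            "application": c.application,
            "state": c.state,
            "arm": c.arm,
        }
        for c in spec.costs
    ]
    for label, u in (("u_pfs", spec.utilities.pfs), ("u_pd", spec.utilities.pd)):
        rows.append(
            {
                "parameter": label,
                "kind": "utility",
                "value": u.value,
                "low": u.low,
                "high": u.high,
                "distribution": u.distribution,
                "application": "per_year",
                "state": label[2:].upper(),
                "arm": "both",
            }
        )
    return pd.DataFrame(rows)
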