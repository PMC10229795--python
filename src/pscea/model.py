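"""Incremental cost-effectiveness statistics and the main modelling objects.

`CostEffectivenessModel` is the package's central object, in the mould of a
statsmodels model: it is constructed from a :class:`~pscea.params.PopulationSpec`
plus :class:`~pscea.params.ModelSettings`, its :meth:`fit` evaluates both arms
through the cohort engine and returns a :class:`CEAResults` carrying totals,
incrementals, the ICER and the decision at the willingness-to-pay threshold,
and one-way / probabilistic sensitivity analyses hang off the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import ArmResult, run_arm
from .params import ModelSettings, PopulationSpec

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"

INTERVENTION = "toripalimab"
COMPARATOR = "placebo"


def icer(delta_cost: float, delta_qaly: float):
    """Incremental cost-effectiveness ratio, or a dominance label.

    Returns ``delta_cost / delta_qaly`` on the ordinary quadrants,
    ``"dominant"`` when the intervention is cheaper and more effective,
    ``"dominated"`` when costlier and less effective, and ``"undefined"``
    when ``delta_qaly`` is zero (no ratio exists).
    """
    if delta_qaly > 0:
        return DOMINANT if delta_cost <= 0 else delta_cost / delta_qaly
    if delta_qaly < 0:
        return DOMINATED if delta_cost >= 0 else delta_cost / delta_qaly
    return UNDEFINED


def net_monetary_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """NMB = wtp * dQALY - dCost; positive iff cost-effective at ``wtp``."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    return wtp * delta_qaly - delta_cost


@dataclass(frozen=True)
class CEAResults:
    """Paired-arm results of one base-case evaluation."""

    population: str
    intervention: ArmResult
    comparator: ArmResult
    settings: ModelSettings = field(repr=False)

    @property
    def delta_cost(self) -> float:
        return self.intervention.cost_total - self.comparator.cost_total

    @property
    def delta_qaly(self) -> float:
        return self.intervention.qaly_total - self.comparator.qaly_total

    @property
    def icer(self):
        return icer(self.delta_cost, self.delta_qaly)

    @property
    def nmb(self) -> float:
        return net_monetary_benefit(
            self.delta_cost, self.delta_qaly, self.settings.wtp_per_qaly
        )

    @property
    def cost_effective(self) -> bool:
        return self.nmb > 0

    def nmb_at(self, wtp: float) -> float:
        return net_monetary_benefit(self.delta_cost, self.delta_qaly, wtp)

    def icer_with_effect(self, delta_qaly: float):
        """ICER recomputed against an externally supplied QALY gain.

        The published report reused the ITT QALY gain (0.67) in every
        population's ICER; this helper reproduces that convention.
        """
        return icer(self.delta_cost, delta_qaly)

    def to_frame(self) -> pd.DataFrame:
        """Results in the layout of the published cost-effectiveness table."""
        rows = []
        for label, res in (("placebo", self.comparator), ("toripalimab", self.intervention)):
            rows.append(
                {
                    "arm": label,
                    "cost_pfs_state": res.cost_by_state["PFS"],
                    "cost_pd_state": res.cost_by_state["PD"],
                    "cost_total": res.cost_total,
                    "qaly_pfs_state": res.qaly_by_state["PFS"],
                    "qaly_pd_state": res.qaly_by_state["PD"],
                    "qaly_total": res.qaly_total,
                }
            )
        df = pd.DataFrame(rows).set_index("arm")
        df.loc["incremental"] = df.loc["toripalimab"] - df.loc["placebo"]
        return df

    def summary(self) -> str:
        ic = self.icer
        ic_str = f"{ic:,.0f} $/QALY" if isinstance(ic, float) else ic
        s = self.settings
        lines = [
            "Cost-effectiveness results",
            "=" * 62,
            f"population:        {self.population}",
            f"cycle / horizon:   {s.cycle_days:g} days x {s.n_cycles} cycles"
            f" ({s.horizon_years:g} y), discount {s.discount_annual:.1%}/y",
            "-" * 62,
            f"{'':22s}{'placebo':>16s}{'toripalimab':>16s}",
            f"{'cost, PFS state ($)':22s}{self.comparator.cost_by_state['PFS']:>16,.0f}"
            f"{self.intervention.cost_by_state['PFS']:>16,.0f}",
            f"{'cost, PD state ($)':22s}{self.comparator.cost_by_state['PD']:>16,.0f}"
            f"{self.intervention.cost_by_state['PD']:>16,.0f}",
            f"{'total cost ($)':22s}{self.comparator.cost_total:>16,.0f}"
            f"{self.intervention.cost_total:>16,.0f}",
            f"{'total QALYs':22s}{self.comparator.qaly_total:>16.3f}"
            f"{self.intervention.qaly_total:>16.3f}",
            "-" * 62,
            f"incremental cost:  ${self.delta_cost:,.0f}",
            f"incremental QALYs: {self.delta_qaly:.3f}",
            f"ICER:              {ic_str}",
            f"NMB at ${s.wtp_per_qaly:,.0f}/QALY: ${self.nmb:,.0f}"
            f"  ->  {'cost-effective' if self.cost_effective else 'not cost-effective'}",
        ]
        return "\n".join(lines)


class CostEffectivenessModel:
    """Two-arm partitioned-survival cost-effectiveness model.

    Parameters
    ----------
    spec : PopulationSpec
        Survival models, cost items and utilities for one population.
    settings : ModelSettings, optional
        Cycle structure, discounting, WTP and analysis settings.

    Examples
    --------
    >>> from pscea import published_analysis, CostEffectivenessModel
    >>> spec, settings = published_analysis("ITT")
    >>> res = CostEffectivenessModel(spec, settings).fit()
    >>> isinstance(res.icer, float)
    True
    """

    def __init__(self, spec: PopulationSpec, settings: ModelSettings | None = None):
        self.spec = spec
        self.settings = settings if settings is not None else ModelSettings()

    def fit(self) -> CEAResults:
        """Run both arms through the cohort engine."""
        return CEAResults(
            population=self.spec.population,
            intervention=run_arm(self.spec, INTERVENTION, self.settings),
            comparator=run_arm(self.spec, COMPARATOR, self.settings),
            settings=self.settings,
        )

    def one_way(self, parameters=None):
        """One-way deterministic sensitivity analysis (tornado)."""
        from .dsa import one_way

        return one_way(self.spec, self.settings, parameters=parameters)

    def run_psa(self, n_iter: int | None = None, seed: int = 0):
        """Probabilistic sensitivity analysis (Monte Carlo)."""
        from .psa import run_psa

        return run_psa(self.spec, self.settings, n_iter=n_iter, seed=seed)


def compare_arms(spec: PopulationSpec, settings: ModelSettings | None = None) -> CEAResults:
    """Functional shorthand for ``CostEffectivenessModel(spec, settings).fit()``."""
    return CostEffectivenessModel(spec, settings).fit()
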