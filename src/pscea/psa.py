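"""Probabilistic sensitivity analysis: parameter sampling, Monte Carlo
propagation, the cost-effectiveness plane and acceptability curves.

Costs are drawn from gamma and utilities from beta distributions with mean at
the base value and standard deviation ``(high - low) / (2 * 1.96)`` — the
published ranges are read as 95 % intervals (``sd_rule="range4"`` switches to
``range / 4``) — parameterised by method of moments.  Sampling is jointly
independent across parameters; grouped cost items share a single draw, and
utilities are shared across arms.  Survival parameters are held fixed: the
published analysis assigned distributions to the priced and utility inputs
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import accumulate, run_trace
from .model import CEAResults, net_monetary_benefit
from .params import ARMS, CostItem, ModelSettings, PopulationSpec, UtilityParam

logger = logging.getLogger(__name__)

DEFAULT_WTP_GRID = np.arange(0, 60001, 1000, dtype=float)
"""Default CEAC grid: $0–60,000/QALY in $1,000 steps (covers both published
thresholds, $25,100 and $37,653)."""


def _sd(low: float, high: float, rule: str) -> float:
    return (high - low) / (2 * 1.96) if rule == "range95" else (high - low) / 4.0


def sample_cost(item: CostItem, rng: np.random.Generator, sd_rule: str = "range95") -> float:
    """One gamma draw with mean = base and method-of-moments shape/scale."""
    mean = item.base_value
    sd = _sd(item.low, item.high, sd_rule)
    if item.distribution == "fixed" or sd == 0:
        return mean
    if mean == 0:
        return 0.0  # degenerate gamma
    shape = mean**2 / sd**2
    scale = sd**2 / mean
    return float(rng.gamma(shape, scale))


def sample_utility(u: UtilityParam, rng: np.random.Generator, sd_rule: str = "range95") -> float:
    """One beta draw with mean = base; uniform fallback if moments are infeasible."""
    mean = u.value
    sd = _sd(u.low, u.high, sd_rule)
    if u.distribution == "fixed" or sd == 0:
        return mean
    nu = mean * (1 - mean) / sd**2 - 1.0
    alpha, beta = mean * nu, (1 - mean) * nu
    if alpha <= 0 or beta <= 0:
        logger.warning(
            "beta moments infeasible (mean=%.3f, sd=%.3f); falling back to uniform", mean, sd
        )
        return float(rng.uniform(u.low, u.high))
    return float(rng.beta(alpha, beta))


def _quadrant(delta_qaly: float, delta_cost: float) -> str:
    ew = "E" if delta_qaly >= 0 else "W"
    ns = "N" if delta_cost >= 0 else "S"
    return ns + ew  # CE-plane quadrants: NE, SE, NW, SW


@dataclass
class PSAResults:
    """Monte Carlo samples of (dCost, dQALY) plus summaries."""

    samples: pd.DataFrame = field(repr=False)
    wtp: float
    seed: int
    base: CEAResults = field(repr=False, default=None)

    @property
    def n_iter(self) -> int:
        return len(self.samples)

    def acceptability(self, wtp: float | None = None) -> float:
        """Fraction of iterations with positive NMB at ``wtp``."""
        wtp = self.wtp if wtp is None else wtp
        nmb = wtp * self.samples["delta_qaly"] - self.samples["delta_cost"]
        return float((nmb > 0).mean())

    def quadrant_fractions(self) -> dict:
        frac = self.samples["quadrant"].value_counts(normalize=True).to_dict()
        return {q: float(frac.get(q, 0.0)) for q in ("NE", "SE", "NW", "SW")}

    def ceac(self, wtp_grid=None) -> pd.DataFrame:
        """Cost-effectiveness acceptability curve on a WTP grid."""
        grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
        if len(self.samples) == 0:
            raise ValueError("no samples")
        if np.any(grid < 0):
            raise ValueError("wtp grid must be non-negative")
        probs = [self.acceptability(w) for w in grid]
        return pd.DataFrame({"wtp": grid, "probability_cost_effective": probs})

    def summary(self) -> dict:
        return {
            "n_iter": self.n_iter,
            "seed": self.seed,
            "mean_delta_cost": float(self.samples["delta_cost"].mean()),
            "mean_delta_qaly": float(self.samples["delta_qaly"].mean()),
            "acceptability_at_wtp": self.acceptability(),
            "wtp": self.wtp,
            "quadrants": self.quadrant_fractions(),
        }

    # ----------------------------- plotting ------------------------------- #
    def plot_ce_plane(self, path=None, ax=None):
        """Scatter of the incremental cost-effectiveness pairs (dE, dC)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        ax.scatter(
            self.samples["delta_qaly"], self.samples["delta_cost"], s=6, alpha=0.4
        )
        lim = ax.get_xlim()
        grid = np.linspace(min(lim[0], 0), lim[1], 50)
        ax.plot(grid, self.wtp * grid, "r--", lw=1, label=f"WTP ${self.wtp:,.0f}/QALY")
        ax.axhline(0, color="k", lw=0.8)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("incremental QALYs")
        ax.set_ylabel("incremental cost ($)")
        ax.legend(fontsize=8)
        ax.figure.tight_layout()
        if path is not None:
            ax.figure.savefig(path, dpi=150)
            plt.close(ax.figure)
        return ax

    def plot_ceac(self, path=None, wtp_grid=None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        curve = self.ceac(wtp_grid)
        ax.plot(curve["wtp"], curve["probability_cost_effective"])
        ax.set_xlabel("willingness to pay ($/QALY)")
        ax.set_ylabel("P(cost-effective)")
        ax.set_ylim(-0.02, 1.02)
        ax.figure.tight_layout()
        if path is not None:
            ax.figure.savefig(path, dpi=150)
            plt.close(ax.figure)
        return ax


def run_psa(
    spec: PopulationSpec,
    settings: ModelSettings,
    n_iter: int | None = None,
    seed: int = 0,
) -> PSAResults:
    """Monte Carlo propagation of the parameter distributions.

    Per iteration every cost group and both utilities are redrawn jointly and
    both arms are re-evaluated; the occupancy traces depend only on the fixed
    survival models and are computed once.  Identical ``seed`` and inputs give
    identical output.
    """
    n_iter = settings.psa_iterations if n_iter is None else int(n_iter)
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    rng = np.random.default_rng(seed)

    traces = {arm: run_trace(spec.survival[arm].os, spec.survival[arm].pfs, settings)
              for arm in ARMS}
    arm_costs = {arm: spec.costs_for(arm) for arm in ARMS}
    group_order = list(dict.fromkeys(c.psa_group for c in spec.costs))

    records = []
    for i in range(n_iter):
        draws = {}
        for g in group_order:
            proto = next(c for c in spec.costs if c.psa_group == g)
            draws[g] = sample_cost(proto, rng, settings.sd_rule)
        u_pfs = sample_utility(spec.utilities.pfs, rng, settings.sd_rule)
        u_pd = sample_utility(spec.utilities.pd, rng, settings.sd_rule)
        utilities = replace(
            spec.utilities,
            pfs=replace(spec.utilities.pfs, value=u_pfs, low=min(u_pfs, spec.utilities.pfs.low),
                        high=max(u_pfs, spec.utilities.pfs.high)),
            pd=replace(spec.utilities.pd, value=min(u_pd, u_pfs),
                       low=min(u_pd, u_pfs, spec.utilities.pd.low),
                       high=max(u_pd, spec.utilities.pd.high)),
        )
        totals = {}
        for arm in ARMS:
            costs = tuple(
                replace(c, base_value=draws[c.psa_group],
                        low=min(draws[c.psa_group], c.low),
                        high=max(draws[c.psa_group], c.high))
                for c in arm_costs[arm]
            )
            res = accumulate(traces[arm], costs, utilities, settings, arm)
            totals[arm] = (res.cost_total, res.qaly_total)
        dc = totals["toripalimab"][0] - totals["placebo"][0]
        de = totals["toripalimab"][1] - totals["placebo"][1]
        rec = {"iteration": i, "delta_cost": dc, "delta_qaly": de,
               "quadrant": _quadrant(de, dc),
               "acceptable": net_monetary_benefit(dc, de, settings.wtp_per_qaly) > 0,
               "u_pfs": u_pfs, "u_pd": u_pd}
        rec.update({f"cost:{g}": v for g, v in draws.items()})
        records.append(rec)

    samples = pd.DataFrame.from_records(records)
    return PSAResults(samples=samples, wtp=settings.wtp_per_qaly, seed=seed)


def ceac(samples: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """CEAC from a raw sample table (columns delta_cost, delta_qaly)."""
    if len(samples) == 0:
        raise ValueError("no samples")
    grid = np.asarray(wtp_grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("wtp grid must be non-negative")
    probs = [
        float(((w * samples["delta_qaly"] - samples["delta_cost"]) > 0).mean())
        for w in grid
    ]
    return pd.DataFrame({"wtp": grid, "probability_cost_effective": probs})
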