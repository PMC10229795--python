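"""One-way deterministic sensitivity analysis and tornado ranking.

Each cost parameter (grouped items move together) and each state utility is
set to its low and high bound in turn — all else at base — and the ICER is
recomputed; rows are ranked by the absolute ICER spread.  Utility bounds are
clipped to [0, 1] with a logged note.  Survival parameters are not varied:
the published one-way analysis swept the priced and utility inputs only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .params import ModelSettings, PopulationSpec, UtilityParam
from .model import compare_arms

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


class TornadoTable:
    """Rows of a one-way sweep, sorted by ICER spread (descending)."""

    def __init__(self, rows, base_icer: float):
        self.rows = sorted(rows, key=lambda r: (-r.spread if np.isfinite(r.spread) else np.inf))
        self.base_icer = base_icer

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": r.parameter,
                    "low_value": r.low_value,
                    "high_value": r.high_value,
                    "icer_at_low": r.icer_at_low,
                    "icer_at_high": r.icer_at_high,
                    "spread": r.spread,
                }
                for r in self.rows
            ]
        )

    def plot(self, path=None, ax=None):
        """Horizontal-bar tornado diagram."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.4 * len(self.rows) + 1.5))
        rows = list(reversed(self.rows))
        y = np.arange(len(rows))
        for i, r in enumerate(rows):
            lo, hi = sorted((r.icer_at_low, r.icer_at_high))
            ax.barh(i, hi - lo, left=lo, color="#4878d0", height=0.6)
        ax.axvline(self.base_icer, color="k", lw=1, ls="--", label="base-case ICER")
        ax.set_yticks(y, [r.parameter for r in rows])
        ax.set_xlabel("ICER ($/QALY)")
        ax.legend(loc="lower right", fontsize=8)
        ax.figure.tight_layout()
        if path is not None:
            ax.figure.savefig(path, dpi=150)
            plt.close(ax.figure)
        return ax


def _icer_number(result) -> float:
    ic = result.icer
    return ic if isinstance(ic, float) else np.nan


def _clip_utility(value: float, name: str) -> float:
    if value > 1.0:
        logger.info("%s high bound %.3f clipped to 1.0", name, value)
        return 1.0
    return max(value, 0.0)


def one_way(
    spec: PopulationSpec, settings: ModelSettings, parameters=None
) -> TornadoTable:
    """Sweep every cost group and both utilities over [low, high].

    ``parameters`` optionally restricts the sweep to the named cost groups /
    ``u_pfs`` / ``u_pd``.
    """
    base_icer = _icer_number(compare_arms(spec, settings))

    groups: dict[str, list] = {}
    for item in spec.costs:
        groups.setdefault(item.psa_group, []).append(item)
    names = list(groups) + ["u_pfs", "u_pd"]
    if parameters is not None:
        parameters = list(parameters)
        unknown = set(parameters) - set(names)
        if unknown:
            raise ValueError(f"unknown parameter(s) {sorted(unknown)}")
        names = [n for n in names if n in parameters]
    if not names:
        raise ValueError("empty parameter selection")

    rows = []
    for name in names:
        if name in ("u_pfs", "u_pd"):
            u = spec.utilities.pfs if name == "u_pfs" else spec.utilities.pd
            lo, hi = max(u.low, 0.0), _clip_utility(u.high, name)
            endpoints = []
            for bound in (lo, hi):
                bounded = UtilityParam(
                    value=bound,
                    low=min(bound, u.low),
                    high=max(bound, u.high),
                    distribution=u.distribution,
                )
                # keep u_pd <= u_pfs structurally valid during the sweep
                utils = spec.utilities
                if name == "u_pfs":
                    new_utils = replace(
                        utils,
                        pfs=bounded,
                        pd=utils.pd if bound >= utils.pd.value else replace(utils.pd, value=bound, low=min(bound, utils.pd.low)),
                    )
                else:
                    new_utils = replace(
                        utils,
                        pd=bounded,
                        pfs=utils.pfs if bound <= utils.pfs.value else replace(utils.pfs, value=bound, high=max(bound, utils.pfs.high)),
                    )
                endpoints.append(
                    _icer_number(compare_arms(replace(spec, utilities=new_utils), settings))
                )
            rows.append(TornadoRow(name, lo, hi, endpoints[0], endpoints[1]))
        else:
            members = groups[name]
            lo, hi = members[0].low, members[0].high
            endpoints = []
            for attr in ("low", "high"):
                new_costs = tuple(
                    replace(c, base_value=getattr(c, attr)) if c.psa_group == name else c
                    for c in spec.costs
                )
                endpoints.append(
                    _icer_number(compare_arms(replace(spec, costs=new_costs), settings))
                )
            rows.append(TornadoRow(name, lo, hi, endpoints[0], endpoints[1]))
    return TornadoTable(rows, base_icer=base_icer)
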