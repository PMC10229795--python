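"""Synthetic survival data with the structure the fitting stage assumes.

Stands in for the trial's unavailable patient-level data: Weibull event
times with administrative and/or random censoring, product-limit (KM)
estimates, and noisy "digitized" curve coordinates emulating plot-digitizer
error.  Everything is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .kmfit import DigitizedCurve


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and censoring scheme for one simulated cohort.

    ``censoring`` is ``"none"``, ``("administrative", T)`` (everyone still at
    risk at T is censored there) or ``("exponential", r)`` (random censoring
    with rate r, same time unit as the event distribution).  Defaults mirror
    the published fits' shape range (roughly 1.2–2.3).
    """

    shape: float = 1.4
    rate: float = 0.05
    n_subjects: int = 300
    censoring: object = "none"
    noise_sd: float = 0.0
    seed: int = 0
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("shape and rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.censoring != "none":
            kind, value = self.censoring
            if kind not in ("administrative", "exponential"):
                raise ValueError(f"unknown censoring kind {kind!r}")
            if value < 0:
                raise ValueError("censoring parameter must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def simulate_ipd(config: SimulationConfig) -> pd.DataFrame:
    """Draw event/censoring records by inverse transform.

    Event times are ``(-ln U / rate) ** (1 / shape)``; censoring is applied
    per ``config.censoring``.
    """
    rng = np.random.default_rng(config.seed)
    u = rng.uniform(size=config.n_subjects)
    t_event = (-np.log(u) / config.rate) ** (1.0 / config.shape)
    if config.censoring == "none":
        time, event = t_event, np.ones(config.n_subjects, dtype=int)
    else:
        kind, value = config.censoring
        if kind == "administrative":
            c = np.full(config.n_subjects, float(value))
        else:
            if value == 0:
                c = np.full(config.n_subjects, np.inf)
            else:
                c = rng.exponential(scale=1.0 / value, size=config.n_subjects)
        event = (t_event < c).astype(int)
        time = np.minimum(t_event, c)
    return pd.DataFrame({"time": time, "event": event})


def km_estimate(ipd, time_unit: str = "months") -> DigitizedCurve:
    """Product-limit estimate of an IPD table as a step-function curve."""
    df = pd.DataFrame(ipd)
    if len(df) == 0:
        raise ValueError("empty IPD")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    sf = kmf.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    if times[0] > 0:  # lifelines always includes t=0, but be safe
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    # enforce strict monotonicity of the time grid (ties already collapsed)
    return DigitizedCurve(times=times, survival=surv, time_unit=time_unit)


def survival_at(curve: DigitizedCurve, grid) -> np.ndarray:
    """Step-function (right-continuous) evaluation of a KM curve on a grid."""
    grid = np.asarray(grid, dtype=float)
    idx = np.searchsorted(curve.times, grid, side="right") - 1
    out = np.where(idx >= 0, curve.survival[np.maximum(idx, 0)], 1.0)
    return out


def digitize(
    curve: DigitizedCurve, grid, noise_sd: float = 0.0, seed: int = 0
) -> DigitizedCurve:
    """Emulate digitizing a plotted curve at the given time grid.

    Samples the step function at ``grid``, applies multiplicative Gaussian
    noise of fractional sd ``noise_sd``, re-monotonizes with a running
    minimum and clips to [0, 1] — always a valid, non-increasing curve.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    s = survival_at(curve, grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s = s * (1.0 + rng.normal(0.0, noise_sd, size=len(grid)))
    s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
    return DigitizedCurve(times=grid, survival=s, time_unit=curve.time_unit)
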