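"""Weibull accelerated-failure-time (AFT) survival mathematics.

The survival inputs of the decision model are Weibull fits to the trial's
overall-survival (OS) and progression-free-survival (PFS) curves, reported in
the AFT parameterisation used by ``survival::survreg`` in R: a location
``intercept`` (log-time) and a ``log_scale``.  The equivalent proportional-
hazards form has

* shape  ``gamma = exp(-log_scale)``
* rate   ``lambda = exp(-gamma * intercept)``

and survival function ``S(t) = exp(-lambda * t**gamma)``.

All published fits use months as the time unit; one calendar month is taken as
30.4375 days (365.25 / 12), so a 3-week model cycle is 21 / 30.4375 ~ 0.69
months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import gamma as _gamma_function

if TYPE_CHECKING:  # pragma: no cover
    from .params import ModelSettings

MONTH_DAYS = 30.4375
"""Days per calendar month (365.25 / 12)."""

#: Days per supported time unit for cycle-grid conversion.
UNIT_DAYS = {"days": 1.0, "weeks": 7.0, "months": MONTH_DAYS, "years": 365.25}

_CONSISTENCY_RTOL = 1e-6


@dataclass(frozen=True)
class WeibullParams:
    """One Weibull survival model in both AFT and shape/rate form.

    Parameters
    ----------
    shape : float
        Weibull shape (``gamma``), dimensionless, > 0.
    rate : float
        Weibull rate (``lambda``), in ``time_unit**-shape``, > 0.
    intercept, log_scale : float, optional
        The AFT location and log-scale the shape/rate derive from.  When both
        an AFT pair and a shape/rate pair are supplied they must agree to
        1e-6 relative tolerance.
    time_unit : str
        Unit of the time axis; one of ``days``, ``weeks``, ``months``,
        ``years``.  The published fits use months.
    """

    shape: float
    rate: float
    intercept: float | None = None
    log_scale: float | None = None
    time_unit: str = "months"
    family: str = field(default="weibull", repr=False)  # reserved for extension

    def __post_init__(self) -> None:
        if not (math.isfinite(self.shape) and self.shape > 0):
            raise ValueError(f"shape must be finite and > 0, got {self.shape}")
        if not (math.isfinite(self.rate) and self.rate > 0):
            raise ValueError(f"rate must be finite and > 0, got {self.rate}")
        if self.time_unit not in UNIT_DAYS:
            raise ValueError(
                f"unknown time_unit {self.time_unit!r}; expected one of {sorted(UNIT_DAYS)}"
            )
        if self.intercept is not None and self.log_scale is not None:
            shape_aft = math.exp(-self.log_scale)
            rate_aft = math.exp(-shape_aft * self.intercept)
            if not (
                math.isclose(shape_aft, self.shape, rel_tol=_CONSISTENCY_RTOL)
                and math.isclose(rate_aft, self.rate, rel_tol=_CONSISTENCY_RTOL)
            ):
                raise ValueError(
                    "inconsistent parameterisation: AFT "
                    f"(intercept={self.intercept}, log_scale={self.log_scale}) implies "
                    f"shape={shape_aft:.8g}, rate={rate_aft:.8g}, got "
                    f"shape={self.shape}, rate={self.rate}"
                )

    # ------------------------------------------------------------------ #
    @classmethod
    def from_aft(
        cls, intercept: float, log_scale: float, time_unit: str = "months"
    ) -> "WeibullParams":
        """Build from the AFT location / log-scale pair (``survreg`` output)."""
        if not (math.isfinite(intercept) and math.isfinite(log_scale)):
            raise ValueError(
                f"intercept and log_scale must be finite, got ({intercept}, {log_scale})"
            )
        shape = math.exp(-log_scale)
        rate = math.exp(-shape * intercept)
        return cls(
            shape=shape, rate=rate, intercept=intercept, log_scale=log_scale, time_unit=time_unit
        )

    @classmethod
    def from_shape_rate(
        cls, shape: float, rate: float, time_unit: str = "months"
    ) -> "WeibullParams":
        """Build from shape/rate, deriving the equivalent AFT pair."""
        if not (math.isfinite(shape) and shape > 0 and math.isfinite(rate) and rate > 0):
            raise ValueError(f"shape and rate must be finite and > 0, got ({shape}, {rate})")
        return cls(
            shape=shape,
            rate=rate,
            intercept=-math.log(rate) / shape,
            log_scale=-math.log(shape),
            time_unit=time_unit,
        )

    # ------------------------------------------------------------------ #
    def survival(self, t):
        """S(t) = exp(-rate * t**shape) for t >= 0 (scalar or array)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("survival time must be >= 0")
        out = np.exp(-self.rate * np.power(t_arr, self.shape))
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def median(self) -> float:
        """Time at which S(t) = 1/2: ``(ln 2 / rate) ** (1 / shape)``."""
        return (math.log(2.0) / self.rate) ** (1.0 / self.shape)

    def mean(self, cap: float | None = None, step: float = 0.05) -> float:
        """Mean survival time, optionally restricted to ``[0, cap]``.

        The uncapped mean is ``rate**(-1/shape) * Gamma(1 + 1/shape)``.  The
        restricted mean is the trapezoid integral of S on ``[0, cap]`` with
        grid step at most ``step`` (same unit as the parameters).
        """
        if cap is None:
            return self.rate ** (-1.0 / self.shape) * _gamma_function(1.0 + 1.0 / self.shape)
        if cap < 0:
            raise ValueError("cap must be >= 0")
        if cap == 0:
            return 0.0
        n = max(int(math.ceil(cap / step)), 2)
        t = np.linspace(0.0, cap, n + 1)
        return float(np.trapezoid(self.survival(t), t))

    def with_time_unit(self, time_unit: str) -> "WeibullParams":
        return replace(self, time_unit=time_unit)


def aft_to_weibull(
    intercept: float, log_scale: float, time_unit: str = "months"
) -> WeibullParams:
    """Convert an AFT (intercept, log-scale) pair to shape/rate form."""
    return WeibullParams.from_aft(intercept, log_scale, time_unit=time_unit)


def weibull_survival(params: WeibullParams, t) -> float:
    """Survival probability at ``t`` (>= 0)."""
    return params.survival(t)


def weibull_median(params: WeibullParams) -> float:
    """Median survival time."""
    return params.median()


def weibull_mean(params: WeibullParams, cap: float | None = None) -> float:
    """(Restricted) mean survival time."""
    return params.mean(cap=cap)


def cycle_length_in(time_unit: str, cycle_days: float) -> float:
    """Length of one model cycle expressed in ``time_unit``."""
    if time_unit not in UNIT_DAYS:
        raise ValueError(f"unknown time_unit {time_unit!r}")
    return cycle_days / UNIT_DAYS[time_unit]


def survival_grid(params: WeibullParams, settings: "ModelSettings") -> np.ndarray:
    """S evaluated at every cycle boundary ``t_k = k * cycle_length``.

    Returns an array of length ``settings.n_cycles + 1`` with element 0 equal
    to 1; non-increasing by construction.
    """
    dt = cycle_length_in(params.time_unit, settings.cycle_days)
    t = np.arange(settings.n_cycles + 1, dtype=float) * dt
    return params.survival(t)
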