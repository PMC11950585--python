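"""Statistical-process-control primitives: 3σ limits and CUSUM.

The 3σ chart declares a charted value out of control when it leaves
``[μ − mσ, μ + mσ]`` (multiplier ``m = 3`` by default).  Boundary values are
in control: a flag requires strict exceedance.

The CUSUM chart accumulates deviations from the in-control mean μ₀ with an
allowance ``k`` per step::

    S⁺_i = max(0, S⁺_{i-1} + x_i − μ₀ − k)
    S⁻_i = min(0, S⁻_{i-1} + x_i − μ₀ + k)

An alarm fires when ``S⁺ > h`` (upward shift) or ``|S⁻| > h`` (downward
shift), with decision interval ``h``.  Defaults follow common practice:
``k = σ/2``, ``h = 4σ``.  The state is *not* reset after an alarm; every
alarm step is reported, so a sustained shift keeps signalling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError

__all__ = [
    "ControlLimits",
    "CusumParams",
    "CusumState",
    "CusumResult",
    "three_sigma_flag",
    "flag_series",
    "run_rule_two_of_three",
    "cusum_update",
    "cusum_run",
]


@dataclass(frozen=True)
class ControlLimits:
    """Center line μ, process σ and the control-limit multiplier."""

    center: float
    sigma: float
    multiplier: float = 3.0

    def __post_init__(self):
        if not np.isfinite(self.center):
            raise ParameterError("center must be finite")
        if not (self.sigma > 0):
            raise ParameterError(f"sigma must be positive, got {self.sigma}")
        if not (self.multiplier > 0):
            raise ParameterError(f"multiplier must be positive, got {self.multiplier}")

    @property
    def lower(self) -> float:
        return self.center - self.multiplier * self.sigma

    @property
    def upper(self) -> float:
        return self.center + self.multiplier * self.sigma


def three_sigma_flag(value: float, limits: ControlLimits) -> bool:
    """True iff the value lies strictly outside the control limits."""
    if not np.isfinite(value):
        raise InputError(f"chart value must be finite, got {value}")
    return bool(value < limits.lower or value > limits.upper)


def flag_series(values, limits: ControlLimits) -> np.ndarray:
    """Vectorized :func:`three_sigma_flag` over an array of chart values."""
    values = np.asarray(values, dtype=float)
    if values.size and not np.all(np.isfinite(values)):
        raise InputError("chart values must be finite")
    return (values < limits.lower) | (values > limits.upper)


def run_rule_two_of_three(values, limits: ControlLimits) -> bool:
    """Supplementary run rule on the last three chart values.

    True iff at least two of the three lie beyond the *same-side* 2σ limit.
    The 2σ limits derive from the chart's center and sigma regardless of its
    own multiplier.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (3,):
        raise InputError(f"run rule needs exactly three values, got {values.shape}")
    if not np.all(np.isfinite(values)):
        raise InputError("chart values must be finite")
    upper2 = limits.center + 2.0 * limits.sigma
    lower2 = limits.center - 2.0 * limits.sigma
    return bool((values > upper2).sum() >= 2 or (values < lower2).sum() >= 2)


@dataclass(frozen=True)
class CusumParams:
    """CUSUM parameters; ``k``/``h`` default to σ/2 and 4σ when omitted."""

    mu0: float
    sigma: float
    k: float = None
    h: float = None

    def __post_init__(self):
        if not (self.sigma > 0):
            raise ParameterError(f"sigma must be positive, got {self.sigma}")
        if self.k is None:
            object.__setattr__(self, "k", self.sigma / 2.0)
        if self.h is None:
            object.__setattr__(self, "h", 4.0 * self.sigma)
        if self.k < 0:
            raise ParameterError(f"allowance k must be >= 0, got {self.k}")
        if not (self.h > 0):
            raise ParameterError(f"decision interval h must be positive, got {self.h}")


@dataclass(frozen=True)
class CusumState:
    """Running CUSUM state after ``step_index`` observations."""

    s_plus: float = 0.0
    s_minus: float = 0.0
    step_index: int = 0
    alarm_high: bool = False
    alarm_low: bool = False


def cusum_update(state: CusumState, x_i: float, params: CusumParams) -> CusumState:
    """One CUSUM step; returns a new state (the input state is unchanged)."""
    if not np.isfinite(x_i):
        raise InputError(f"CUSUM input must be finite, got {x_i}")
    s_plus = max(0.0, state.s_plus + x_i - params.mu0 - params.k)
    s_minus = min(0.0, state.s_minus + x_i - params.mu0 + params.k)
    return CusumState(
        s_plus=s_plus,
        s_minus=s_minus,
        step_index=state.step_index + 1,
        alarm_high=s_plus > params.h,
        alarm_low=abs(s_minus) > params.h,
    )


@dataclass
class CusumResult:
    """Full CUSUM trajectory over a series (1-based step indices)."""

    s_plus: np.ndarray
    s_minus: np.ndarray
    alarm_high: np.ndarray
    alarm_low: np.ndarray
    params: CusumParams

    @property
    def alarm_steps(self) -> list[int]:
        """Ordered 1-based indices of every alarmed step (either side)."""
        return [int(i) + 1 for i in np.flatnonzero(self.alarm_high | self.alarm_low)]

    @property
    def states(self) -> list[CusumState]:
        return [
            CusumState(
                s_plus=float(self.s_plus[i]),
                s_minus=float(self.s_minus[i]),
                step_index=i + 1,
                alarm_high=bool(self.alarm_high[i]),
                alarm_low=bool(self.alarm_low[i]),
            )
            for i in range(len(self.s_plus))
        ]


def cusum_run(series, params: CusumParams) -> CusumResult:
    """Fold :func:`cusum_update` over a series from the zero state.

    The state is not reset after an alarm; all alarm steps appear in
    ``result.alarm_steps``.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise InputError("CUSUM series must be nonempty")
    if not np.all(np.isfinite(series)):
        raise InputError("CUSUM series must be finite")
    n = series.size
    s_plus = np.empty(n)
    s_minus = np.empty(n)
    sp = sm = 0.0
    for i, x in enumerate(series):
        sp = max(0.0, sp + x - params.mu0 - params.k)
        sm = min(0.0, sm + x - params.mu0 + params.k)
        s_plus[i] = sp
        s_minus[i] = sm
    return CusumResult(
        s_plus=s_plus,
        s_minus=s_minus,
        alarm_high=s_plus > params.h,
        alarm_low=np.abs(s_minus) > params.h,
        params=params,
    )
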