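"""Monitoring orchestration: per-image flags, daily charts, CUSUM drift alarms.

Given a day-indexed stream and a fitted :class:`~spcdrift.ood_metrics.ReferenceProfile`,
:func:`monitor`

1. scores every image and applies the 3σ flag with limits from the profile's
   per-image metric μ/σ;
2. averages the metric within each day and charts the daily means — by
   default against the *same* per-image limits (daily averaging then tends to
   obscure moderate drift, which is the motivation for CUSUM), optionally
   against √batch-tightened limits;
3. runs a two-sided CUSUM on the daily means with μ₀ = metric μ.

The σ entering the CUSUM's default ``k = σ/2`` and ``h = 4σ`` is, by default,
the per-image metric σ (``sigma_scale="per-image"``).  With daily batches of
``d`` images the daily mean has standard deviation σ/√d, so this convention
is deliberately conservative: the allowance swallows the small residual OOD
contamination present even in the nominal phase, and a genuine rate shift —
which moves the daily mean by many σ/√d — still crosses ``h`` within days.
``sigma_scale="daily-mean"`` rescales k and h to σ/√d units for a textbook
CUSUM on the charted statistic (markedly more false-alarm prone over long
horizons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GapError, ParameterError
from .ood_metrics import ReferenceProfile, score_stream
from .simulate import StreamRecord, stream_to_frame
from .spc_charts import (
    ControlLimits,
    CusumParams,
    CusumResult,
    cusum_run,
    flag_series,
)

__all__ = [
    "ChartConfig",
    "MetricSeries",
    "MonitorReport",
    "daily_aggregate",
    "monitor",
    "detection_delay",
    "DelaySummary",
    "plot_charts",
]


@dataclass(frozen=True)
class ChartConfig:
    """Knobs of the monitoring run.

    ``multiplier`` is the control-limit width in σ units; ``k_factor`` and
    ``h_factor`` are the CUSUM allowance and decision interval as multiples
    of the σ chosen by ``sigma_scale``.
    """

    multiplier: float = 3.0
    sigma_scale: str = "per-image"  # or "daily-mean"
    k_factor: float = 0.5
    h_factor: float = 4.0
    tightened_daily_limits: bool = False

    def __post_init__(self):
        if self.sigma_scale not in ("per-image", "daily-mean"):
            raise ConfigurationError(
                f"sigma_scale must be 'per-image' or 'daily-mean', got {self.sigma_scale!r}"
            )
        if self.k_factor < 0 or self.h_factor <= 0 or self.multiplier <= 0:
            raise ConfigurationError("multiplier/h_factor must be > 0 and k_factor >= 0")


@dataclass
class MetricSeries:
    """Per-day mean metric plus the underlying per-image table."""

    days: np.ndarray
    daily_values: np.ndarray
    per_image: pd.DataFrame | None = None

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=int)
        self.daily_values = np.asarray(self.daily_values, dtype=float)
        if self.days.shape != self.daily_values.shape:
            raise ParameterError("days and daily_values must align")
        if self.days.size > 1 and not np.all(np.diff(self.days) > 0):
            raise ParameterError("days must be strictly increasing")


def daily_aggregate(scored: pd.DataFrame, sparse_ok: bool = False) -> MetricSeries:
    """Average the per-image metric within each day.

    ``scored`` needs columns ``day``, ``image_id``, ``metric``.  Days must be
    contiguous between the first and last observed day unless
    ``sparse_ok=True`` declares the stream sparse.
    """
    for col in ("day", "image_id", "metric"):
        if col not in scored.columns:
            raise ParameterError(f"scored stream lacks column {col!r}")
    if len(scored) == 0:
        return MetricSeries(np.empty(0, dtype=int), np.empty(0), scored)
    grouped = scored.groupby("day", sort=True)["metric"].mean()
    days = grouped.index.to_numpy(dtype=int)
    if not sparse_ok:
        missing = sorted(set(range(days.min(), days.max() + 1)) - set(days.tolist()))
        if missing:
            raise GapError(
                f"days {missing[:5]}{'...' if len(missing) > 5 else ''} have no "
                "records; pass sparse_ok=True for a sparse stream"
            )
    return MetricSeries(days, grouped.to_numpy(), scored)


@dataclass
class MonitorReport:
    """Everything a monitoring run produced, ready for serialization."""

    image_flags: pd.DataFrame
    daily_series: MetricSeries
    daily_three_sigma_flags: list[int]
    cusum: CusumResult
    cusum_alarm_days: list[int]
    cusum_alarm_sides: dict[int, str]
    first_alarm_day: int | None
    limits: ControlLimits
    daily_limits: ControlLimits
    config_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_images": int(len(self.image_flags)),
            "n_image_flags": int(self.image_flags["flagged"].sum()),
            "daily_three_sigma_flags": self.daily_three_sigma_flags,
            "cusum_alarm_days": self.cusum_alarm_days,
            "cusum_alarm_sides": {str(d): s for d, s in self.cusum_alarm_sides.items()},
            "first_alarm_day": self.first_alarm_day,
            "limits": {"center": self.limits.center, "sigma": self.limits.sigma,
                       "multiplier": self.limits.multiplier},
            "config": self.config_echo,
        }

    def save_json(self, path) -> None:
        import json

        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def chart_frame(self) -> pd.DataFrame:
        """Daily chart trajectory: day, value, s_plus, s_minus, flags."""
        return pd.DataFrame({
            "day": self.daily_series.days,
            "value": self.daily_series.daily_values,
            "s_plus": self.cusum.s_plus,
            "s_minus": self.cusum.s_minus,
            "three_sigma_flag": [int(d in self.daily_three_sigma_flags)
                                 for d in self.daily_series.days],
            "cusum_alarm": [int(d in self.cusum_alarm_days)
                            for d in self.daily_series.days],
        })


def monitor(stream: Sequence[StreamRecord], profile: ReferenceProfile,
            config: ChartConfig = ChartConfig()) -> MonitorReport:
    """Run the full monitoring pipeline on a stream.

    Returns per-image 3σ flags, daily-mean 3σ flags, and CUSUM alarms over
    the daily means, with the alarm side annotated (for cosine similarity
    drift manifests low-side; for Mahalanobis distance high-side).
    """
    if not (profile.metric_std > 0):
        raise ConfigurationError("profile metric_std must be positive")
    if len(stream) == 0:
        raise ParameterError("empty stream")

    scores = score_stream(stream, profile)
    frame = stream_to_frame(stream)[["day", "image_id", "truth_label"]]
    frame["metric"] = scores

    limits = ControlLimits(profile.metric_mean, profile.metric_std, config.multiplier)
    frame["flagged"] = flag_series(scores, limits)
    series = daily_aggregate(frame)

    counts = frame.groupby("day")["metric"].size()
    batch_size = int(counts.median())
    if config.tightened_daily_limits:
        daily_limits = ControlLimits(
            profile.metric_mean, profile.metric_std / np.sqrt(batch_size),
            config.multiplier,
        )
    else:
        daily_limits = limits
    daily_flagged = flag_series(series.daily_values, daily_limits)

    sigma_c = profile.metric_std
    if config.sigma_scale == "daily-mean":
        sigma_c = profile.metric_std / np.sqrt(batch_size)
    params = CusumParams(mu0=profile.metric_mean, sigma=sigma_c,
                         k=config.k_factor * sigma_c, h=config.h_factor * sigma_c)
    cusum = cusum_run(series.daily_values, params)

    day_arr = series.days
    alarm_mask = cusum.alarm_high | cusum.alarm_low
    alarm_days = [int(d) for d in day_arr[alarm_mask]]
    sides = {}
    for i in np.flatnonzero(alarm_mask):
        both = cusum.alarm_high[i] and cusum.alarm_low[i]
        sides[int(day_arr[i])] = "both" if both else ("high" if cusum.alarm_high[i] else "low")

    return MonitorReport(
        image_flags=frame[["day", "image_id", "truth_label", "metric", "flagged"]],
        daily_series=series,
        daily_three_sigma_flags=[int(d) for d in day_arr[daily_flagged]],
        cusum=cusum,
        cusum_alarm_days=alarm_days,
        cusum_alarm_sides=sides,
        first_alarm_day=alarm_days[0] if alarm_days else None,
        limits=limits,
        daily_limits=daily_limits,
        config_echo={
            "metric_name": profile.metric_name,
            "multiplier": config.multiplier,
            "sigma_scale": config.sigma_scale,
            "k": params.k, "h": params.h, "mu0": params.mu0,
            "batch_size": batch_size,
            "tightened_daily_limits": config.tightened_daily_limits,
        },
    )


@dataclass(frozen=True)
class DelaySummary:
    """Detection delay relative to a known shift day."""

    delay: int | None
    first_alarm_on_or_after_shift: int | None
    false_alarm_days: tuple[int, ...]


def detection_delay(report: MonitorReport, shift_day: int) -> DelaySummary:
    """Days from the true shift to the first alarm at/after it.

    Alarms strictly before ``shift_day`` are reported separately as false
    alarms; the delay is None when no alarm occurs on or after the shift.
    """
    days = report.daily_series.days
    if not (days.min() <= shift_day <= days.max() + 1):
        raise ParameterError(f"shift_day {shift_day} outside monitored range")
    false_alarms = tuple(d for d in report.cusum_alarm_days if d < shift_day)
    post = [d for d in report.cusum_alarm_days if d >= shift_day]
    if not post:
        return DelaySummary(None, None, false_alarms)
    return DelaySummary(post[0] - shift_day, post[0], false_alarms)


def plot_charts(report: MonitorReport, path, shift_day: int | None = None) -> None:
    """Three-panel control-chart figure: per-image, daily 3σ, CUSUM."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(9, 9), sharex=False)
    imgs = report.image_flags
    x = np.arange(len(imgs))
    axes[0].scatter(x, imgs["metric"], s=4,
                    c=np.where(imgs["flagged"], "crimson", "steelblue"))
    for y in (report.limits.lower, report.limits.center, report.limits.upper):
        axes[0].axhline(y, color="k", ls="--", lw=0.7)
    axes[0].set_title("per-image metric with 3σ limits")

    d = report.daily_series
    axes[1].plot(d.days, d.daily_values, "o-", ms=3)
    for y in (report.daily_limits.lower, report.daily_limits.center, report.daily_limits.upper):
        axes[1].axhline(y, color="k", ls="--", lw=0.7)
    axes[1].set_title("daily mean metric")

    axes[2].plot(d.days, report.cusum.s_plus, label="S+", color="tab:blue")
    axes[2].plot(d.days, report.cusum.s_minus, label="S-", color="tab:green")
    h = report.cusum.params.h
    axes[2].axhline(h, color="k", ls="--", lw=0.7)
    axes[2].axhline(-h, color="k", ls="--", lw=0.7)
    for day in report.cusum_alarm_days:
        axes[2].axvline(day, color="crimson", alpha=0.3, lw=0.8)
    axes[2].legend()
    axes[2].set_title("CUSUM over daily means")
    if shift_day is not None:
        for ax in axes[1:]:
            ax.axvline(shift_day, color="purple", ls=":", lw=1.2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
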