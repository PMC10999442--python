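"""Core body temperature mathematics.

Quantifies two features of an intra-abdominal logger trace:

* **Stress-induced hyperthermia (SIH)** — the transient rise of core
  temperature (``T_c``) above a slow running baseline (``T_s``, the centred
  12-h running average) following a psychological stressor.  Each event is
  summarised by the signed area under ``T_c - T_s`` over a 50-min window
  (°C·min) and by the maximum deviation in that window (amplitude, °C).

* **Circadian rhythm of core temperature (CRT)** — a single-component
  cosinor (cosine with fixed 24-h period) fitted by linear least squares to
  each civil day of data, yielding mesor, amplitude, acrophase and the
  cosinor minimum/maximum.  Daily fits are averaged over blocks of three
  consecutive days ("periods") for group comparison.

All functions operate on :class:`TemperatureTrace`, a uniform-grid series
(default 5-min sampling) of one animal's temperature and activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureTrace",
    "BaselineTrace",
    "SIHMetrics",
    "CosinorFit",
    "PeriodSummary",
    "running_baseline",
    "sih_metrics",
    "cosinor_fit_day",
    "cosinor_series",
    "summarise_periods",
]

#: plausible physiological range for ovine core temperature (°C); samples
#: outside it are flagged, not rejected
TC_RANGE = (33.0, 43.0)


@dataclass
class TemperatureTrace:
    """One animal's uniform-grid core temperature (and activity) series.

    Parameters
    ----------
    animal_id : str
        Identifier of the animal the logger was implanted in.
    timestamps : pandas.DatetimeIndex
        Strictly increasing instants on a uniform grid (default 5 min).
    tc : ndarray of float
        Core body temperature, °C, one value per timestamp.
    activity : ndarray of float, optional
        Composite activity score (sum of the three accelerometer axis
        means per epoch); unitless.
    """

    animal_id: str
    timestamps: pd.DatetimeIndex
    tc: np.ndarray
    activity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.tc = np.asarray(self.tc, dtype=float)
        if self.activity is not None:
            self.activity = np.asarray(self.activity, dtype=float)
            if len(self.activity) != len(self.tc):
                raise ValueError("activity and tc must have equal length")
        if len(self.timestamps) != len(self.tc):
            raise ValueError("timestamps and tc must have equal length")
        if len(self.timestamps) < 2:
            raise ValueError("trace needs at least two samples")
        deltas = np.diff(self.timestamps.asi8)
        if (deltas <= 0).any():
            raise ValueError("timestamps must be strictly increasing")
        if len(set(deltas)) != 1:
            bad = np.nonzero(deltas != deltas[0])[0]
            raise ValueError(
                f"non-uniform sampling grid for animal {self.animal_id!r}: "
                f"irregular gaps after sample indices {bad[:5].tolist()}"
            )

    @property
    def interval_minutes(self) -> float:
        """Sampling interval in minutes."""
        return (self.timestamps[1] - self.timestamps[0]) / pd.Timedelta(minutes=1)

    @property
    def out_of_range(self) -> np.ndarray:
        """Boolean mask of samples outside the physiological range."""
        return (self.tc < TC_RANGE[0]) | (self.tc > TC_RANGE[1])

    def __len__(self) -> int:
        return len(self.tc)


@dataclass
class BaselineTrace:
    """Centred running average ``T_s`` of a trace, on the same grid.

    ``complete`` marks samples whose averaging window was fully inside the
    trace; near the edges the window is truncated and the sample flagged.
    """

    timestamps: pd.DatetimeIndex
    ts: np.ndarray
    complete: np.ndarray

    def __len__(self) -> int:
        return len(self.ts)


@dataclass
class SIHMetrics:
    """Quantification of one stress-induced hyperthermia event.

    ``auc`` is the signed sum of ``T_c - T_s`` over the window multiplied by
    the sampling interval in minutes (°C·min); ``amplitude`` is the maximum
    of ``T_c - T_s`` over the same samples (°C).  ``duration_minutes`` is an
    interpretation, not part of the core definition: the time from window
    start until the deviation first returns to or below zero, censored at
    the window length.
    """

    event_label: str
    window_start: pd.Timestamp
    window_minutes: float
    auc: float
    amplitude: float
    duration_minutes: float
    n_samples: int


@dataclass
class CosinorFit:
    """Single-day cosinor fit: ``tc(t) = mesor + amplitude·cos(ω(t − acrophase))``.

    ``acrophase`` is the clock time (decimal hours in [0, 24)) at which the
    fitted cosine peaks; it is NaN when the fitted amplitude is zero
    (degenerate, direction undefined) or the fit is flagged.
    """

    animal_id: str
    day_start: pd.Timestamp
    mesor: float
    amplitude: float
    acrophase_hours: float
    cosinor_min: float
    cosinor_max: float
    rss: float
    n_samples: int
    flagged: bool = False
    flag_reason: str = ""


@dataclass
class PeriodSummary:
    """Mean daily cosinor parameters over (normally) three consecutive days."""

    animal_id: str
    period_label: str
    day_starts: list = field(default_factory=list)
    mesor: float = math.nan
    amplitude: float = math.nan
    cosinor_min: float = math.nan
    cosinor_max: float = math.nan
    n_days: int = 0
    flagged: bool = False
    flag_reason: str = ""


def running_baseline(
    trace: TemperatureTrace, half_window: pd.Timedelta = pd.Timedelta(hours=6)
) -> BaselineTrace:
    """Centred running average of ``T_c`` over ±``half_window``.

    The window is inclusive of the centre sample, so at 5-min spacing the
    interior window holds 145 samples (72 before, the sample itself, 72
    after).  At the trace edges the window is truncated to the available
    samples and the output flagged incomplete there.

    Parameters
    ----------
    trace : TemperatureTrace
    half_window : pandas.Timedelta
        Half-width of the averaging window; must be a multiple of the
        sampling interval.  Default 6 h, giving the 12-h window used for
        SIH baselining.
    """
    half_window = pd.Timedelta(half_window)
    interval = pd.Timedelta(minutes=trace.interval_minutes)
    k, rem = divmod(half_window, interval)
    if rem != pd.Timedelta(0):
        raise ValueError(
            f"half_window {half_window} is not a multiple of the "
            f"sampling interval {interval}"
        )
    k = int(k)
    s = pd.Series(trace.tc)
    ts = s.rolling(window=2 * k + 1, center=True, min_periods=1).mean().to_numpy()
    n = len(s)
    idx = np.arange(n)
    complete = (idx >= k) & (idx <= n - 1 - k)
    return BaselineTrace(timestamps=trace.timestamps, ts=ts, complete=complete)


def sih_metrics(
    trace: TemperatureTrace,
    baseline: BaselineTrace,
    start: pd.Timestamp,
    window_minutes: float = 50.0,
    event_label: str = "",
    require_complete_baseline: bool = True,
) -> SIHMetrics:
    """Quantify one SIH event over ``[start, start + window_minutes)``.

    With the default 50-min window and 5-min sampling the window holds
    exactly 10 samples, and multiplying their summed deviation by the 5-min
    interval converts the sum to °C·min.  The AUC keeps its sign —
    deviations below baseline subtract.

    Raises
    ------
    ValueError
        If the window extends beyond the trace (the message names the
        event), or if any window sample has an edge-truncated baseline and
        ``require_complete_baseline`` is set.
    """
    start = pd.Timestamp(start)
    if len(baseline) != len(trace):
        raise ValueError("baseline and trace are not on the same grid")
    end = start + pd.Timedelta(minutes=window_minutes)
    mask = (trace.timestamps >= start) & (trace.timestamps < end)
    expected = int(round(window_minutes / trace.interval_minutes))
    if start < trace.timestamps[0] or end > trace.timestamps[-1] + pd.Timedelta(
        minutes=trace.interval_minutes
    ) or mask.sum() != expected:
        raise ValueError(
            f"SIH window for event {event_label!r} "
            f"([{start}, {end})) extends beyond the trace"
        )
    if require_complete_baseline and not baseline.complete[mask].all():
        raise ValueError(
            f"SIH window for event {event_label!r} overlaps samples with an "
            "edge-truncated baseline window"
        )
    d = trace.tc[mask] - baseline.ts[mask]
    auc = float(trace.interval_minutes * d.sum())
    amplitude = float(d.max())
    # interpreted quantity: time from window start until the deviation first
    # returns to or below baseline after its onset (first positive sample);
    # censored at the window length, zero if the deviation never turns positive
    pos = np.nonzero(d > 0.0)[0]
    if pos.size == 0:
        duration = 0.0
    else:
        below = np.nonzero(d[pos[0] :] <= 0.0)[0]
        duration = (
            float((pos[0] + below[0]) * trace.interval_minutes)
            if below.size
            else float(window_minutes)
        )
    return SIHMetrics(
        event_label=event_label,
        window_start=start,
        window_minutes=float(window_minutes),
        auc=auc,
        amplitude=amplitude,
        duration_minutes=duration,
        n_samples=int(mask.sum()),
    )


def _flagged_fit(animal_id: str, day_start: pd.Timestamp, n: int, reason: str) -> CosinorFit:
    return CosinorFit(
        animal_id=animal_id,
        day_start=day_start,
        mesor=math.nan,
        amplitude=math.nan,
        acrophase_hours=math.nan,
        cosinor_min=math.nan,
        cosinor_max=math.nan,
        rss=math.nan,
        n_samples=n,
        flagged=True,
        flag_reason=reason,
    )


def cosinor_fit_day(
    trace: TemperatureTrace,
    day_start: pd.Timestamp,
    period_hours: float = 24.0,
    min_coverage: float = 0.8,
) -> CosinorFit:
    """Fit a fixed-period cosinor to one civil day of data.

    Solves the linear least-squares problem
    ``tc(t) = M + β·cos(ωt) + γ·sin(ωt)`` with ``ω = 2π/period`` over the
    samples in ``[day_start, day_start + period)``; then
    ``amplitude = sqrt(β² + γ²)`` and the acrophase is the clock time at
    which the fitted cosine attains its maximum.  The period is fixed, not
    estimated, so the problem is linear and the solution exact.

    A fit is flagged (and later excluded from period summaries) when fewer
    than 3 samples are available, the design is rank deficient, or the day
    holds less than ``min_coverage`` of its expected samples.
    """
    day_start = pd.Timestamp(day_start)
    end = day_start + pd.Timedelta(hours=period_hours)
    mask = (trace.timestamps >= day_start) & (trace.timestamps < end)
    n = int(mask.sum())
    if n < 3:
        return _flagged_fit(trace.animal_id, day_start, n, "fewer than 3 samples")
    t_hours = (
        (trace.timestamps[mask] - day_start) / pd.Timedelta(hours=1)
    ).to_numpy(dtype=float)
    y = trace.tc[mask]
    omega = 2.0 * math.pi / period_hours
    X = np.column_stack(
        [np.ones_like(t_hours), np.cos(omega * t_hours), np.sin(omega * t_hours)]
    )
    if np.linalg.matrix_rank(X) < 3:
        return _flagged_fit(trace.animal_id, day_start, n, "rank-deficient design")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    mesor, beta, gamma = coef
    amplitude = math.hypot(beta, gamma)
    resid = y - X @ coef
    rss = float(resid @ resid)
    if amplitude > 1e-12 * max(1.0, abs(mesor)):
        # fitted curve = M + A·cos(ωt − φ) with φ = atan2(γ, β); peak at ωt = φ
        acrophase = (math.atan2(gamma, beta) / omega) % period_hours
    else:
        # below the numerical floor the rhythm direction is undefined
        amplitude = 0.0
        acrophase = math.nan
    expected = int(round(period_hours * 60.0 / trace.interval_minutes))
    flagged = n < min_coverage * expected
    return CosinorFit(
        animal_id=trace.animal_id,
        day_start=day_start,
        mesor=float(mesor),
        amplitude=float(amplitude),
        acrophase_hours=float(acrophase),
        cosinor_min=float(mesor - amplitude),
        cosinor_max=float(mesor + amplitude),
        rss=rss,
        n_samples=n,
        flagged=flagged,
        flag_reason="low coverage" if flagged else "",
    )


def cosinor_series(trace: TemperatureTrace, period_hours: float = 24.0) -> list[CosinorFit]:
    """Fit one cosinor per complete midnight-to-midnight day of the trace.

    Partial first and last days are skipped; a day counts as complete when
    every one of its sample slots lies within the trace span (flagging of
    days with missing samples is handled per-day by the fit).
    """
    interval = pd.Timedelta(minutes=trace.interval_minutes)
    first = trace.timestamps[0].normalize()
    if first < trace.timestamps[0]:
        first += pd.Timedelta(days=1)
    fits: list[CosinorFit] = []
    day = first
    # the day's last sample slot is day + 24 h - interval
    while day + pd.Timedelta(hours=period_hours) - interval <= trace.timestamps[-1]:
        fits.append(cosinor_fit_day(trace, day, period_hours=period_hours))
        day += pd.Timedelta(days=1)
    return fits


def summarise_periods(
    fits: list[CosinorFit],
    period_specs: dict[str, list[pd.Timestamp]],
) -> list[PeriodSummary]:
    """Average daily cosinor fits over labelled multi-day periods.

    ``period_specs`` maps each period label (e.g. ``"P1"``..``"P5"``) to the
    day starts (normally three consecutive midnights) whose fits are to be
    averaged.  Averaging is per animal.  A summary referencing a missing or
    flagged day is itself flagged with the reason, never silently averaged
    over fewer days.
    """
    by_animal: dict[str, dict[pd.Timestamp, CosinorFit]] = {}
    for f in fits:
        by_animal.setdefault(f.animal_id, {})[pd.Timestamp(f.day_start)] = f
    out: list[PeriodSummary] = []
    for animal_id, days in sorted(by_animal.items()):
        for label, day_starts in period_specs.items():
            day_starts = [pd.Timestamp(d) for d in day_starts]
            missing = [d for d in day_starts if d not in days]
            flagged_days = [
                d for d in day_starts if d in days and days[d].flagged
            ]
            if missing or flagged_days:
                reasons = []
                if missing:
                    reasons.append(f"missing days {[str(d) for d in missing]}")
                if flagged_days:
                    reasons.append(f"flagged days {[str(d) for d in flagged_days]}")
                out.append(
                    PeriodSummary(
                        animal_id=animal_id,
                        period_label=label,
                        day_starts=day_starts,
                        n_days=len(day_starts) - len(missing),
                        flagged=True,
                        flag_reason="; ".join(reasons),
                    )
                )
                continue
            sel = [days[d] for d in day_starts]
            out.append(
                PeriodSummary(
                    animal_id=animal_id,
                    period_label=label,
                    day_starts=day_starts,
                    mesor=float(np.mean([f.mesor for f in sel])),
                    amplitude=float(np.mean([f.amplitude for f in sel])),
                    cosinor_min=float(np.mean([f.cosinor_min for f in sel])),
                    cosinor_max=float(np.mean([f.cosinor_max for f in sel])),
                    n_days=len(sel),
                )
            )
    return out
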