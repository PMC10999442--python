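"""Seeded synthetic cohort generator.

Emulates the data layout of a temperament study on intra-abdominally
logged sheep: a cohort of animals in genotype groups, each carrying ~4
weeks of 5-min core-temperature and activity records with

* a circadian cosine component (mesor, amplitude, acrophase drawn per
  animal),
* stationary AR(1) noise on the sampling grid (logger residuals are
  autocorrelated), and
* stress-induced hyperthermia (SIH) pulses at scheduled stressor events
  (behavioural test sessions, dog exposure), with per-animal, per-event
  amplitudes drawn from group-specific distributions,

plus per-session behaviour scores (IBT agitation, arena bleats/crosses)
and blood-assay panels with configurable group effects.  Every draw is
reproducible: one global seed spawns independent per-animal substreams
keyed by a stable hash of the animal id, so adding an animal leaves all
others' data unchanged.

The ground truth of every draw (circadian parameters, per-event pulse
amplitudes) is recorded so downstream estimators can be checked against
what was actually simulated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .behaviour import AnimalRecord, AssayPanel, normalise_ibt
from .thermal import TemperatureTrace

__all__ = [
    "GroupSpec",
    "EventSpec",
    "SimConfig",
    "AnimalParams",
    "SyntheticCohort",
    "simulate_trace",
    "simulate_cohort",
    "default_config",
    "default_period_specs",
]

#: assay distributions a practitioner would call typical for adult wethers
#: (means/sds in AssayPanel units)
DEFAULT_ASSAYS = {
    "cortisol": (30.0, 10.0),  # ng/ml
    "prolactin": (200.0, 60.0),  # µIU/ml
    "dhea": (1.5, 0.5),  # ng/ml
    "bdnf": (120.0, 40.0),  # pg/ml
    "oxy_pre": (1.0, 0.3),
    "oxy_post": (1.2, 0.35),
}


@dataclass
class GroupSpec:
    """Distributional definition of one cohort group."""

    label: str
    genotype: str
    sih_amplitude_mean: float  # °C
    sih_amplitude_sd: float
    ibt_mean: float  # raw agitation units
    ibt_sd: float
    bleats_mean: float = 8.0  # arena counts are Poisson
    crosses_mean: float = 10.0
    assay_means: dict[str, float] = field(default_factory=dict)
    assay_sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for analyte, (m, s) in DEFAULT_ASSAYS.items():
            self.assay_means.setdefault(analyte, m)
            self.assay_sds.setdefault(analyte, s)
        for name in ("sih_amplitude_sd", "ibt_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s < 0 for s in self.assay_sds.values()):
            raise ValueError("assay sds must be >= 0")


@dataclass(frozen=True)
class EventSpec:
    """One scheduled stressor: label, day index, clock time, duration."""

    label: str
    day: int
    clock_time: str  # "HH:MM"
    duration_min: float = 30.0

    def start(self, origin: pd.Timestamp) -> pd.Timestamp:
        h, m = map(int, self.clock_time.split(":"))
        return origin + pd.Timedelta(days=self.day, hours=h, minutes=m)


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort simulation."""

    n_per_group: int = 9
    group_defs: list[GroupSpec] = field(default_factory=list)
    trace_days: int = 28
    sample_interval: int = 5  # minutes
    start: str = "2024-01-01"  # midnight of day 0
    mesor_mean: float = 39.2  # °C
    mesor_sd: float = 0.15
    circ_amplitude_mean: float = 0.30  # °C
    circ_amplitude_sd: float = 0.05
    acrophase_mean: float = 18.0  # h, evening peak
    acrophase_sd: float = 1.0
    noise_sd: float = 0.05  # °C, stationary AR(1) marginal sd
    noise_ar1: float = 0.8
    pulse_rise_min: float = 10.0
    pulse_half_life_min: float = 20.0
    event_schedule: list[EventSpec] = field(default_factory=list)
    live_weight_mean: float = 60.0  # kg, adult Merino wethers
    live_weight_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for name in (
            "mesor_sd", "circ_amplitude_sd", "acrophase_sd", "noise_sd",
            "live_weight_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must be in [0, 1)")
        if 1440 % self.sample_interval != 0:
            raise ValueError("sample_interval must divide 1440 minutes")
        origin = pd.Timestamp(self.start)
        span_end = origin + pd.Timedelta(days=self.trace_days)
        for ev in self.event_schedule:
            s = ev.start(origin)
            if not (origin <= s and s + pd.Timedelta(minutes=ev.duration_min) <= span_end):
                raise ValueError(
                    f"event {ev.label!r} (day {ev.day} {ev.clock_time}) falls "
                    "outside the simulated span"
                )

    @property
    def origin(self) -> pd.Timestamp:
        return pd.Timestamp(self.start)


@dataclass
class AnimalParams:
    """Ground-truth generative parameters for one animal's trace."""

    animal_id: str
    mesor: float
    circ_amplitude: float
    acrophase_hours: float
    noise_sd: float
    noise_ar1: float
    sih_amplitudes: dict[str, float] = field(default_factory=dict)  # event → °C
    pulse_rise_min: float = 10.0
    pulse_half_life_min: float = 20.0


@dataclass
class SyntheticCohort:
    """Everything one simulation produced, with its ground truth."""

    config: SimConfig
    traces: list[TemperatureTrace]
    animals: list[AnimalRecord]
    assays: list[AssayPanel]
    truth: pd.DataFrame  # one row per animal

    def __post_init__(self) -> None:
        trace_ids = {t.animal_id for t in self.traces}
        animal_ids = {a.animal_id for a in self.animals}
        if trace_ids != animal_ids or set(self.truth["animal_id"]) != animal_ids:
            raise ValueError("traces, animals and truth must cover the same ids")


def _animal_rng(seed: int, animal_id: str) -> np.random.Generator:
    # stable across processes: CRC32 of the id, not Python's salted hash()
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(animal_id.encode())])
    )


def _pulse_profile(
    minutes_since: np.ndarray, amplitude: float, duration: float,
    rise: float, half_life: float,
) -> np.ndarray:
    """Pulse: linear rise, plateau for the event duration, exponential decay."""
    y = np.zeros_like(minutes_since, dtype=float)
    m = minutes_since
    if rise > 0:
        in_rise = (m >= 0) & (m < rise)
        y[in_rise] = amplitude * m[in_rise] / rise
    plateau_end = rise + duration
    in_plateau = (m >= rise) & (m <= plateau_end)
    y[in_plateau] = amplitude
    in_decay = m > plateau_end
    if half_life > 0:
        y[in_decay] = amplitude * 0.5 ** ((m[in_decay] - plateau_end) / half_life)
    return y


def simulate_trace(
    params: AnimalParams,
    schedule: list[EventSpec],
    *,
    origin: pd.Timestamp,
    days: int,
    sample_interval: int = 5,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> TemperatureTrace:
    """Simulate one animal's core-temperature and activity trace.

    ``T_c(t) = mesor + A·cos(2π(t − acrophase)/24 h) + Σ pulses + AR(1)``,
    sampled on a strict grid starting at midnight of day 0.  The AR(1)
    noise is stationary (marginal sd ``noise_sd``, lag-1 correlation
    ``noise_ar1``); each pulse rises linearly over ``pulse_rise_min`` to
    its event's SIH amplitude, holds for the event duration, then decays
    exponentially with half-life ``pulse_half_life_min``.

    The same ``seed`` (or generator state) always yields a bit-identical
    trace.
    """
    origin = pd.Timestamp(origin)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = days * 1440 // sample_interval
    timestamps = pd.date_range(origin, periods=n, freq=f"{sample_interval}min")
    t_hours = np.arange(n) * sample_interval / 60.0
    tc = params.mesor + params.circ_amplitude * np.cos(
        2.0 * np.pi * (t_hours - params.acrophase_hours) / 24.0
    )
    span_end = origin + pd.Timedelta(days=days)
    for ev in schedule:
        start = ev.start(origin)
        if not (origin <= start and start + pd.Timedelta(minutes=ev.duration_min) <= span_end):
            raise ValueError(
                f"event {ev.label!r} (day {ev.day} {ev.clock_time}) falls "
                "outside the simulated span"
            )
        amp = params.sih_amplitudes.get(ev.label, 0.0)
        minutes_since = (timestamps - start) / pd.Timedelta(minutes=1)
        tc = tc + _pulse_profile(
            np.asarray(minutes_since, dtype=float), amp, ev.duration_min,
            params.pulse_rise_min, params.pulse_half_life_min,
        )
    if params.noise_sd > 0:
        rho = params.noise_ar1
        # stationary AR(1): first innovation at the marginal sd, the rest
        # scaled so the marginal sd stays noise_sd at every lag
        innov_sd = params.noise_sd * np.sqrt(1.0 - rho**2)
        e = rng.normal(0.0, innov_sd, size=n)
        e[0] = rng.normal(0.0, params.noise_sd)
        tc = tc + lfilter([1.0], [1.0, -rho], e)
    # activity: diurnal (higher when warm phase) non-negative noise
    activity = np.clip(
        5.0
        + 4.0 * np.cos(2.0 * np.pi * (t_hours - params.acrophase_hours) / 24.0)
        + rng.normal(0.0, 1.0, size=n),
        0.0,
        None,
    )
    return TemperatureTrace(
        animal_id=params.animal_id, timestamps=timestamps, tc=tc, activity=activity
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw redrawn until non-negative (concentrations, weights)."""
    if sd == 0:
        return max(mean, 0.0)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    raise RuntimeError("truncated normal failed after 1000 redraws")


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Simulate a full cohort: traces, behaviour scores, assays, truth table.

    Animal ids are ``"<group>-<k>"``; each animal's draws come from its own
    substream (seeded by the global seed and a CRC32 of the id) so the
    cohort is reproducible draw-for-draw and insensitive to animal order.
    """
    if not config.group_defs:
        raise ValueError("config.group_defs must not be empty")
    traces: list[TemperatureTrace] = []
    animals: list[AnimalRecord] = []
    assays: list[AssayPanel] = []
    truth_rows: list[dict] = []
    for group in config.group_defs:
        for k in range(1, config.n_per_group + 1):
            animal_id = f"{group.label}-{k:02d}"
            rng = _animal_rng(config.seed, animal_id)
            params = AnimalParams(
                animal_id=animal_id,
                mesor=float(rng.normal(config.mesor_mean, config.mesor_sd)),
                circ_amplitude=_truncated_normal(
                    rng, config.circ_amplitude_mean, config.circ_amplitude_sd
                ),
                acrophase_hours=float(
                    rng.normal(config.acrophase_mean, config.acrophase_sd) % 24.0
                ),
                noise_sd=config.noise_sd,
                noise_ar1=config.noise_ar1,
                sih_amplitudes={
                    ev.label: _truncated_normal(
                        rng, group.sih_amplitude_mean, group.sih_amplitude_sd
                    )
                    for ev in config.event_schedule
                },
                pulse_rise_min=config.pulse_rise_min,
                pulse_half_life_min=config.pulse_half_life_min,
            )
            trace = simulate_trace(
                params,
                config.event_schedule,
                origin=config.origin,
                days=config.trace_days,
                sample_interval=config.sample_interval,
                rng=rng,
            )
            traces.append(trace)
            live_weight = _truncated_normal(
                rng, config.live_weight_mean, config.live_weight_sd
            )
            raw_ibt = {
                s: _truncated_normal(rng, group.ibt_mean, group.ibt_sd)
                for s in ("S1", "S2")
            }
            record = AnimalRecord(
                animal_id=animal_id,
                genotype=group.genotype,
                live_weight=live_weight,
                raw_ibt=raw_ibt,
                ibt_lwt={
                    s: normalise_ibt(v, live_weight) for s, v in raw_ibt.items()
                },
                bleats={
                    s: int(rng.poisson(group.bleats_mean)) for s in ("S1", "S2")
                },
                crosses={
                    s: int(rng.poisson(group.crosses_mean)) for s in ("S1", "S2")
                },
                group=group.label,
            )
            animals.append(record)
            for s in ("S1", "S2"):
                assays.append(
                    AssayPanel(
                        animal_id=animal_id,
                        session=s,
                        **{
                            a: _truncated_normal(
                                rng, group.assay_means[a], group.assay_sds[a]
                            )
                            for a in DEFAULT_ASSAYS
                        },
                    )
                )
            row = {
                "animal_id": animal_id,
                "group": group.label,
                "genotype": group.genotype,
                "mesor": params.mesor,
                "circ_amplitude": params.circ_amplitude,
                "acrophase_hours": params.acrophase_hours,
                "live_weight": live_weight,
            }
            for ev_label, amp in params.sih_amplitudes.items():
                row[f"sih_amplitude_{ev_label}"] = amp
            truth_rows.append(row)
    return SyntheticCohort(
        config=config,
        traces=traces,
        animals=animals,
        assays=assays,
        truth=pd.DataFrame(truth_rows),
    )


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-style default simulation: 2 groups × 9 sheep, 28 days.

    A calm (A/A, low-agitation, small SIH) and a nervous (G/G,
    high-agitation, large SIH) group; behavioural test sessions S1 (day 3)
    and S2 (day 17, two weeks later) at 10:00, and a dog exposure on the
    afternoon of the S2 day.
    """
    groups = overrides.pop(
        "group_defs",
        [
            GroupSpec(
                label="calm", genotype="A/A",
                sih_amplitude_mean=0.3, sih_amplitude_sd=0.08,
                ibt_mean=40.0, ibt_sd=12.0,
                bleats_mean=6.0, crosses_mean=9.0,
            ),
            GroupSpec(
                label="nervous", genotype="G/G",
                sih_amplitude_mean=0.9, sih_amplitude_sd=0.12,
                ibt_mean=80.0, ibt_sd=15.0,
                bleats_mean=10.0, crosses_mean=11.0,
            ),
        ],
    )
    schedule = overrides.pop(
        "event_schedule",
        [
            EventSpec("S1", day=3, clock_time="10:00", duration_min=30.0),
            EventSpec("S2", day=17, clock_time="10:00", duration_min=30.0),
            EventSpec("dog", day=17, clock_time="14:00", duration_min=20.0),
        ],
    )
    return SimConfig(
        group_defs=groups, event_schedule=schedule, seed=seed, **overrides
    )


def default_period_specs(config: SimConfig) -> dict[str, list[pd.Timestamp]]:
    """Three-day circadian-analysis periods anchored to the test sessions.

    P1 = the three days before S1, P2 = the three days after the S1 day,
    P3 = the three days before S2, P4 = the three days after the S2 day,
    P5 = the three days after P4.
    """
    events = {ev.label: ev.day for ev in config.event_schedule}
    if "S1" not in events or "S2" not in events:
        raise ValueError("period layout needs S1 and S2 in the event schedule")
    origin = config.origin
    s1, s2 = events["S1"], events["S2"]
    layout = {
        "P1": range(s1 - 3, s1),
        "P2": range(s1 + 1, s1 + 4),
        "P3": range(s2 - 3, s2),
        "P4": range(s2 + 1, s2 + 4),
        "P5": range(s2 + 4, s2 + 7),
    }
    return {
        label: [origin + pd.Timedelta(days=d) for d in days]
        for label, days in layout.items()
    }
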