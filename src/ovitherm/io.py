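"""File formats, configuration and the end-to-end pipeline driver.

All tabular artefacts are plain CSV with fixed, documented headers so runs
diff cleanly; the only JSON outputs are the run manifest and the stats
summary.  The trace format is long:

    animal_id,timestamp,tc_celsius,activity

with ISO-8601 timestamps on a uniform grid per animal.  ``run_pipeline``
chains simulation (optional) → SIH quantification → daily cosinor fits →
period summaries → phenotype classification → factorial and mixed-model
statistics → correlation matrix, and records row counts and warnings in a
:class:`RunManifest`.  Identical config + seed reproduces every output file
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behaviour import AnimalRecord, AssayPanel, classify_phenotype
from .stats import (
    ModelSpec,
    correlation_matrix,
    fit_factorial,
    fit_mixed_periods,
)
from .synthetic import (
    EventSpec,
    GroupSpec,
    SimConfig,
    SyntheticCohort,
    default_period_specs,
    simulate_cohort,
)
from .thermal import (
    TemperatureTrace,
    cosinor_series,
    running_baseline,
    sih_metrics,
    summarise_periods,
)

__all__ = [
    "TRACE_HEADER",
    "PipelineConfig",
    "RunManifest",
    "read_trace_csv",
    "write_trace_csv",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_assay_csv",
    "read_assay_csv",
    "read_event_csv",
    "write_event_csv",
    "read_period_csv",
    "write_period_csv",
    "sim_config_from_dict",
    "sim_config_to_dict",
    "run_pipeline",
]

log = logging.getLogger("ovitherm")

TRACE_HEADER = ["animal_id", "timestamp", "tc_celsius", "activity"]
ASSAY_COLUMNS = ["animal_id", "session", "cortisol", "prolactin", "dhea",
                 "bdnf", "oxy_pre", "oxy_post"]


# ---------------------------------------------------------------------------
# trace CSV

def write_trace_csv(traces: list[TemperatureTrace], path) -> None:
    frames = []
    for t in traces:
        frames.append(pd.DataFrame({
            "animal_id": t.animal_id,
            "timestamp": t.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "tc_celsius": t.tc,
            "activity": t.activity if t.activity is not None else np.nan,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace_csv(path) -> list[TemperatureTrace]:
    """Read and validate a long-format trace CSV.

    The header must be exactly ``animal_id,timestamp,tc_celsius,activity``.
    Unparseable timestamps are reported with their line number; a
    non-uniform grid is rejected with the offending gap locations.  An
    empty file yields an empty list with a warning.
    """
    df = pd.read_csv(path, dtype={"animal_id": str})
    if list(df.columns) != TRACE_HEADER:
        raise ValueError(
            f"{path}: header must be {','.join(TRACE_HEADER)!r}, "
            f"got {','.join(df.columns)!r}"
        )
    if df.empty:
        warnings.warn(f"{path}: empty trace file", stacklevel=2)
        return []
    parsed = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if parsed.isna().any():
        # +2: one for the header row, one for 1-based line numbering
        lines = (df.index[parsed.isna()] + 2).tolist()
        raise ValueError(f"{path}: unparseable timestamps at lines {lines[:5]}")
    df["timestamp"] = parsed
    traces = []
    for animal_id, g in df.groupby("animal_id", sort=True):
        g = g.sort_values("timestamp")
        deltas = g["timestamp"].diff().dropna()
        if deltas.nunique() > 1:
            step = deltas.mode().iloc[0]
            gaps = g["timestamp"][deltas.ne(step).reindex(g.index, fill_value=False)]
            raise ValueError(
                f"{path}: non-uniform sampling grid for animal {animal_id!r}; "
                f"irregular gaps at {[str(x) for x in gaps[:5]]}"
            )
        activity = g["activity"].to_numpy(dtype=float)
        traces.append(TemperatureTrace(
            animal_id=str(animal_id),
            timestamps=pd.DatetimeIndex(g["timestamp"]),
            tc=g["tc_celsius"].to_numpy(dtype=float),
            activity=None if np.isnan(activity).all() else activity,
        ))
    return traces


# ---------------------------------------------------------------------------
# cohort / assay / schedule CSV

def cohort_frame(animals: list[AnimalRecord]) -> pd.DataFrame:
    rows = []
    for a in animals:
        row = {"animal_id": a.animal_id, "group": a.group,
               "genotype": a.genotype, "live_weight": a.live_weight,
               "phenotype": a.phenotype}
        for s in ("S1", "S2"):
            row[f"raw_ibt_{s}"] = a.raw_ibt.get(s, np.nan)
            row[f"ibt_lwt_{s}"] = a.ibt_lwt.get(s, np.nan)
            row[f"bleats_{s}"] = a.bleats.get(s, np.nan)
            row[f"crosses_{s}"] = a.crosses.get(s, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(animals: list[AnimalRecord], path) -> None:
    cohort_frame(animals).to_csv(path, index=False)


def read_cohort_csv(path) -> list[AnimalRecord]:
    df = pd.read_csv(path, dtype={"animal_id": str})
    animals = []
    for _, r in df.iterrows():
        animals.append(AnimalRecord(
            animal_id=r["animal_id"],
            genotype=r["genotype"],
            live_weight=float(r["live_weight"]),
            raw_ibt={s: float(r[f"raw_ibt_{s}"]) for s in ("S1", "S2")},
            ibt_lwt={s: float(r[f"ibt_lwt_{s}"]) for s in ("S1", "S2")},
            bleats={s: int(r[f"bleats_{s}"]) for s in ("S1", "S2")},
            crosses={s: int(r[f"crosses_{s}"]) for s in ("S1", "S2")},
            phenotype=r.get("phenotype", "unassigned"),
            group=r.get("group", ""),
        ))
    return animals


def write_assay_csv(assays: list[AssayPanel], path) -> None:
    pd.DataFrame([
        {c: getattr(a, c) for c in ASSAY_COLUMNS} for a in assays
    ]).to_csv(path, index=False)


def read_assay_csv(path) -> list[AssayPanel]:
    df = pd.read_csv(path, dtype={"animal_id": str})
    return [AssayPanel(**{c: r[c] for c in ASSAY_COLUMNS})
            for _, r in df.iterrows()]


def write_event_csv(events: list[EventSpec], path) -> None:
    pd.DataFrame([dataclasses.asdict(e) for e in events]).to_csv(path, index=False)


def read_event_csv(path) -> list[EventSpec]:
    df = pd.read_csv(path)
    return [EventSpec(label=str(r["label"]), day=int(r["day"]),
                      clock_time=str(r["clock_time"]),
                      duration_min=float(r["duration_min"]))
            for _, r in df.iterrows()]


def write_period_csv(specs: dict[str, list[pd.Timestamp]], path) -> None:
    rows = [{"period_label": label, "day_start": d.strftime("%Y-%m-%dT%H:%M:%S")}
            for label, days in specs.items() for d in days]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_period_csv(path) -> dict[str, list[pd.Timestamp]]:
    df = pd.read_csv(path)
    specs: dict[str, list[pd.Timestamp]] = {}
    for _, r in df.iterrows():
        specs.setdefault(str(r["period_label"]), []).append(
            pd.Timestamp(r["day_start"]))
    return specs


# ---------------------------------------------------------------------------
# configuration

def sim_config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["group_defs"] = [dataclasses.asdict(g) for g in config.group_defs]
    d["event_schedule"] = [dataclasses.asdict(e) for e in config.event_schedule]
    return d


def sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["group_defs"] = [GroupSpec(**g) for g in d.get("group_defs", [])]
    d["event_schedule"] = [EventSpec(**e) for e in d.get("event_schedule", [])]
    return SimConfig(**d)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    Either ``sim`` (simulate a cohort) or the three input paths
    (``traces_csv``, ``cohort_csv``, ``assays_csv``) must be given.  The
    event schedule and period layout default to the simulation's own when
    simulating; otherwise they come from CSV files.
    """

    output_dir: str
    sim: SimConfig | None = None
    traces_csv: str | None = None
    cohort_csv: str | None = None
    assays_csv: str | None = None
    events_csv: str | None = None
    periods_csv: str | None = None
    sih_window_minutes: float = 50.0
    baseline_half_window_hours: float = 6.0
    n_low: int | None = None
    n_high: int | None = None
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        # where the outputs land does not change what they contain
        d.pop("output_dir", None)
        d.pop("log_level", None)
        if self.sim is not None:
            d["sim"] = sim_config_to_dict(self.sim)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    stage_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    excluded: list[dict] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# pipeline

def _sih_table(traces, events, origin, half_window_hours, window_minutes,
               manifest) -> pd.DataFrame:
    rows = []
    hw = pd.Timedelta(hours=half_window_hours)
    for trace in traces:
        baseline = running_baseline(trace, half_window=hw)
        for ev in events:
            start = ev.start(origin)
            try:
                m = sih_metrics(trace, baseline, start,
                                window_minutes=window_minutes,
                                event_label=ev.label)
            except ValueError as exc:
                manifest.excluded.append(
                    {"stage": "sih", "animal_id": trace.animal_id,
                     "event": ev.label, "reason": str(exc)})
                continue
            rows.append({"animal_id": trace.animal_id, "event": ev.label,
                         "window_start": str(m.window_start),
                         "auc_cmin": m.auc, "amplitude_c": m.amplitude,
                         "duration_min": m.duration_minutes})
    return pd.DataFrame(rows)


def _cosinor_tables(traces, period_specs, manifest):
    fits = []
    for trace in traces:
        fits.extend(cosinor_series(trace))
    daily = pd.DataFrame([{
        "animal_id": f.animal_id, "day_start": str(f.day_start),
        "mesor": f.mesor, "amplitude": f.amplitude,
        "acrophase_hours": f.acrophase_hours,
        "cosinor_min": f.cosinor_min, "cosinor_max": f.cosinor_max,
        "rss": f.rss, "n_samples": f.n_samples, "flagged": f.flagged,
        "flag_reason": f.flag_reason,
    } for f in fits])
    for f in fits:
        if f.flagged:
            manifest.warnings.append(
                f"cosinor: {f.animal_id} day {f.day_start} flagged "
                f"({f.flag_reason})")
    summaries = summarise_periods(fits, period_specs) if period_specs else []
    periods = pd.DataFrame([{
        "animal_id": s.animal_id, "period": s.period_label,
        "mesor": s.mesor, "amplitude": s.amplitude,
        "cosinor_min": s.cosinor_min, "cosinor_max": s.cosinor_max,
        "n_days": s.n_days, "flagged": s.flagged,
        "flag_reason": s.flag_reason,
    } for s in summaries])
    return daily, periods


def _analysis_table(animals, sih, assays_df) -> pd.DataFrame:
    """Per-animal table for correlations: session-1 measures + SIH AUC."""
    cohort = cohort_frame(animals)
    base = cohort[["animal_id", "ibt_lwt_S1", "crosses_S1"]].copy()
    s1 = assays_df[assays_df["session"] == "S1"].drop(columns=["session"])
    base = base.merge(s1, on="animal_id", how="left")
    if not sih.empty:
        for ev in sih["event"].unique():
            col = sih[sih["event"] == ev][["animal_id", "auc_cmin"]]
            col = col.rename(columns={"auc_cmin": f"sih_auc_{ev}"})
            base = base.merge(col, on="animal_id", how="left")
    return base


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis and write all artefacts to ``output_dir``.

    Stages: (1) simulate or load; (2) SIH metrics per animal × event;
    (3) daily cosinor fits and period summaries; (4) live-weight-normalised
    IBT scoring and low/high responder classification; (5) factorial
    group-comparison models, mixed-model period comparisons and the
    correlation matrix.  Any stage failure aborts with the stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest = RunManifest(config_hash=config.config_hash(),
                           seed=config.seed, version=__version__)

    def emit(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        manifest.outputs.append(name)

    # stage 1: simulate or load -------------------------------------------
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        cohort: SyntheticCohort = simulate_cohort(sim)
        traces, animals, assays = cohort.traces, cohort.animals, cohort.assays
        events = sim.event_schedule
        origin = sim.origin
        period_specs = (read_period_csv(config.periods_csv)
                        if config.periods_csv else default_period_specs(sim))
        write_trace_csv(traces, out / "traces.csv")
        manifest.outputs.append("traces.csv")
        emit(cohort.truth, "truth.csv")
    elif config.traces_csv and config.cohort_csv and config.assays_csv:
        traces = read_trace_csv(config.traces_csv)
        animals = read_cohort_csv(config.cohort_csv)
        assays = read_assay_csv(config.assays_csv)
        if not config.events_csv:
            raise ValueError("stage load: events_csv required when not simulating")
        events = read_event_csv(config.events_csv)
        origin = min(t.timestamps[0] for t in traces).normalize()
        period_specs = (read_period_csv(config.periods_csv)
                        if config.periods_csv else {})
    else:
        raise ValueError("stage load: need either sim config or input CSV paths")
    log.info("stage load: %d animals, %d traces", len(animals), len(traces))
    manifest.stage_counts["animals"] = len(animals)
    manifest.stage_counts["traces"] = len(traces)

    # stage 2: SIH ---------------------------------------------------------
    sih = _sih_table(traces, events, origin, config.baseline_half_window_hours,
                     config.sih_window_minutes, manifest)
    emit(sih, "sih.csv")
    manifest.stage_counts["sih_events"] = len(sih)

    # stage 3: cosinor -----------------------------------------------------
    daily, periods = _cosinor_tables(traces, period_specs, manifest)
    emit(daily, "cosinor_daily.csv")
    emit(periods, "cosinor_periods.csv")
    manifest.stage_counts["cosinor_days"] = len(daily)
    manifest.stage_counts["cosinor_periods"] = len(periods)

    # stage 4: phenotype classification -----------------------------------
    scores = {a.animal_id: a.ibt_lwt["S1"] for a in animals}
    n_low = config.n_low if config.n_low is not None else len(animals) // 2
    n_high = config.n_high if config.n_high is not None else len(animals) // 2
    result = classify_phenotype(scores, n_low=n_low, n_high=n_high)
    for a in animals:
        a.phenotype = result.labels[a.animal_id]
    if result.ties:
        manifest.warnings.append(
            f"classify: score ties at class boundary for {result.ties}")
    emit(cohort_frame(animals), "cohort.csv")
    manifest.stage_counts["classified"] = sum(
        1 for a in animals if a.phenotype != "unassigned")
    manifest.excluded.extend(
        {"stage": "classify", "animal_id": a.animal_id,
         "reason": "between classification quantiles"}
        for a in animals if a.phenotype == "unassigned")

    # stage 5: statistics --------------------------------------------------
    assays_df = pd.DataFrame([{c: getattr(a, c) for c in ASSAY_COLUMNS}
                              for a in assays])
    emit(assays_df, "assays.csv")
    summary: dict = {}
    lookup = {a.animal_id: a for a in animals}
    if not sih.empty:
        stats_in = sih.copy()
        stats_in["group"] = stats_in["animal_id"].map(
            lambda i: lookup[i].group or lookup[i].genotype)
        stats_in["phenotype"] = stats_in["animal_id"].map(
            lambda i: lookup[i].phenotype)
        term_rows, pair_rows = [], []
        for outcome in ("auc_cmin", "amplitude_c", "duration_min"):
            for factor in ("group", "phenotype"):
                frame = stats_in[stats_in[factor] != "unassigned"]
                if frame[factor].nunique() < 2 or frame["event"].nunique() < 1:
                    continue
                spec = ModelSpec(outcome=outcome,
                                 fixed_factors=[factor, "event"],
                                 transform="none")
                try:
                    res = fit_factorial(spec, frame)
                except ValueError as exc:
                    manifest.warnings.append(f"stats sih {outcome}/{factor}: {exc}")
                    continue
                t = res.terms.assign(outcome=outcome, grouping=factor)
                p = res.pairwise.assign(outcome=outcome, grouping=factor)
                term_rows.append(t)
                pair_rows.append(p)
        if term_rows:
            emit(pd.concat(term_rows, ignore_index=True), "sih_terms.csv")
            emit(pd.concat(pair_rows, ignore_index=True), "sih_pairwise.csv")
    # assays: group × session factorial per analyte, name-driven transform
    assay_terms = []
    adata = assays_df.copy()
    adata["group"] = adata["animal_id"].map(
        lambda i: lookup[i].group or lookup[i].genotype)
    for analyte in ("cortisol", "prolactin", "dhea", "bdnf",
                    "oxy_pre", "oxy_post"):
        spec = ModelSpec(outcome=analyte, fixed_factors=["group", "session"])
        try:
            res = fit_factorial(spec, adata)
        except ValueError as exc:
            manifest.warnings.append(f"stats assay {analyte}: {exc}")
            continue
        assay_terms.append(res.terms.assign(outcome=analyte,
                                            transform=res.transformation))
    if assay_terms:
        emit(pd.concat(assay_terms, ignore_index=True), "assay_terms.csv")
    # circadian periods: mixed model per cosinor parameter
    if not periods.empty:
        ok = periods[~periods["flagged"]]
        mixed_terms, mixed_pairs = [], []
        for param in ("amplitude", "mesor", "cosinor_min", "cosinor_max"):
            frame = ok[["animal_id", "period", param]].rename(
                columns={param: "value"})
            if frame["period"].nunique() < 2:
                continue
            res = fit_mixed_periods(frame)
            mixed_terms.append(res.terms.assign(outcome=param))
            mixed_pairs.append(res.pairwise.assign(outcome=param))
            manifest.warnings.extend(
                f"mixed {param}: {w}" for w in res.warnings)
        if mixed_terms:
            emit(pd.concat(mixed_terms, ignore_index=True), "crt_terms.csv")
            emit(pd.concat(mixed_pairs, ignore_index=True), "crt_pairwise.csv")
    # correlations
    table = _analysis_table(animals, sih, assays_df)
    try:
        corr = correlation_matrix(table)
        corr.r.round(10).to_csv(out / "correlations_r.csv")
        corr.p.round(10).to_csv(out / "correlations_p.csv")
        manifest.outputs.extend(["correlations_r.csv", "correlations_p.csv"])
        manifest.stage_counts["correlation_animals"] = corr.n
        manifest.excluded.extend(
            {"stage": "correlation", "animal_id": a, "reason": "missing variable"}
            for a in corr.excluded_animals)
        summary["correlation_n"] = corr.n
    except ValueError as exc:
        manifest.warnings.append(f"stats correlation: {exc}")
    summary["stage_counts"] = manifest.stage_counts
    (out / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str))
    manifest.outputs.append("run_summary.json")
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
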