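# ovitherm

Analysis toolkit for temperament studies on livestock carrying
intra-abdominal temperature loggers. It quantifies **stress-induced
hyperthermia (SIH)** — the transient rise of core body temperature after a
psychological stressor — characterises the **circadian rhythm of core
temperature (CRT)** by cosinor analysis, scores **isolation-box
temperament** normalised for live weight, and runs the group-comparison and
correlation statistics such studies report. A seeded synthetic-cohort
generator with a recorded ground truth drives the whole pipeline, so every
estimator can be validated against what was actually simulated.

Written for physiologists and biostatisticians working with 5-min
biotelemetry records (sheep, goats, cattle), but nothing in the temperature
mathematics is species-specific.

## The quantities it computes

With `T_c(t)` the logged core temperature and `T_s(t)` its centred 12-h
running average (6 h before and after each sample, 145 samples at 5-min
spacing), an SIH event starting at time `t0` is summarised over the ten
samples in `[t0, t0 + 50 min)` as

    AUC       = 5 · Σ_k (T_c,k − T_s,k)        [°C·min, signed]
    amplitude = max_k (T_c,k − T_s,k)          [°C]

The CRT is fitted per civil day (midnight to midnight) by linear least
squares with a fixed 24-h period,

    T_c(t) = M + A·cos(2π(t − φ)/24 h) + ε(t),

giving the mesor `M`, amplitude `A`, acrophase `φ` (clock time of the
fitted peak) and the cosinor minimum/maximum `M ∓ A`; daily fits are
averaged over three-day periods bracketing the test sessions (P1–P5) and
compared with linear mixed-effects models (random animal intercept,
Benjamini–Hochberg-adjusted pairwise contrasts). Isolation-box agitation
scores are normalised as `raw × 27 kg / live weight`, the cohort is split
into low/high responders on session-1 scores, and factorial linear models
(sum-to-zero coding, Type-III term tests, iterative pruning of
non-significant interactions, Bonferroni pairwise contrasts) plus Pearson
correlation matrices with listwise exclusion complete the inference layer.

## Worked example

```python
from ovitherm import (default_config, simulate_cohort,
                      running_baseline, sih_metrics)

cfg = default_config(seed=1)          # 2 groups x 9 sheep, 28 days, 5-min grid
cohort = simulate_cohort(cfg)
trace = cohort.traces[-1]             # a nervous-group animal
baseline = running_baseline(trace)    # centred 12-h running mean
event = cfg.event_schedule[0]         # behavioural test S1, day 3, 10:00
m = sih_metrics(trace, baseline, event.start(cfg.origin), event_label="S1")
print(m.auc, m.amplitude)
```

prints

```
29.11 degC·min   0.777 degC
```

for an animal whose injected pulse amplitude was 0.886 °C: the AUC is the
heat load of the stress response above baseline, and the measured amplitude
sits a little below the programmed pulse because the running mean absorbs a
small share of the pulse itself (see `docs/methods.md`). Running the
factorial layer on the full cohort
(`examples/05_group_statistics.py`) recovers the programmed 0.6 °C
group gap as a −0.509 °C calm-minus-nervous contrast with Bonferroni
p ≈ 1e-19, and the per-animal correlation between SIH AUC and the
normalised isolation-box score comes out at r = 0.70 over 18 animals.

The `examples/` directory holds one short script per capability
(simulation, SIH, cosinor, temperament scoring, statistics, full
pipeline); each prints the numbers it computes and what they mean. The
same stages are scriptable from a shell:

```sh
ovitherm run-all --seed 7 --out out/        # simulate + full analysis
ovitherm sih --traces traces.csv --events events.csv --out sih.csv
```

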