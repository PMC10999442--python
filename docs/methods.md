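# Methods

## Scope and model

The package analyses uniform-grid (default 5-min) core body temperature
records from implanted loggers together with behavioural scores and blood
assay panels, for cohort designs in which animals are grouped by genotype
and, post hoc, by temperament phenotype. Three layers sit on top of each
other: deterministic temperature mathematics (baseline, SIH, cosinor),
scoring and classification, and the inferential models. A synthetic-cohort
generator supplies data with recorded ground truth for validation.

## SIH quantification

The baseline `T_s` is the running average of `T_c` over a centred 12-h
window, inclusive of the centre sample — 72 samples either side at 5-min
spacing, 145 in the interior. Inclusion of the centre sample keeps the
window symmetric, which makes the baseline pass exactly through any
locally linear trend. At the trace edges the window is truncated to the
available samples and those baseline values are flagged incomplete; SIH
windows that touch flagged samples are rejected by default
(`require_complete_baseline=False` overrides).

An SIH event over `[t0, t0 + 50 min)` — a half-open window, so exactly
ten samples at 5-min spacing — yields

* `AUC = interval · Σ (T_c − T_s)` in °C·min. The sum is **signed**:
  excursions below baseline subtract. The multiply-by-interval convention
  makes the ten-sample sum an area on the time axis.
* `amplitude = max (T_c − T_s)` over the same ten samples.
* `duration`: an *interpreted* quantity — the time from window start until
  the deviation first returns to or below zero after its onset (first
  positive sample), censored at the window length, zero if the deviation
  never turns positive. It is reported because group analyses of SIH
  commonly include a duration term, but it has no unique definition from
  the two quantities above; treat it accordingly.

Because `T_s` averages over only 12 h, two systematic effects are inherent
to this estimator (not defects of the implementation):

1. the circadian component is attenuated, not removed — a residual of
   roughly `(1 − sinc(π/2)) ≈ 36 %` of the circadian amplitude remains in
   `T_c − T_s`, with sign depending on event clock time; it is common to
   all animals tested at the same time of day and largely cancels in group
   contrasts;
2. the pulse itself leaks into its own baseline by (pulse area)/(window
   length), attenuating measured amplitudes by ≈ 9 % for the default pulse
   shape. The generator tests assert this leakage in closed form.

## Cosinor analysis

Each civil day (midnight to midnight, timezone of the trace timestamps, no
DST handling) is fitted by ordinary least squares to
`M + β cos(ωt) + γ sin(ωt)` with `ω = 2π/24 h` fixed; amplitude is
`√(β²+γ²)`, the acrophase is `atan2(γ, β)/ω mod 24` (clock time of the
fitted maximum), and cosinor min/max are `M ∓ A`. The problem is linear,
so the solution is exact and deterministic — no iteration, no starting
values. Degenerate cases: fewer than 3 samples or a rank-deficient design
flag the fit; a fitted amplitude below `1e-12·max(1, |M|)` is reported as
zero with an undefined (NaN) acrophase; a day with less than 80 % of its
expected samples is fitted but flagged, and flagged days propagate a flag
(never a silent partial mean) into the three-day period summaries.

Partial first/last days of a record are skipped entirely rather than
fitted on a fragment.

## Period layout

The default five analysis periods are anchored to the two test sessions:
P1 = the three days before S1, P2 = the three days after the S1 day,
P3 = the three days before S2, P4 = the three days after the S2 day,
P5 = the three days after P4. Study descriptions of this design are
internally inconsistent about whether P3 precedes S2 or follows P2
directly; the period specification is an explicit input (CSV of labelled
day starts), so either layout is expressible — the default follows the
"three days before S2" reading.

## Synthetic cohort generator

Each animal's trace is `mesor + A·cos(2π(t − φ)/24) + Σ pulses + AR(1)`.
Defaults describe a two-group (calm A/A vs nervous G/G) cohort of nine
adult wethers each over 28 days: mesor 39.2 ± 0.15 °C, circadian
amplitude 0.30 ± 0.05 °C, evening acrophase 18 ± 1 h, stationary AR(1)
noise with marginal sd 0.05 °C and lag-1 correlation 0.8 (logger residuals
are strongly autocorrelated at 5-min spacing; the innovation sd is scaled
by `√(1−ρ²)` so the marginal sd stays at the configured value). Events:
test sessions on days 3 and 17 at 10:00 and a dog exposure on the S2
afternoon. SIH pulses rise linearly over 10 min to the event's amplitude,
hold for the event duration, then decay exponentially with a 20-min
half-life — a shape chosen to have a closed-form sampled area so recovery
tests can be exact; rise time and half-life are configurable, and zero
values give a rectangular pulse. Pulse amplitudes are drawn per animal and
event from group distributions (defaults 0.3 ± 0.08 °C calm vs
0.9 ± 0.12 °C nervous, a 0.6 °C gap). Concentrations, weights and scores
are normal draws redrawn until non-negative; arena counts are Poisson.

Randomness: one global seed spawns a per-animal `SeedSequence` keyed by a
CRC32 of the animal id, so cohorts are reproducible draw-for-draw and an
animal's data do not change when others are added.

What the generator does **not** emulate: ambient-temperature coupling,
rumen/drinking artefacts, logger drift or quantisation, activity-driven
thermogenesis, missing samples, or any dependence of assay values on the
temperature trace. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated noise model, not robustness
to every artefact of field data.

## Inference layer

* Transformations are selected by variable name (log for oxidative-stress
  ratios, reciprocal for prolactin, `1/√x` for DHEA) and are exactly
  invertible on their domains; domain violations are flagged and excluded
  with a report, never imputed.
* Factorial models use sum-to-zero factor coding and Type-III-style term
  F tests (each term dropped from the otherwise-full model), which keeps
  the tests well defined for unbalanced data and reduces to the classical
  orthogonal ANOVA decomposition when balanced. Interaction pruning
  removes, iteratively, the highest-order interaction with the largest
  p ≥ 0.05 and refits. Pairwise contrasts are differences of estimated
  marginal means over the full factorial grid (equal cell weights),
  t-tested on the residual df and Bonferroni-adjusted within each factor's
  family. The multivariate-looking outcome sets (AUC, amplitude, duration)
  are analysed as per-outcome univariate models; no pooled multivariate
  statistic is computed.
* Period comparisons use a linear mixed model with fixed period effects
  (treatment-coded against P1) and a random animal intercept, fitted by
  REML through statsmodels; pairwise period contrasts are Wald z tests
  with Benjamini–Hochberg adjustment. A single-animal input degenerates to
  OLS with a warning (and is rejected outright if saturated).
* Correlations are Pearson r with two-sided t p-values; animals missing
  any variable are excluded listwise so every pair shares the same n, and
  zero-variance variables are reported as undefined rather than silently
  dropped. α = 0.05 throughout.

## Numerical and design choices

* 4PL calibration curves are fitted on the log-EC50 scale with a
  deterministic multi-start over candidate Hill slopes (±1, ±2) from
  moment-based initial values; the fitted curve is canonicalised to
  `bottom < top` (swapping asymptotes and negating the slope is an exact
  reparameterisation). Inversion is closed-form; responses outside the
  open asymptote interval return NaN with a warning.
* Phenotype classification breaks score ties by stable animal-id order and
  reports the tied ids, so the arbitrariness is visible.
* Assay values below the kit detection limits (0.25 ng/ml cortisol,
  5 µIU/ml prolactin, 0.045 ng/ml DHEA, 10 pg/ml BDNF) are flagged, not
  imputed at the limit.
* All tabular outputs are plain CSV; the manifest (JSON) carries a
  config hash that excludes the output path, so runs into different
  directories with the same configuration and seed are byte-identical.

## Problem sizes in the test and acceptance runs

The shipped checks use 50 two-day traces for the brute-force oracle
comparisons, 200 single-day simulations for circadian parameter recovery,
the full 18-animal × 28-day default cohort for gap recovery, and 1000
replicates for the type-I/power calibration of the factorial layer at
n = 9 per group — sizes chosen to make the Monte-Carlo error small
relative to the tolerances being asserted while keeping a full run in the
tens of seconds.

## Known limitations

The cosinor is single-component with a fixed 24-h period (no period
estimation, no harmonics); the SIH window is fixed-length rather than
adaptive to response shape; the mixed model assumes a common residual
variance across periods; and the factorial layer's Type-III convention is
one documented choice among several defensible ones for unbalanced data.
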