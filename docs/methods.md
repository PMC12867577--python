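# Methods

This note documents the models, algorithms, defaults and design choices
behind `calokit`, in the order the pipeline applies them.

## Canonical data model

Every stage operates on a long-format table with one row per
(animal, timestamp) sample. Gas-exchange rates are normalised to ml/h on
ingestion (`ml/min` ×60, `l/h` ×1000); timestamps are timezone-naive local
clock times, since a metabolic-cage experiment runs in a single facility
clock. Duplicate (cohort, animal, timestamp) samples are rejected at
construction; negative gas values are legal in a raw frame and handled by
curation, not by the parser.

## Dialects

The five registered dialects (`tse_v1`, `clams_v1`, `sable_v1`,
`cosmed_v1`, `calr_csv`) are this package's own precisely documented text
formats, designed to mimic the structural variety of commercial exports:
a multi-line header block with key=value metadata and decimal commas
(`tse_v1`), one file per animal with the subject named in the header
(`clams_v1`), interleaved non-sample event rows (`sable_v1`), a minimal
gas-only table in l/h (`cosmed_v1`), and a single-header-row interchange
CSV (`calr_csv`, also the export target). They are not byte-compatible
with any proprietary format; the registry is a plain dict and new
`DialectSpec` entries can be registered at run time. Floats are written
with 12 significant digits, which bounds round-trip error well below the
1e-9 relative tolerance the I/O tests enforce. Dialect detection matches
the first line (exact title prefix, or the header-token set for
header-only dialects); signatures are kept disjoint by construction.

When cohorts are merged and the same animal id occurs in more than one
cohort, the id is prefixed with its cohort (`cohort:animal`) so that all
per-animal computations remain well defined.

## Metadata harmonization

Factor names and levels are unified in three ordered steps: trim +
case-fold, then a synonym dictionary (a small built-in core of
genotype/sex/diet aliases, extensible via a YAML file mapping canonical →
aliases), then explicit per-label user overrides, which always win. Every
applied rule is recorded (`exact`, `case_fold`, `synonym`,
`user_override`) in a harmonization map exported with the bundle. The
procedure is idempotent: canonical labels map to themselves. Two distinct
factors of one cohort collapsing onto a single canonical name is an error
rather than a silent merge.

Zeitgeber time is `ZT = (clock − lights_on) mod 24 h`; ZT0 is lights-on
and the dark phase starts at `(lights_off − lights_on) mod 24`. When no
photoperiod is supplied anywhere, the common vivarium default (12:12,
lights-on 07:00) is assumed with a prominent warning — visibility was
preferred over failure because many archived exports carry no photoperiod
at all.

## Curation

Checks **flag**; only explicit corrective operations remove:

- negative gas rates: flagged; deletion requires `drop_negative_gas`.
- high-frequency sampling: animals whose median interval is below
  `min_sample_interval`.
- complete days: a day (zeitgeber by default when a photoperiod is known,
  calendar otherwise) is complete when it holds at least
  `complete_day_min_fraction` (default 0.95, tolerating isolated dropped
  samples) of the expected samples, expected = 24 h / per-animal median
  interval.
- temperature: range check, default 20–26 °C, configurable — a plain
  plausibility band for murine housing.

Outlier removal is single-pass z-scoring: each scope group's mean and SD
(ddof = 1) are computed once on the pre-removal data and samples with
|z| > threshold (default 3.0) are removed, with no iterative re-scoring —
single-pass is reproducible and directly checkable against a brute-force
oracle. The default scope is per-animal because between-animal level
differences would dominate pooled scores. Zero-variance groups remove
nothing and warn. The rectangular region removal (`remove_region`) is the
programmatic equivalent of an interactive rectangle selection, with
half-open time and value windows so a degenerate selection removes
nothing.

Resampling aggregates non-overlapping windows aligned to each animal's
first sample: intensities (gas rates, temperature) are averaged,
per-interval amounts (activity, food, water) are summed.

The full chain runs in a fixed order — checks → exclusions → negative-gas
drop → z-score → trim → day selection → resample — and the report always
reconciles: rows in − rows out = Σ removed. Trimming and single-pass
z-scoring are not idempotent operations in isolation, so the chain stamps
a hash of the applied configuration into the frame's header metadata and
`curate` becomes a no-op when re-run with the same configuration; this is
the package's definition of pipeline idempotence.

## Energetics

- **EE**: Heldmaier caloric equivalent `(4.44 + 1.43·RER)` mW per
  (ml O2/h), converted by 3.6/1000 to kJ/h; Weir-type alternative
  (3.941/1.106 kcal per litre) in the same registry. EE is linear in V̇O2
  by construction.
- **RER band**: values outside [0.5, 1.3] are flagged, never filtered.
- **RMR**: sliding window (default 30 min, ≥3 samples) over the EE series
  at single-sample steps; windows spanning a time gap larger than 1.5×
  the nominal spacing are disqualified; among windows with CoV = sd/mean ≤
  5% the minimum mean is the RMR. Fallback: mean of the lowest 5% of EE
  samples. Defaults reflect common murine practice; everything is exposed
  in `RMRConfig` including an optional light/dark phase restriction. The
  variability-window method is this package's documented stand-in for
  "signal-variability-based" RMR extraction; the exact algorithms shipped
  by GUI tools differ and are rarely published.
- **TEE/AEE**: TEE = 24 × mean EE over the (already day-selected) trace;
  AEE = TEE − 24·RMR, flagged (never clamped) when negative. Feeding TEE
  only complete selected days avoids partial-day bias.
- **Substrate oxidation**: Frayn-type non-protein coefficients
  (fat 1.67·(V̇O2 − V̇CO2); CHO 4.55·V̇CO2 − 3.21·V̇O2; g per litre),
  centralised in one constants table. Negative rates (RER outside the
  non-protein range) are flagged. A soft consistency check multiplies the
  rates by oxidation energy densities (fat 39.6, CHO 16.7 kJ/g) and
  verifies the sum tracks EE within 5% on synthetic data; the two routes
  use independent coefficient sets, so exact closure is not expected.
- **Profiles**: tumbling zeitgeber-time windows folded across days
  (mean or min); photoperiod aggregates average intensities and sum
  amount channels per phase.
- **Locomotion density**: per-animal occupancy histogram over the
  (activity_x, activity_y) plane — each sample with nonzero total
  beam-breaks contributes one count at its coordinate, and the histogram
  is normalised to unit mass. Weighting samples by their count total was
  rejected: it cannot produce a uniform map over positions with unequal
  totals, which contradicts the intended "uniform activity → uniform
  density" reading.

## Statistics

Per-animal summary metrics (RMR, TEE, AEE, mean EE, mean RER) are joined
with harmonized factors and body mass into an analysis table. Gaussian
models are least-squares fits with Type-II sums of squares by default
(robust to mild imbalance and the common default in the R ecosystem this
workflow mirrors); Type III with sum-to-zero contrasts is available by
flag. Poisson responses use maximum likelihood with per-term Wald tests.
Rank-deficient designs fail with the aliased terms named. ANCOVA reports
covariate-adjusted group means (predictions at the covariate mean).

Normality is tested on model residuals (not per group — residual testing
remains valid with covariates in the model); homogeneity with
median-centred Levene across the factor-level groups. Both are summarised
as pass/fail at α = 0.05, which is fixed so that check-marks are
comparable across reports; groups too small to test are reported
not-computable, distinct from failing. Post-hoc: Tukey HSD (its own
family-wise control) for a single factor, otherwise pairwise t-tests with
Holm (default), Bonferroni or Benjamini–Hochberg adjustment, starred
`*/**/***` at 0.05/0.01/0.001.

## Synthetic cohorts

The generator emulates exactly the structure the analyses are sensitive
to: `EE(t) = rmr + dark_increment·s(t) + Σ bursts(t) + ε`, with `s(t)` a
dark indicator ramped linearly over 30 min at both transitions (avoiding
discontinuity artifacts in window statistics), dark-phase-only Poisson
activity bursts with exponential decay, iid Gaussian noise, and RER
interpolating between light (0.80) and dark (0.95) values along `s`.
Gases come from inverting the Heldmaier equation, so recomputing EE from
the generated gases reproduces the truth to machine precision. Activity
counts are Poisson draws driven by the burst envelope; food/water events
occur only in the dark phase. Defaults are mouse-scale: RMR 8 kJ/h, dark
increment 6 kJ/h, noise SD 0.16 kJ/h (2% of RMR), 5-min sampling, 3 days,
25 g body mass.

Cohorts draw per-animal body mass (N(25, 2²) g) and RMR =
template + group effect (group B) + 0.2 kJ/h/g × mass deviation +
N(0, 0.3²) between-animal jitter, under one hierarchical seed scheme
(cohort → animal → channel), so adding an animal never perturbs existing
ones. `simulate_cohort_summary` exposes the identical per-animal draw as
an analysis table without generating time series; the statistical
calibrations (type-I error over 500 null cohorts, power over 200 cohorts
with a 2 kJ/h effect) run on it because the ANCOVA consumes per-animal
summaries — the full time-series route is exercised end-to-end separately.

What the generator does **not** emulate: thermoregulatory coupling,
food-intake/EE feedback, instrument drift, missing-data patterns or
inter-animal circadian phase differences. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
generative model, not robustness to every pathology of real cage data.

## Numerical and degenerate-input conventions

- Round-trip tolerance 1e-9 relative (12 significant digits on disk).
- A constant response yields statistic 0 / p 1 rather than 0/0 noise.
- CoV windows with zero SD qualify (CoV 0); zero-mean windows cannot.
- Window/region boundaries: time and value windows are half-open; trim
  keeps the boundary samples at exactly `first + trim_start` and
  `last − trim_end`.
- Degenerate activity ranges (a single position) are padded by ±0.5 so
  the histogram still has one well-defined bin.
- All exports use "." decimals, ISO-8601 timestamps, UTF-8.

## Problem sizes

Tests and the acceptance script use deliberately small cohorts (2–8
animals per group, 1–3 simulated days, 5–30 min sampling) and run the
statistical calibrations on the summary-level generator; these sizes were
chosen to keep the full validation loop interactive while leaving every
estimate's sampling error far smaller than the tolerances being checked.

## Known limitations

- The dialect registry emulates vendor structure; real-file conformance
  against proprietary exports is future work.
- The metadata sheet schema is this package's own minimal one (an
  animal-id column plus free factor columns, mass/photoperiod aliases).
- No mixed-effects or repeated-measures models; one summary value per
  animal enters the statistics.
- Tukey post-hoc contrasts are unadjusted for covariates (they compare
  raw group means); covariate-adjusted contrasts would require estimated
  marginal means, which are out of scope.
- No protein-oxidation correction from urinary nitrogen.
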