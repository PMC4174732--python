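# Methods

## The problem

A performer repeats a simple wrist flexion-extension at a steady tempo for
about a minute.  The temporal precision of such an isochronous performance
is limited by central (timekeeper) and peripheral (motor) noise, and its
serial structure reveals *how* the timing is controlled: an internal
timekeeper that emits discrete interval representations (event-based
timing) produces intervals whose lag-one autocorrelation lies in
[−0.5, 0), while timing that emerges from the dynamics of the limb
(emergent timing) produces positive lag-one autocorrelation in (0, 0.5).
The analysis implemented here asks whether an elastic tape applied over
the wrist extensors (i) reduces the residual trial-to-trial variability of
interval durations and (ii) shifts the timing mode toward the emergent
regime.

## Timing-process models

**Event-based (two-level) generator.**  Produced interval
`I_n = T_n + M_{n+1} − M_n`, with timekeeper intervals
`T_n ~ N(μ, σ_T²)` and motor delays `M_n ~ N(0, σ_M²)`, all independent.
The autocovariance is `var(I) = σ_T² + 2σ_M²`, `cov lag 1 = −σ_M²`, zero
beyond lag one, so the lag-one autocorrelation is
`−σ_M²/(σ_T² + 2σ_M²) ∈ [−0.5, 0]`, reaching −0.5 when σ_T = 0.  Normal
noise distributions are the standard choice in this literature; nothing
here depends on higher moments.

**Emergent surrogate.**  A stationary AR(1) on interval durations,
`I_n − μ = φ(I_{n−1} − μ) + ε_n`, with `φ ∈ [0, 0.5)`.  Its stationary
lag-k autocorrelation is `φ^k`, which reproduces the only property the
analysis uses — positive lag-one autocorrelation bounded by 0.5 — with a
closed-form oracle.  An explicit limit-cycle oscillator would add
parameters without adding testable structure, so it was deliberately not
used.

Durations that come out non-positive (possible only at extreme SD/mean
ratios) are resampled from the marginal distribution and logged; this
keeps durations physical at the cost of locally breaking the serial
dependence, and it never triggers at the study's parameter scales
(SD/mean ≈ 0.05).

**Switching series** concatenate segments from either process, threading
one random stream through the segments so a single-segment call equals
the plain generator; per-interval regime labels support tests of windowed
classification across regime boundaries.

## Accelerometer synthesis and interval extraction

Traces are synthesized at 200 Hz: one channel carries
`−cos(2π·phase(t))`, where the phase increases by exactly one cycle per
interval, so local minima (maximum wrist flexion) fall at cumulative
interval boundaries; the other two channels are pure sensor noise.  Five
seconds of continued oscillation at the first/last interval's period are
prepended/appended, mimicking the transient portions of a real recording.

Extraction mirrors the measurement convention: select a channel (default:
highest variance, since the analyzed axis is not fixed a priori), smooth
with a zero-phase 4th-order Butterworth low-pass at 10 Hz (movement
cycling is ≤ 3 Hz; the corner is configurable), detect minima by
prominence, optionally refine each minimum to the argmin of the raw
signal within ±50 ms followed by parabolic sub-sample interpolation
(the default; the smoothed-signal variant is more robust when sensor
noise is heavy), drop events inside the first and last 5 s, and
difference consecutive retained event times.  Trimming excludes *events*,
not intervals: an interval survives only if both endpoints are retained.
Equal-valued neighboring samples resolve to the earliest sample.  With
noise-free traces the round trip recovers every duration within one
sample period (5 ms); this bound is exercised in the test suite and the
acceptance script.

## Tempo ranking

Eight ranked tempo bands (Adagio 937.21 ms … Presto 340.95 ms) ship as a
packaged CSV; the ms columns are the half-up-rounded reciprocals of the
Hz columns, which are treated as authoritative (64 bpm is 937.50 ms
arithmetically but the band reference is defined as 1/1.067 Hz =
937.21 ms).  Band membership is tested on duration with inclusive bounds.
The frequency bands have gaps, so a mean duration falling between bands
is explicitly *unassigned* rather than snapped to the nearest rank — real
performances always fell inside bands, synthetic ones need not.  The
fast/slow dichotomy splits at 517.33 ms (the short edge of the Moderato
band), fast strictly below.

## Windowed lag-one autocorrelation

wγ(1) is the lag-one autocorrelation (mean-centered, lag-0 normalized)
computed in sliding windows of 30 consecutive intervals, step 1.  The
source description — "mean of a set of 30 autocorrelations" — is
ambiguous between this reading and a mean of sub-window coefficients; the
former is the default, the latter is available via `nested_mean=True`.
Per-performance summaries: the Fisher-Z mean (`tanh` of the mean `atanh`)
normalizes the skewed distribution of correlation coefficients before
averaging and before the mixed-model ANOVA; the raw arithmetic mean is
reported alongside for description.  Coefficients at ±1 are clipped to
±(1 − 1e−12) with a warning before the transform.  Window values equal to
zero count as non-positive, so %positive + %negative = 100 always.

Classification of a performance: event-based if the Z-mean is negative
and ≥ 60% of windows are negative, emergent in the mirror case, otherwise
mixed.  The 60% majority threshold is a package convention (the source
analysis classifies qualitatively); it is configurable.  At 500 intervals
per series, window-30 classification separates the two generating
processes with ≥ 90% accuracy (measured in the acceptance script).

The CV uses the sample (n−1) standard deviation; the divisor is not
specified in the source description and the difference is negligible at
these set lengths.

## Heteroscedastic random-effects model

Per-interval response (seconds): observed − expected duration for paced
conditions, observed duration for the free condition.  The published
estimate magnitudes (e.g. a mean error of −0.0063) are only plausible in
seconds, hence the response unit.  Model:

    y_ijk = β₀ + β_speed·fast_ij + β_ktt·ktt_ij + u_i + v_ij + ε_ijk
    u_i ~ N(0, σ_u²),  v_ij ~ N(0, σ_v²),
    ε_ijk ~ N(0, σ²)          untaped
    ε_ijk ~ N(0, σ²·ρ)        taped

Estimation is restricted maximum likelihood.  Because all fixed
covariates are set-constant, the REML criterion factorizes over per-set
sufficient statistics: within-set contrasts contribute
`(n_j−1)·log d_j + SSE_j/d_j` with `d_j` the set's residual variance, and
set means enter through a per-subject (m_sets × m_sets) covariance
`σ_u²·J + diag(σ_v² + d_j/n_j)`.  This makes an evaluation cost
independent of the number of intervals per set, which is what lets the
calibration simulations (hundreds of full-study fits) run in minutes.

Numerics: parameters are `(log σ_u, log σ_v, log σ, log ρ)` —
unconstrained, stable, and yielding natural log-scale Wald intervals
(back-transformed).  The criterion is scaled per observation, optimized
by L-BFGS-B (bounds at ±∞-like extremes only) and then polished by a
short Nelder-Mead run, keeping the better point — the polish guards
against premature quasi-Newton stops with finite-difference gradients.
Variance components at the lower bound are reported as 0 with a boundary
warning.  The Hessian for Wald CIs is central-difference.  Convergence:
relative criterion change 1e−8, max 500 iterations.  Fixed effects get
t-based CIs with containment-style degrees of freedom (subjects − 1 for
the intercept; sets − subjects − set-level parameters for set-level
effects); the denominator-df method is not identifiable from the printed
integer dfs, so containment was chosen and documented.

The LRT for ρ = 1 compares two REML fits with identical fixed effects
(where REML likelihood ratios are valid) to χ²(1); ρ = 1 is interior to
the parameter space, so no boundary correction applies.  ML vs REML is
not stated in the source; REML was chosen because variance parameters are
the quantities of interest and the subject count (25) is modest.  The fit
is verified in the test suite against an independent oracle
(nlme's `lme` with a `varIdent` residual structure), matching fixed
effects, variance components, and the restricted log-likelihood.

The per-set Fisher-Z mean wγ(1) values are analyzed with a subject
random-intercept mixed model (statsmodels MixedLM, REML) on effect-coded
taping and speed factors; Wald F-tests (1 numerator df) use the same
containment-style denominator df.

## Synthetic study generator

`StudyDesign` defaults are the clicks-condition magnitudes: 25 subjects,
2 taping cases, 8 reference tempi × 2 sets (16 sets per case), 80
intervals per set (a ~60 s set minus trimming spans roughly 55–100
intervals across the tempo range; 80 is the single representative value
used throughout), σ_u = 0.0045 s, σ_v = 0.0049 s, σ² = 0.00076729 s²,
ρ = 0.8635, slow mean error −0.0063 s, fast correction +0.0021 s.
Per-set random substreams derive deterministically from the master seed,
so datasets are bit-identical across runs.

Within-set residuals default to the pure-timekeeper limit (serially
independent), which is exactly the residual structure the variance model
assumes; `event_motor_fraction` and the per-case emergent probabilities
add serial structure for timing-mode analyses (the `analysis/` drivers
use 0.25 untaped vs 0.39 taped emergent probability to emulate the
taping-induced shift).  Expected durations are the band references, so
the generator's speed factor is balanced 4 fast / 4 slow.

What the generator does *not* emulate: drift or fatigue within a set,
subject-specific tempo preferences in the free condition, asymmetric or
heavy-tailed error distributions, movement-amplitude covariates, and any
dependence of CV on tempo beyond what a constant residual SD implies (in
real data CV falls for faster tempi; here CV rises because the absolute
SD is constant).  Passing calibration tests therefore demonstrate that
the estimators recover the truth *under the model's own assumptions*, not
that real recordings satisfy those assumptions.

## Problem sizes in the calibration runs

CI coverage of ρ uses 200 simulated studies (64,000 observations each);
LRT size uses 500 studies at ρ = 1; timing-mode classification uses 100
series per process at 500 intervals.  These sizes give Monte-Carlo
standard errors of ~1.5% on a 95% coverage proportion and ~1% on a 5%
rejection rate — small enough to detect meaningful miscalibration while
keeping a full run in the minutes range on one CPU.

## Known limitations

- The real study's participant-level estimates (fixed-effect values,
  specific F statistics, per-range CV curves) are not reproducible
  because no raw data are deposited; the pipeline reproduces the
  *printed arithmetic* exactly and the *methodology* under simulation.
- The heteroscedastic model assumes independent residuals within a set;
  fitting it to strongly autocorrelated series (large motor fraction or
  AR coefficient) leaves the marginal variance estimates consistent but
  makes the Wald/LRT calibration approximate.
- Extraction is not designed for real-world artifacts (sensor drift,
  gravity reorientation, missed cycles); it assumes one dominant
  oscillatory channel.
- The varIdent-style ratio is a single multiplicative factor; residual
  variance differences across tempo bands are absorbed by the random
  effects rather than modelled.
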