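# isochron

Analysis pipeline for the timing variability of isochronous rhythmic
movements — repeated wrist flexion-extensions performed at a steady tempo,
recorded with a wrist-worn tri-axial accelerometer, with and without an
elastic therapeutic tape (kinesio taping, "KTT") applied over the wrist
extensors.

The package is aimed at motor-control and rehabilitation researchers who
want to run, or stress-test on synthetic data, the full analysis chain:

1. **Interval extraction** (`isochron.kinematics`): flexion minima are
   detected on the (smoothed) acceleration signal; the duration of one
   flexion-extension is the difference between consecutive minima; the
   first and last 5 s of each recording are excluded to avoid transients.
2. **Tempo ranking** (`isochron.tempo`): each performed set is assigned to
   one of 8 ranked tempo bands (937.21 ms Adagio … 340.95 ms Presto) and
   dichotomized as fast (< 517.33 ms) or slow.
3. **Variability statistics** (`isochron.stats`): coefficient of variation
   CV = SD/mean × 100, and the windowed lag-one autocorrelation wγ(1) —
   the lag-one autocorrelation of produced intervals computed in sliding
   windows of 30 intervals, summarized by a Fisher-Z mean and by the
   percentages of positive/negative window values.  Event-based (internal
   timekeeper) timing implies wγ(1) ∈ [−0.5, 0); emergent
   (dynamics-driven) timing implies wγ(1) ∈ (0, 0.5).
4. **Variance modelling** (`isochron.variance`): a random-effects ANOVA
   for repeated measurements of the per-interval timing error
   `y = β₀ + β_speed·fast + β_ktt·ktt + u_subject + v_set + ε`, with
   σ²(ε) = σ² for untaped and σ²·ρ for taped observations.  The
   taping-specific **residual variance ratio ρ** is estimated by REML with
   a log-scale Wald CI and tested against ρ = 1 by a likelihood-ratio
   test; mixed-model F-tests analyze the per-set Fisher-Z mean wγ(1).
5. **Synthetic data** (`isochron.synthetic`): a Wing–Kristofferson
   two-level generator (interval = timekeeper interval + motor-delay
   difference), an AR(1) surrogate for emergent timing, regime-switching
   series, accelerometer-trace synthesis, and a full hierarchical study
   generator whose defaults reproduce the magnitudes estimated for the
   clicks condition of the original study.

## Worked example

```python
from isochron import (
    StudyDesign, gen_study, fit_hetero_lmm, lrt_heteroscedasticity,
)

study = gen_study(StudyDesign(), seed=3)      # 25 subjects x 2 cases x 16 sets
obs = study.error_frame()                     # 64,000 per-interval errors (s)
full = fit_hetero_lmm(obs, heteroscedastic=True)
restricted = fit_hetero_lmm(obs, heteroscedastic=False, compute_ci=False)
lrt = lrt_heteroscedasticity(restricted, full)

print(f"variance ratio {full.variance_ratio:.4f}, CI {full.variance_ratio_ci}")
print(f"within-individual SD {full.within_individual_sd:.4f} s, "
      f"within-set SD {full.within_set_sd:.4f} s")
print(f"LRT chi2(1) = {lrt.statistic:.1f}, p = {lrt.p_value:.2e}")
```

prints

```
variance ratio 0.8474, CI (0.8289285824535176, 0.86628725476307)
within-individual SD 0.0046 s, within-set SD 0.0048 s
LRT chi2(1) = 216.5, p = 5.13e-49
```

i.e. on this simulated study the taped residual variance is estimated at
85% of the untaped one (the generating truth is 0.8635, inside the 95%
CI), the subject- and set-level SDs are recovered near their design
values (0.0045 s and 0.0049 s), and the heteroscedasticity is
overwhelmingly supported by the likelihood-ratio test.

The same chain is available from the shell:

```sh
isochron simulate --seed 3 --out sim/
isochron stats --in sim/intervals.csv --window 30 --out stats.tsv
isochron fit --in sim/intervals.csv --model hetero --out fit.json
isochron run --seed 3 --out report/          # full pipeline, all tables
```

The numbered scripts under `analysis/` run the same stages as narrative
drivers (simulation, extraction accuracy, timing-mode statistics, variance
models) and write their tables under `results/analysis/`.

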