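# ecoconv

Bioenergetics of a pelagic planktivorous fish (chub mackerel, *Scomber
japonicus*) estimated from destructive stomach sampling: gastric evacuation
rate, Eggers daily ration, daily growth, ecological (gross) conversion
efficiency, and a temperature × body-weight efficiency surface filled by
natural-cubic-spline interpolation. An individual-based simulator of the
underlying sampling designs provides ground-truthed data for validating the
whole chain.

The package is aimed at trophodynamics / fish-feeding-ecology work where
ration and conversion efficiency must be reconstructed from diel snapshots
of stomach content rather than from direct feeding records.

## The model

After feeding stops, stomach content decays exponentially,

    S(t) = S₀ · e^(−R·t)

and the instantaneous gastric evacuation rate **R** (h⁻¹) is the negated
slope of the OLS regression of ln S on t. Content is normalised to percent
body weight (%BW) to remove fish-size effects. Daily ration follows the
Eggers estimator,

    C_d = 24 · S̄ · R ,

with S̄ the mean stomach content over a 24-h diel series (one estimate per
sampling day, aggregated as mean ± sd). Daily growth **G_d** is the OLS
slope of body weight on experiment day, and gross conversion efficiency is

    E_g = 100 · G_d / C_d   (%),

the fraction of ingested food converted to somatic growth. Determined E_g
values on a 5 × 8 (temperature × weight-class) grid are completed by a
two-pass separable natural-cubic-spline fill — along weight within each
determined-temperature row, then along temperature within each weight
column — and iso-temperature profiles (e.g. 25 °C) are read off the filled
grid.

## Worked example

```sh
ecoconv run-all --seed 42 --outdir run_demo
```

simulates an hourly evacuation trial (10 fish × 11 h) and a 30-day diel
experiment (5 fish × 9 clock times × 5 sampling days, two satiation meals a
day) under sea-cage-like conditions (R = 0.19 h⁻¹, ration ≈ 15.6 %BW/day,
growth ≈ 3.8 %BW/day), then runs every estimation stage:

```
[evacuation] S0=9.154 %BW R=0.1979 /h r2=0.943
[ration]     C_d = 15.16 ± 0.22 %BW/day
[growth]     G_d = 3.651 %BW/day
[efficiency] E_g = 24.08 %
[surface]    filled 5x8 grid; profile at 25.0 °C
```

The fitted evacuation rate (0.198 h⁻¹) and daily ration (15.2 %BW/day)
recover the configured truths (0.19, 15.6) to within sampling noise, and
the resulting conversion efficiency (24.1 %) sits in the 10–30 % range
typical of fish. Per-stage tables plus a reproducibility manifest (config
hash, seed, versions) are written to `run_demo/`.

The same steps are available in Python, scikit-learn style:

```python
from ecoconv import (SimulationConfig, simulate_evacuation_trial,
                     fit_evacuation, EfficiencySurfaceInterpolator,
                     load_reference_knots)

fit = fit_evacuation(simulate_evacuation_trial(SimulationConfig(seed=42)))
print(fit.rate)            # ≈ 0.19 per hour

knots = load_reference_knots()     # packaged 17 determined E_g cells
est = EfficiencySurfaceInterpolator().fit(
    knots[["temperature", "weight_class"]].to_numpy(),
    knots["e_g"].to_numpy())
print(est.predict([[25.0, 90.0]]))  # E_g (%) at 25 °C, 90 g
```

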