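# Methods

## Estimation chain

**Gastric evacuation.** The evacuation model is a single exponential,
S(t) = S₀e^(−Rt). R (h⁻¹) and S₀ are obtained in closed form from the OLS
regression of ln S on t (no iterative fitting), with R reported as a
positive rate (the fitted slope is −R). The fit defaults to
%BW-normalised content — stomach mass divided by the fish's own body
weight — so that between-fish size differences do not leak into the decay
estimate; raw grams are available by option. By default every individual
fish enters the regression; fitting per-time-point means is available
(`by="mean"`) and is identical on noiseless data (aggregation invariance,
tested). Empty stomachs cannot enter the logarithm: the default policy
drops zero records with a warning (the least-assumption choice); an
additive-offset policy (+½ of the smallest positive observation) is
available for series where zeros carry information. Constant content fits
R = 0 with r² defined as 1 (a flat line is a perfect fit when there is no
variance to explain).

**Daily ration.** The Eggers estimator C_d = 24·S̄·R, with S̄ the
unweighted mean content over all fish sampled across the 24-h series.
Unweighted is the default because the diel design is an (almost) even 3-h
grid; a trapezoidal time-weighted mean is provided for irregular designs.
One C_d is computed per sampling day and the experiment-level value is
their mean ± sd, mirroring a design of five separate 24-h determinations
rather than a pooled regression.

**Growth.** G_d is the OLS slope of body weight on day, regressed on
per-sampling-day mean weights by default (the design's granularity: batches
of fish on a handful of days); per-fish regression is an option. Units
default to g/day; a mass-specific %BW/day output (100·slope/mean weight)
exists because E_g is dimensionless only when G_d and C_d share units — the
unit contract is enforced with string tags at the efficiency stage, and
mismatches raise.

**Conversion efficiency.** E_g = 100·G_d/C_d (%). Growth cannot exceed
ingestion, so E_g > 100 % triggers a warning as a unit/orientation check.
Group comparison uses one-way ANOVA plus Tukey HSD, summarised as a compact
letter display computed by insert-and-absorb on the set of significant
pairs, letters assigned in ascending order of group mean.

**Efficiency surface.** Determined E_g values sit on a 5 × 8 grid
(temperatures 10–26 °C in 4 °C steps × weight classes 30–170 g in 20 g
steps; 17 of 40 cells determined in the packaged reference set). The fill
is separable 1-D natural cubic splines in two passes: (1) each temperature
row holding ≥ 2 determined cells is completed along the weight axis;
(2) the remaining rows are filled per weight column through the completed
rows (three knots in the reference layout). Rows-then-columns is the
default order because the determined rows are near-complete (5–7 of 8
cells) while columns hold only 2–3 knots; the reverse order is available
for sensitivity analysis. Separable 1-D passes were chosen over
thin-plate/bicubic scattered interpolation for reproducibility and because
they admit an exact desk oracle (a tridiagonal natural-spline solver, used
in the tests). Natural boundary conditions (zero second derivative at the
end knots) are used throughout; outside the knot range the end cubic is
continued, which is exercised at two corner cells of the reference grid.
Determined knots are never altered — the fill is interpolation, not
smoothing — and iso-temperature profiles at off-knot temperatures (e.g.
25 °C) are evaluated by per-column splines through all five rows of the
filled grid.

The published estimates for the 23 non-determined reference cells came
from a spreadsheet spline whose boundary conditions are undocumented, so
agreement with them is reported diagnostically (±3 percentage points per
cell) rather than enforced; the extrapolated corners are where the dialects
visibly diverge.

## Synthetic data

The simulator emulates three destructive-sampling designs: an hourly
evacuation trial (one satiation meal at t = 0, then 10 fish sampled each
hour for 11 h), a repeated diel experiment (5 fish at nine clock times
0:00–24:00 every 3 h, every 6 days over 30 days), and a per-group
temperature × weight-class rate experiment (groups under a minimum fish
count are flagged excluded). Each fish is sampled at most once.

The stomach-content process is the evacuation model itself: meals are
instantaneous additions to stomach mass (meal mechanics are not resolved by
any of the estimators, so the simplest mechanism is used) and evacuation is
continuous exponential decay in between, giving every observation a
closed-form ground truth. With `warm_start` (default) the daily feeding
schedule is treated as having run indefinitely, so diel series start at
their periodic steady state with no transient; a fish sampled at the exact
instant of a meal counts as not yet fed. The steady-state time-average of
this process equals (daily intake)/(24R), so the Eggers estimator is exact
for the true time-average — what the tests probe is the additional error
from sampling it at nine clock times with five fish.

The canned "continuous-equivalent" schedule (`hourly_feeding_schedule`)
places its 24 equal meals on the half-hour. With meals on the hour, every
on-the-hour sample would land exactly at a sawtooth discontinuity, where
the pre/post-meal convention alone shifts the apparent mean content by
≈ ±10 % at R ≈ 0.19; mid-cycle sampling reads the sawtooth where it is
close to its time-average, leaving the design bias at ~0.1 %.

Observation noise is multiplicative lognormal with unit mean (stomach
masses are positive and right-skewed), default cv 0.2; between-fish
heterogeneity enters the same way through `s0_cv` and `w0_cv`. Unit-mean
noise is additive in log space with a constant offset, so it biases the
evacuation intercept (slightly) but not the fitted rate. Body weight grows
at a specific daily rate, compounded daily by default (`exponential`) with
a `linear` option — the downstream fit is a linear regression either way,
and the linear mode makes noise-free growth recovery exact at machine
precision. Growth compounds at day granularity; within-day growth is
ignored.

Default parameter values are the sea-cage condition of the motivating
experiment: R = 0.19 h⁻¹, S₀ = 9.09 %BW, start weight ≈ 29 g, growth
3.8 %BW/day (the compound rate implied by growing 28.85 g → 88.51 g in 30
days), daily ration ≈ 15.6 %BW/day, 25.1 °C. The group experiment's default
truth functions are a warm-water dome for G_d with an allometric decline
(W^−0.25), and an E_g(T, W) with a mid-temperature trough and a mild
decline in weight (W^−0.15) — qualitative shapes consistent with the
determined grid, used only as configurable ground truth for estimator
recovery.

What the simulator deliberately does not reproduce: multi-prey diets and
prey-dependent evacuation shapes, temperature change within a trial,
appetite feedback between gastric fullness and meal size, and
activity-dependent energy expenditure (the mechanism believed to separate
cage from tank efficiencies). Passing recovery tests therefore shows the
estimators are correct for the exponential-evacuation model under the
stated designs, not that the model captures every feature of wild feeding.

## Numerical choices and degenerate inputs

- Exact closed-form OLS throughout (centered sums); fits require ≥ 3 usable
  time points (evacuation) / ≥ 2 distinct days (growth).
- Grid placement of surface records uses an absolute tolerance of 1e-9;
  duplicate or off-grid records raise.
- Profile extraction refuses temperatures outside the grid range unless
  extrapolation is explicitly allowed.
- C_d = 0 iff S̄ = 0 or R = 0; negative inputs raise everywhere.
- All simulation randomness flows from a single `numpy` Generator seeded by
  the config, so identical configs give bit-identical tables.
- Problem sizes in the validation suite follow the experimental designs
  themselves (11 × 10 evacuation, 9 × 5 × 5 diel; 200 replicates for bias
  checks), which keeps every check well under a minute.

## Known limitations

- The exponential model is assumed, not selected; square-root or linear
  evacuation variants are out of scope.
- The per-individual data behind the published group means are not
  available, so group-level E_g values that were averaged per fish cannot
  be reproduced exactly from the printed G_d and C_d alone.
- Spline extrapolation beyond the determined knot range (two corner cells
  of the reference grid) inherits the natural-boundary choice and should
  not be over-interpreted.
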