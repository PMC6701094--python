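# Methods

## The measurement model

A mobile wind machine blows over two adjacent 7 m rows of maize while the
generated speed is stepped upward: 5 m s⁻¹ increments up to 10 m s⁻¹ (each
level held 30 s), then 2 m s⁻¹ increments up to the 30 m s⁻¹ machine cap
(each held 19 s) — twelve levels in all. Newly lodged plants are counted
against the generated level at which they fell; plants still standing at the
cap are right-censored. Anemometers sample at 1 Hz at the outlet and at
stations behind the canopy at three heights (bottom 0.2 m, middle 1.2 m,
top 2.2 m).

`windlodge` treats the resulting lodging counts as a discrete probability
distribution: masses `p(v)` at the generated levels plus a censored mass,
summing to 1. All four indices are functionals of this distribution or of
the anemometer logs.

## Index definitions and conventions

The substantive conventions, chosen once and applied everywhere:

* **Fractions, not percent.** `p(v)` is stored in [0, 1]. This is what keeps
  `LR(s) = 1/(1 + ∫p dv)` in [0.5, 1] and the CLI in the interpretable
  [0.5, 1] range.
* **Point-mass integrals.** Lodging is only observed at generated levels, so
  `∫₀ˢ p(v) dv` is the cumulative mass at levels ≤ s; the LR curve is a
  right-continuous step function (a plant lodging exactly at `s` counts
  against resistance at `s`, since that is the level at which it was
  observed) and the CLI integral is evaluated in closed form as the area of
  that step function. A midpoint-rule quadrature at ds = 0.01 m s⁻¹ serves
  as the independent cross-check in the tests.
* **Censoring.** The censored mass represents survival beyond `S_m`. It
  never enters LR or the CLI — a cultivar that never lodges has CLI exactly
  1, and any observed lodging pulls the CLI below 1. It does enter the FWS
  objective, at a pseudo-speed `S_m + 2` m s⁻¹ (one fine schedule step above
  the cap): this keeps the L1 objective aware of the surviving plants
  without inventing an unobservable failure speed, and any minimiser at the
  boundary with a censored majority is reported as censored (`> S_m`)
  rather than as a number.
* **FWS candidate grid.** The weighted L1 median is minimised over a 1 m s⁻¹
  grid on `(0, S_m]` augmented with the observed bin speeds, because the
  minimiser of the piecewise-linear objective need not coincide with an
  observed level (a bimodal cultivar's median can sit between its modes).
  Ties — the objective is flat wherever the cumulative mass balances — are
  broken toward the smallest minimiser. The tests verify agreement with
  exhaustive minimisation at 0.01 m s⁻¹ resolution on 1000+ random
  distributions.
* **Reliability with censored values.** In the between-year RMSE/nRMSE a
  censored FWS enters as the value `S_m`. A cultivar that never lodges in
  either year then contributes a zero difference. This is the convention
  under which both published reliability figures are reproduced
  simultaneously, and it is deliberately conservative: it biases the RMSE
  downward, so FWS reliability figures involving censored cultivars should
  be read as optimistic. Cultivars tested in only one year are excluded
  pairwise.
* **Reduction index.** `RI = 1 − ū₁/ū₀` with `ū₀` the time mean of outlet
  samples within a level's hold window and `ū₁` the time-and-station mean of
  downstream samples at the chosen layer in the same window. Negative values
  (downstream momentarily faster than the outlet, as gusts can produce) are
  returned and flagged, never clamped.

## The simulator

The simulator emulates the three ingredients of a trial so that every index
can be validated end to end.

**Wind schedule.** `build_wind_schedule()` reproduces the stepped protocol
above; all parameters (cap, step sizes, changeover speed, holds) are
overridable, and a non-divisible range clamps the final level to the cap
with a warning.

**Attenuation.** Wind speed decays with distance from the outlet and varies
with height. The model is a per-layer reduction index anchored at 2 m and
7 m with linear interpolation between the anchors and a constant value
below 2 m. The default anchors (bottom 0.22 → 0.59, middle 0.02 → 0.65,
top 0.02 → 0.66) are the open-field values measured for this machine
configuration; 7 m is the validated limit and longer distances raise an
error rather than extrapolate.

**Lodging model.** Each plant draws a critical failure speed from a
cultivar-specific Gaussian mixture (components: weight, mean, sd in m s⁻¹)
and lodges at the first level whose *local middle-layer* speed — the
generated speed attenuated to the plant's distance at ear height — reaches
that threshold. Lodging is bookkept against the generated level, matching
field practice. One-component mixtures give unimodal lodging distributions;
two separated components give the bimodal shapes some cultivars show when a
weak sub-population fails early. An optional neighbour-knockdown probability
(default 0) lets a falling plant take an adjacent standing plant with it,
cascading within a level; field reports describe such contagion
qualitatively but give no rates, so the plain threshold model is the
default.

**Defaults.** `n_plants = 84` per trial reflects a planting density of six
plants m⁻² in 0.6 m rows: two tested 7 m rows. Plant positions alternate
between the two rows, evenly spaced along (0, 7]. Anemometer noise is
zero-mean Gaussian (default sd 0.3 m s⁻¹), truncated at zero, sampled at
1 Hz; downstream stations sit at the far (7 m) anchor. The preset library
(`fig3_like_library`) expresses thresholds against the generated speed and
is therefore meant to be simulated with the identity attenuation profile;
pairing it with the default profile shifts every distribution toward
censoring, which is physically sensible but no longer mimics the observed
shapes.

**Randomness.** One `numpy` generator per trial, seeded explicitly. Per
plant, in plant-index order, the mixture component is drawn first and then
the threshold; anemometer noise follows. Identical (spec, schedule, profile,
seed) input gives bit-identical output, and the config pipeline derives
per-trial seeds from the master seed via `SeedSequence.spawn`, so a config
file re-run is byte-identical.

## What the simulator does and does not capture

It captures the stepped exposure protocol, distance/height attenuation,
unimodal and bimodal failure-threshold heterogeneity, censoring at the
machine cap, and instrument noise. It does not model gust spectra or
turbulence structure, leaf drag and its loss when leaves shred, directional
or domino dynamics beyond the optional nearest-neighbour knockdown, or
between-year covariates (rainfall, phenology) that move real thresholds.
Passing tests therefore demonstrate that the statistics behave correctly on
distributions *shaped like* field data — not that the threshold model
predicts any particular cultivar's field behaviour.

## Numerical choices

* Mass bookkeeping uses `math.fsum`; distribution validity demands masses
  sum to 1 within 1e-9.
* FWS tie detection uses an absolute objective tolerance of 1e-12; the
  candidate grid is built to include `S_m` exactly.
* CLI is exact (piecewise closed form), so the 1e-4 quadrature agreement in
  the tests is limited only by the oracle's grid.
* CSV round-trips write floats via `repr`, which round-trips binary64
  exactly; the dialect is comma-separated UTF-8 with a header row and `NA`
  for not-applicable fields, decimal point only.
* Simulated trials in the validation suite use up to 1000 plants and 100
  replicates per condition, sizes at which binomial counting noise is well
  below the 2 m s⁻¹ schedule resolution being tested.

## Known limitations

* The FWS of a heavily censored cultivar is reported as `> S_m`; downstream
  numerical use (reliability) substitutes `S_m`, an explicit lower-bound
  convention rather than an estimate.
* The attenuation model is piecewise linear between two measured anchors;
  real decay is smooth and cultivar-dependent once a canopy is present.
* Trait-index association is plain pairwise Pearson correlation over
  cultivar means, with no multiple-testing correction and typically very few
  cultivars; treat the coefficients as descriptive.
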