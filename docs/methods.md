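# Methods

## Scope and model

`microfilt` analyses constant-pressure microfiltration of soft particles
(cultured cells, calibration beads) through thin microsieve membranes. It
implements three things: (i) the four classical blocking filtration laws and
their fitting/ranking against measured flux-decline curves, (ii) size and
recovery statistics of particle populations, including a micrograph-based
cell-size-measurement (CSM) pipeline, and (iii) synthetic-data generators
that emulate the bench data such studies produce but rarely publish.

### Blocking filtration laws

Under constant transmembrane pressure, fouling-driven flux decline obeys the
characteristic ODE

d²t/dv² = k (dt/dv)ⁿ,

with `v` the cumulative filtrate volume per unit membrane area (m) and the
blocking index `n` selecting the mechanism: cake filtration (n = 0),
intermediate blocking (n = 1), standard blocking (n = 1.5), complete
blocking (n = 2). The closed forms coded in `microfilt.blocking` are

| model        | v(t)                                  | J(t)                        |
|--------------|---------------------------------------|-----------------------------|
| cake         | (√(1 + 2k_c J₀²t) − 1)/(k_c J₀)       | J₀/√(1 + 2k_c J₀²t)         |
| intermediate | ln(1 + k_i J₀ t)/k_i                  | J₀/(1 + k_i J₀ t)           |
| standard     | J₀t/(1 + k_s J₀ t/2)                  | J₀/(1 + k_s J₀ t/2)²        |
| complete     | (J₀/k_b)(1 − e^(−k_b t))              | J₀ e^(−k_b t)               |

Numerical care: the cake form is rationalized as `2J₀t/(1 + √(1+2k J₀² t))`
and the log/exp forms use `log1p`/`expm1`, so k → 0 degrades gracefully into
the no-fouling line v = J₀t (k = 0 is accepted exactly, by analytic limit
rather than division). One identity worth recording: the constant of the
characteristic ODE equals the law's blocking constant for cake,
intermediate and complete, but is k_s·√J₀ for standard blocking (evident
from units once n = 1.5); the test-suite ODE oracle uses that mapping.

### Blocking-index estimation

`estimate_blocking_index` resamples t onto a uniform v grid (linear
interpolation — both derivatives in the ODE are with respect to v, not t),
applies 3-point central differences twice, discards the two boundary points
of each derivative plus the top 10% of the v range (where t(v) steepens and
finite-difference truncation error concentrates), and regresses
ln(d²t/dv²) on ln(dt/dv). The grid is kept ~3× coarser than the widest raw
v spacing so interpolation error stays below the curvature signal. On
noiseless generated curves the estimator lands within ±0.01 of the true
index; the tests assert ±0.05. An exactly linear curve has no curvature to
regress on and raises `NoBlockingSignal` instead of returning a slope.

### Fitting and model ranking

Two routes, mirroring common practice:

* **RMSE least squares** (`fit_model_lsm`): minimizes
  √(Σ(v_meas − v_calc)²/N) over J₀ > 0, k ≥ 0. Deterministic by
  construction: a fixed 5×6 logarithmic start grid (J₀ from the initial
  slope of the curve, k from the record's fouling timescale, plus a k = 0
  column), bounded trust-region refinement from the best four starts, ties
  broken toward the lowest k. An explicit k = 0 line candidate means
  exactly linear data report k = 0, not optimizer noise.
* **Linearized regression** (`fit_model_linearized`): OLS on the
  flux-domain Hermia linear form of each law — 1/J² vs t (cake), 1/J vs t
  (intermediate), 1/√J vs t (standard), ln J vs t (complete) — each
  algebraically exact for its law. J comes from central differences of the
  raw (t, v) record (5-point moving-average pre-smoothing available); the
  end points and any non-positive flux estimates are dropped and counted.
  Working entirely in the flux domain was a deliberate choice: volume-ratio
  transforms such as t/v acquire a spurious monotone trend on periodically
  backflushed records (the hold phases make v lag t by a slowly decaying
  offset), which would misreport a sawtooth-flux experiment as cake-like
  with R² ≈ 0.5. The flux forms are trendless on a periodic flux and
  reproduce the expected "no model fits" verdict.

`compare_models` runs both routes for all four laws, ranks by minimum RMSE
and maximum R², and sets `no_preferred_model` when every R² falls below 0.5
— a threshold that cleanly separates the backflushed regime (R² < 0.1 in
practice) from ordinary dead-end/tangential records (R² ≳ 0.65). "Initial
15% of the data" truncation is provided as `truncate_initial_fraction`
(first ⌈0.15·N⌉ *points*; fitting early data isolates fouling onset).

### Particle sizing and recovery

Percentiles use linear interpolation between order statistics (the j-th of
n sorted values at cumulative probability (j−1)/(n−1)); D values are
reported to 0.1 µm. The single-Gaussian summary is the sample MLE
(mean, sd with ddof = 0) plus a histogram-dip multimodality flag. Mixture
fitting is EM (scikit-learn `GaussianMixture`) with deterministic
quantile-spaced initialization so reports reproduce without seeds;
`reg_covar = 1e-12` keeps the one-component fit equal to the sample MLE to
< 1e-6. Recovery rates follow
total (%) = (N_filtrate + N_retentate)/N_original × 100.

### Cell-size measurement (CSM)

Grayscale conversion (luminance weights), 3×3 median denoising, global
threshold (Otsu by default, fixed value overridable), hole filling,
8-connected components, then a transparent triage in fixed order:

1. area < 20 px → `noise`;
2. touches the field border → `border` (truncated areas bias the
   equivalent diameter downward);
3. circularity 4πA/P² < 0.7 → `aggregate` (fused cells form two-lobed
   outlines; circularity is capped at 1.1 against digitization overshoot);
4. mean interior intensity < background + 0.25·(foreground − background) →
   `dead` — a rule standing in for learned dead-cell recognition: vital
   stains darken dead-cell interiors while the rim stays bright, so the
   interior (the filled component eroded by 3 px to strip the rim) is
   compared against the image's background/foreground levels;
5. otherwise `live`.

Only live particles enter statistics; each is reported as the equivalent
circular diameter 2√(A/π)·pixel size. Aggregate rule note: the area-based
criterion (area > 2× the median single-cell area) was considered and
dropped — the union of two overlapping disks has area *below* twice the
median, so circularity alone is the discriminating feature.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their arguments including the seed.

* **Curves**: closed forms sampled on a uniform time grid with additive
  Gaussian noise on v (balance-reading noise on cumulative mass), clipped
  at 0 and re-monotonized by cumulative max, v(0) pinned to 0.
* **Backflush (PHF) curves**: 5 s filtering / 5 s backflush by default. The
  membrane state is a single effective fouling time τ; filtering advances
  τ, backflush rescales it by (1 − restore_fraction). No filtrate
  accumulates during backflush. Full restoration makes every cycle
  identical — equal per-cycle volume increments and an exactly linear
  envelope — which is the regime no single blocking law explains.
* **Beads**: equal-weight 4-component Gaussian mixture at 5.12/6.78/8.91/
  10.6 µm with cv = 2% (manufacturer-grade monodispersity).
* **Cells**: shifted log-normal d = shift + exp(µ + σZ), solved in closed
  form so the distribution D10/D50/D90 are exactly 13.4/15.7/18.6 µm
  (shift 4.583 µm, µ = 2.4084, σ = 0.18088). Right-skew follows the
  observed D99 − D50 > D50 − D10; the distribution mean comes out ≈15.9 µm
  — consistent with the reported average cell size, checked but not
  enforced.
* **Filtration splits**: rigid (strict d < d_pore sieve, multiset
  partition, hence always 100% recovery) and soft — independent logistic
  passage p = 1/(1 + exp(β(d/d_pore − r50))). Default r50 = 2.6, β = 8:
  deformable leukemia-line cells pass pores ~2.6× smaller than themselves
  at even odds, the ratio implied by filtrate medians shifting only a
  couple of microns through 5 µm pores. Driving pressure modulates r50 as a
  weak power law ((Δp/140 Pa)^0.1) — a qualitative soft-passage emulator,
  not a mechanical model.
* **Micrographs**: anti-aliased disks (exact pixel-coverage compositing) on
  a 0.25 background, live cells filled at 0.85, dead cells a 3 px bright
  rim over a 0.10 interior, aggregates as pairs at 0.9× the sum of radii
  (deep neck, circularity ≈ 0.65), optional Gaussian intensity noise,
  rejection-sampled disjoint placement, ground truth returned alongside.

What passing tests on these data do **not** show: real micrographs have
uneven illumination, focus gradients, halos and debris the renderer omits,
so CSM accuracy here bounds digitization error only; real backflush rigs
return some permeate during suction (here v simply holds); the soft-passage
law is phenomenological; and the noise model is i.i.d. additive, not drift.

## Problem sizes and numerical defaults

Monte-Carlo checks use curves of 241 points (60 s at 0.25 s) with
per-model constants set so the flux declines to 25% of J₀ within the
record — parameters of that identifiability class are what the fitting is
for (some published cake constants imply millisecond-scale decay, which no
bench sampling resolves). Parameter recovery uses 100 noise seeds at 1% of
final v; model selection 20 seeds at 0.5%; the backflush verdict 20 seeds
at 1%; CSM accuracy 20 rendered fields of 30 cells at 0.5 µm/px. Optimizer
tolerances are 1e-15 (ftol/xtol/gtol), EM runs to 1e-7 over at most 500
iterations, and the population calibration check uses n = 1e5 samples.

## Known limitations

* Single-mechanism, constant-pressure laws only; no combined two-parameter
  fouling models, variable pressure, or cross-flow hydrodynamics.
* The linearized route needs a resolvable flux: records sampled much
  coarser than the decay timescale bias the finite-difference J and the
  recovered J₀ (the RMSE route is robust to this).
* Standard vs intermediate blocking produce near-identical v(t) over
  realistic windows; selection between them from noisy data is inherently
  unreliable and the ranking tolerates their confusion.
* The dead/aggregate rules are intensity- and shape-based stand-ins tuned
  for stained brightfield-like images; heavily clumped fields or faint
  staining will need the thresholds in `SegmentationConfig` revisited.
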