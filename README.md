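# microfilt

Analysis toolkit for constant-pressure microfiltration of cells and
microparticles through thin microsieve membranes: blocking-law fitting and
model selection on flux-decline curves, particle-size and recovery
statistics, cell-size measurement from stained micrographs, pore-array
geometry, and synthetic-data generators for all of the above.

It is written for membrane/bioseparation researchers who filter soft
particles (cultured cells, calibration beads) and need to answer three
recurring questions: *which fouling mechanism governs my run*, *what size
cut-off did the filter actually achieve*, and *how many particles did I
lose*.

## The models at the core

Constant-pressure fouling obeys the characteristic equation
d²t/dv² = k (dt/dv)ⁿ, where v is the filtrate volume per unit membrane
area (m) and the blocking index n identifies the mechanism — cake
filtration (n = 0), intermediate blocking (n = 1), standard blocking
(n = 1.5), complete blocking (n = 2). The package provides the four
closed-form solutions v(t) and J(t) = dv/dt, an estimator of n by log–log
derivative regression, and two fitting routes for (J₀, k): RMSE
minimization in the volume domain (√(Σ(v_meas − v_calc)²/N)) and OLS on
each law's exact flux-domain linearization (1/J², 1/J, 1/√J, ln J against
t). A comparison across all four laws ranks models and flags records —
notably periodically backflushed, sawtooth-flux runs — that no single
blocking mechanism explains (all R² below threshold).

Separation performance is summarized by D-percentiles (D10…D99) of
particle-diameter populations, Gaussian/mixture fits, and the recovery
rate, total (%) = (N_filtrate + N_retentate)/N_original × 100. The CSM
(cell-size-measurement) pipeline extracts live-cell equivalent circular
diameters 2√(A/π) from stained brightfield micrographs, excluding noise,
border-clipped objects, aggregates (low circularity) and dead cells (dark
interior) by transparent rules.

## Worked example

Generate a noisy intermediate-blocking curve (J₀ = 1.26×10⁻² m/s,
k_i = 3.97 m⁻¹, 60 s at 4 Hz, balance noise 0.1% of final volume) and ask
which law explains it:

```python
from microfilt import (ModelParams, compare_models, gen_filtration_curve,
                       volume)

params = ModelParams(j0=1.26e-2, k=3.968)
v_final = float(volume("intermediate", params, 60.0))
curve = gen_filtration_curve("intermediate", params, duration_s=60.0,
                             dt_s=0.25, noise_sd=0.001 * v_final, seed=1)
result = compare_models(curve, smooth_flux=True)
for name, row in result.fits.items():
    fit = row["lsm"]
    print(f"{name:13s} J0={fit.params.j0:.3e}  k={fit.params.k:.3e}  "
          f"rmse={fit.rmse:.3e}  R2={row['linearized'].r_squared:.3f}")
print(result.best_model_by_rmse, result.no_preferred_model)
```

```
cake          J0=1.559e-02  k=5.922e+02  rmse=2.683e-03  R2=0.887
intermediate  J0=1.260e-02  k=3.968e+00  rmse=3.151e-04  R2=0.958
standard      J0=1.173e-02  k=2.929e+00  rmse=1.382e-03  R2=0.966
complete      J0=1.105e-02  k=2.495e-02  rmse=2.775e-03  R2=0.955
intermediate False
```

The generating law wins the RMSE ranking by an order of magnitude and its
parameters are recovered to three digits; the linearized R² values show the
familiar ambiguity between intermediate and standard blocking on short
records. A backflushed (sawtooth-flux) curve run through the same
comparison returns `no_preferred_model = True` with every R² below 0.1.

A command-line interface mirrors the library
(`microfilt fit|distribution|size|geometry|simulate|simulate-phf|
simulate-population|render-fields`); e.g.

```sh
microfilt geometry --pore 4.82 --pitch 8.34 --thickness 0.89 \
    --membranes 130 --side 0.7
```

prints the hexagonal-array porosity, total active area (63.7 mm² for 130
membranes of 0.7 mm side) and pore aspect ratio of a microsieve design.

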