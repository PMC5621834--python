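# chromohop

Single-molecule tracking and FRAP analysis of chromatin-binding kinetics,
with a particle-level simulator of state-switching ("hopping") diffusion in
the nucleus.

## The problem

Many nuclear proteins — the motivating case is the cohesin loader
Scc2/Nipbl — spend their lives alternating between free diffusion and
chromatin binding. When binding is frequent relative to diffusion, the
protein's macroscopic transport is *punctuated*: it hops from site to site
and spreads across the nucleus far more slowly than its free diffusion
coefficient suggests. Quantifying this behaviour from live-cell imaging
requires several estimators working together:

* **Single-particle tracking (fast regime, 15 ms exposures at
  64.5 frames/s):** detect single fluorophores, localize them to ~25 nm by
  elliptical-Gaussian PSF fitting, link them into tracks (0.48 µm radius,
  1-frame blink memory, ≥4 steps), and compute per-track apparent diffusion
  coefficients
  `D* = MSD/(4 dt)` and `Dcorrected = D* − σ²/dt`
  (σ = localization precision). Tracks with `Dcorrected < 0.1 µm²/s` are
  chromatin-bound; the bound percentage and the mobile-class mean D* are
  the headline statistics.
* **Dwell times (slow regime, 1 s exposures):** diffusing molecules blur
  away and only bound molecules localize; filtered track durations follow a
  double-exponential mixture. Photobleaching/defocus loss is calibrated
  from a stably bound reference species as an apparent constant `tBleach`,
  and true residence times follow from
  `tBound = tDwell·tBleach/(tBleach − tDwell)`.
* **FRAP:** spot-bleach recovery curves are normalized (background-
  subtracted bleached/unbleached ratio, prebleach mean = 1) and fitted
  either with exponential components
  `F(t) = F0 + Σ A_i(1 − exp(−k_i t))` or with a two-state
  reaction–diffusion model
  `∂f/∂t = D∇²f − k_on* f + k_off c`, `∂c/∂t = k_on* f − k_off c`
  on a radially symmetric nucleus, yielding the bound fraction
  `k_on*/(k_on*+k_off)`, the residence time `1/k_off` and `D_free`.
  Half-nuclear bleaches with Near/Far readout zones expose hopping
  directly: with strong rebinding the far zone takes minutes to
  equilibrate.

Every estimator can be exercised against the package's own stochastic
simulator (continuous-time Markov state switching + reflected Brownian
motion + camera-realistic rendering), so the whole pipeline is testable
end-to-end without any experimental data. See `docs/methods.md` for the
model details and numerical choices.

## Worked example

Simulate fast-regime tracks from a two-state model with a 37% bound
fraction, then recover that fraction with the tracking classifier:

```python
import numpy as np
from chromohop import (AcquisitionSettings, classify_tracks,
                       compute_motion_stats, simulate_mixture_tracks)

settings = AcquisitionSettings()           # dt = 1/64.5 s, sigma_loc = 25 nm
tracks, truth = simulate_mixture_tracks(
    10_000, immobile_fraction=0.37, D_mobile=0.6, settings=settings, seed=31)
stats = compute_motion_stats(tracks, settings)
summary = classify_tracks(stats, threshold=0.1, use_corrected=True)
print(f"immobile: {summary.bound_fraction:.1f}%")
print(f"mobile mean D*: {summary.mean_D_star_mobile:.3f} um^2/s")
```

```
immobile: 37.1%
mobile mean D*: 0.648 um^2/s
```

The classifier returns 37.1% immobile — the generative 37% within counting
noise — and the mobile-class mean D* of 0.648 µm²/s sits slightly above the
generative 0.6 µm²/s because localization noise adds σ²/dt ≈ 0.04 µm²/s to
D\* and the 0.1 µm²/s threshold clips the low tail of the mobile class.

The same round-trip logic runs for FRAP. Fit the reaction–diffusion model
to a particle-simulated spot bleach (44% bound, 22 s residence,
D_free = 0.79 µm²/s):

```python
from chromohop import KineticModel, NucleusGeometry
from chromohop.workflow import frap_parameter_recovery, spot_frap_protocol

model = KineticModel.from_bound_fraction(0.79, 0.44, 22.0)
fit = frap_parameter_recovery(model, NucleusGeometry(semi_axes=(8., 8.)),
                              spot_frap_protocol(), n_cells=40,
                              molecules_per_cell=10_000, seed=11)
print(f"bound: {100 * fit.bound_fraction:.1f}%, "
      f"residence: {fit.residence_time:.1f} s, D: {fit.D_free:.2f} um^2/s")
```

```
bound: 45.2%, residence: 20.8 s, D: 0.80 um^2/s
```

(This averages 40 simulated bleach experiments and takes a few minutes;
the generative values 44% / 22 s / 0.79 µm²/s are recovered within the
estimator's ~6% Monte-Carlo spread.)

A command-line interface mirrors the library
(`chromohop simulate|localize|track|classify|segment|dwell|frap|compare|run`);
see `chromohop --help`.

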