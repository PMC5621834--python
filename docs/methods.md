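# Methods

`chromohop` models and analyses the nuclear dynamics of a chromatin-binding
protein — the motivating case is the cohesin loader Scc2/Nipbl — whose
movement alternates between free diffusion and chromatin binding ("hopping"
or punctuated diffusion). The package contains both the forward model (a
particle-level simulator of state-switching diffusion, camera-realistic
movie rendering, and FRAP protocols) and the inference pipeline
(localization, tracking, diffusion-coefficient classification, dwell-time
estimation with photobleaching correction, and FRAP model fitting).

## Kinetic model

Molecules follow a continuous-time Markov chain over discrete states with
per-state diffusion coefficients. The workhorse two-state reduction,

    FREE  --k_on*-->  BOUND,      BOUND  --k_off-->  FREE,

uses a pseudo-first-order association rate k_on* (binding sites are
unsaturated and implicit), giving the equilibrium bound fraction
k_on*/(k_on* + k_off) and residence time 1/k_off. The default three-state
model splits binding into a transient "search" mode (half-life ~1 s) and a
stable, cohesin-like mode (half-life ~47 s), parameterized so that 37% of
molecules are bound at equilibrium and transient binding events outnumber
stable ones 55:45, with D_free = 0.6 µm²/s — the operating point of
fast-regime single-molecule tracking in wild-type cells. Repeated transient
binding slows macroscopic transport to the effective (hopping) coefficient
D_eff = D_free · k_off/(k_on* + k_off).

Photophysics is deliberately minimal: a permanent exponential bleach, an
optional two-state blinking telegraph, and a permanent defocus-escape
channel. Dark molecules keep moving and binding — only their fluorescence
is removed, because FRAP measures fluorescence, not occupancy.

## Simulation

State timelines are drawn exactly (Gillespie); positions advance in
sub-frame steps (20 per frame by default) with per-step displacement
sd √(2 D Δt) per axis, mirror-reflected at the elliptical nuclear boundary
(preserves the uniform equilibrium density for small steps). Observed
positions are exposure-averaged true positions plus isotropic Gaussian
localization noise (default 25 nm). With a curvilinear site layout
(polylines emulating the vermicelli of Wapl-deficient cells), binding snaps
the molecule to the nearest site point. All randomness flows from one
`numpy` `Generator`; identical seeds give bit-identical outputs.

Movie rendering integrates a pixel-integrated Gaussian PSF along each
molecule's sub-frame path (motion blur), then applies Poisson shot noise ×
gain + offset + Gaussian read noise at 16 bit. A uniform cellular
autofluorescence background (200 photons/px/frame by default) sets the
realistic operating point: at the default 500 signal photons the empirical
localization precision is ~21 nm, consistent with the ~25 nm regime of
live-cell imaging; without it the simulated camera is unrealistically
quiet (~5 nm). The EM-register excess noise of an EMCCD is omitted — the
camera model exists to test detection and fitting, not to calibrate gain.

The two acquisition regimes are pre-configured: fast (15 ms exposure,
64.5 frames/s, for diffusion analysis) and slow (1 s exposure, 1 frame/s,
where diffusing molecules blur away and only bound molecules localize).

## Localization and tracking

Detection subtracts the per-frame median background, applies a PSF-sized
Gaussian matched filter, and takes local maxima above a threshold (default
5× the robust noise sd of the filtered frame; maxima closer than one PSF
diameter merge to the brighter one). Sub-pixel positions come from
least-squares fits of a pixel-integrated elliptical Gaussian in a 7×7
window; fits that fail to converge or whose widths fall outside
[0.3, 5]×psf_sigma are flagged and dropped, not raised. Coordinates are µm
from the image corner; pixel (i, j) has its centre at ((j+½)p, (i+½)p).

Linking minimizes, per frame pair, the summed squared displacement plus a
penalty of radius² per unmatched localization (solved exactly with the
Hungarian algorithm) — deterministic, order-independent, and equal to
brute-force enumeration on small instances. A memory parameter (default 1
frame) bridges blinking gaps, with the allowed gap displacement scaled by
√(gap+1) (Brownian growth of the search area). Tracks with fewer than 4
steps are discarded. Default radii: 0.48 µm (fast regime), 0.192 µm (slow).

## Diffusion analysis

Per track, the lag-1 mean-squared displacement over consecutive frames
(gap-spanning steps excluded — they cover 2 dt and would inflate the
estimate) gives D* = MSD/(4 dt) and the localization-error-corrected
Dcorrected = D* − σ²/dt. Dcorrected may be negative and is not clipped;
clipping would bias the bound fraction. Classification: BOUND iff
Dcorrected < 0.1 µm²/s (the corrected coefficient is the default
classifier; D* against the same threshold is also computed). Interval
segmentation slides a 5-step window along a track, thresholds the
instantaneous Dcorrected, and merges runs shorter than 3 frames into their
flanking state — enough to resolve the ~100 ms search-binding events at
15.5 ms frames without chattering.

## Dwell times and photobleaching correction

In the slow regime, tracks passing a maximum-D* filter (0.1 µm²/s) and a
maximum fitted-width filter (1.5× psf_sigma; a D = 0.6 µm²/s molecule
blurred over 1 s is ~3× wider than the PSF) are stationary molecules, and
their durations are apparent dwell times. The dwell distribution is fitted
with f·exp(−t/τ₁) + (1−f)·exp(−t/τ₂), by least squares on the empirical
survival curve (the representation the distributions are displayed in) by
default, with an unbinned maximum-likelihood variant as cross-check. If
the two constants collapse within 5% the fit degenerates to a flagged
single exponential. Observations beyond 80% of the movie span are dropped
as right-censored pile-up.

Apparent dwells are shortened by photobleaching/blinking/defocus loss. A
reference species that is stably bound on the observation time scale (the
cohesin kleisin, resident 15–30 min) calibrates the loss constant tBleach —
its apparent dwell distribution reflects loss alone; the dominant-amplitude
component of its double-exponential fit is returned, and a reference whose
dwells mostly run to the movie end raises an error (loss unresolved). True
constants follow from tBound = tDwell·tBleach/(tBleach − tDwell),
equivalently 1/tDwell = 1/tBound + 1/tBleach. The correction diverges as
tDwell → tBleach: near the pole, small errors in the apparent constant are
strongly amplified (≈3.4× at the package's default operating point), which
is why the headline corrected constants in `scripts/acceptance.py` use the
lower-variance MLE fitter. Printed residence values are emitted both as
exponential constants τ and as half-lives ln2·τ; the package treats
published per-component values such as "1 s / 47 s" as half-lives, a
convention that round-trips consistently either way.

## FRAP

Normalization follows the experimental recipe: background-subtracted
bleached/unbleached intensity ratio, divided by its prebleach mean (the
published Methods sentence states the inverted ratio, which would decrease;
published curves recover toward 1, so bleached/unbleached is used). The
normalization is scale-invariant.

Recovery models:

* **Exponential components** F(t) = F0 + Σ A_i(1 − exp(−k_i t)), reported
  as percent fractions and half-lives ln2/k_i, with 1-vs-2-component
  selection by AIC. The unrecovered remainder stays in the F0 complement
  (not renormalized), which is why printed fractions like 53% + 45% need
  not reach 100%.
* **Two-state reaction–diffusion**: ∂f/∂t = D∇²f − k_on*f + k_off c,
  ∂c/∂t = k_on*f − k_off c on a radially symmetric nuclear disc (default
  radius 8 µm) with reflecting boundary, solved by Crank–Nicolson on a
  cell-centred radial grid (200 nodes default; graded time steps, 10 ms
  early). The equations and discretization are this package's choices.
  The initial condition scales the equilibrium profiles by the bleach
  survival profile (a disc of radius 1.25 µm — a "2.5 µm circle" read as a
  diameter — with a Gaussian edge, sd 0.25 µm). Without a bleach the
  solver conserves total mass to 1e-8; at k_on* = 0 it matches the
  uniform-disc closed form exp(−2τ/t)[I0 + I1](2τ/t) with τ = w²/(4D) to
  0.2% RMS (the τ convention was verified against direct heat-kernel
  quadrature).

Fitting (D_free, k_on*, k_off) runs bounded least squares in log-parameters
from 8 seeded multi-starts (the objective is multi-modal: a slow-diffusion/
high-bound-fraction ridge shadows the reaction-dominant solution). Two
estimator-design points matter for synthetic-counts data:

* a *single* spot-mean curve from 10⁴ molecules leaves the inversion badly
  conditioned — only ~2.4% of molecules ever occupy the 1.25 µm spot, and
  their counting noise is correlated over the 22 s residence time. The
  canonical experiment (`workflow.spot_frap_protocol` +
  `frap_parameter_recovery`) therefore records ten annular readout zones
  tiling the whole nucleus and fits them jointly with √area Poisson
  weights, averaging the normalized curves over repeated simulated bleach
  experiments — the same averaging over repeats applied to experimental
  recovery curves. At 40 repeats of 10⁴ molecules the residence-time
  estimate carries ~6–7% Monte-Carlo sd, measured by seed sweeps at the
  generative truth;
* synthetic curves are normalized by the exact zone-area fractions
  (`normalize="expected"`/`"area"`) rather than the measured prebleach mean:
  with known geometry the measured prebleach is just a noisy estimate of the
  area ratio, and its error rescales the whole curve, masquerading as
  incomplete recovery (i.e. a spuriously long residence time). For measured
  data, where areas are unknown, the prebleach procedure is the default and
  an optional multiplicative nuisance scale can be profiled in the fit.

Half-nuclear protocols report per-zone (Near/Far band) recovery and
times-to-level; in the strong-binding regime the far zone takes >5 min to
equilibrate while a no-binding control equilibrates in tens of seconds —
the qualitative signature of hopping transport.

## Synthetic data vs real data

The generator emulates: two acquisition regimes, state-switching Brownian
motion in a 2-D nuclear cross-section, localization noise, motion blur,
camera noise with autofluorescence background, bleach/blink/defocus loss,
disc and half-nuclear bleach geometries, and curvilinear binding sites. It
does not emulate: 3-D diffusion and axial defocus (loss is a single rate,
not a depth model), chromatin polymer motion of the binding sites,
EM-register excess noise, drift, or spatial heterogeneity of binding rates.
Passing round trips therefore demonstrate that the *analysis* recovers the
*model's* parameters under realistic sampling and noise — not that the
model captures every property of real nuclei.

## Problem sizes and numerical defaults

Round-trip suites run at 10⁴ tracks / 10⁴ dwell intervals / 10⁴ molecules
per simulated nucleus (40 nuclei for the reaction-diffusion fit), chosen to
put Monte-Carlo noise comfortably inside the 10–15% recovery tolerances
while the full test suite and the acceptance script each finish in minutes
on one CPU. FRAP particle simulations use 20–50 ms sub-steps (the recovery
observables depend on positions only at sample times, so the main
requirement is resolving the sampling grid and the state-switching rates);
PDE fits use 300 radial nodes, which agree with the 1200-node solution well
below the counting noise. Degenerate inputs are handled explicitly: empty
localization tables link to empty track sets, tracks shorter than the
window or step minimum are rejected with reasons, tDwell ≥ tBleach raises
a dedicated error, and a bleach region outside the nucleus is a protocol
error.

## Known limitations

* The 2-D disc/ellipse nucleus ignores axial structure; absolute D* values
  from the simulator carry the same motion-blur and defocus biases as the
  experimental estimator (by design — D* is a comparative statistic).
* The reaction-diffusion fit assumes one binding state; applied to
  three-state data it returns an effective two-state compromise.
* `effective_diffusion` is exact only in the fast-exchange limit; at slow
  exchange ensemble spreading is scale-dependent.
* Survival-curve least squares ignores the correlation of adjacent
  empirical survival points; its parameter uncertainties are realistic only
  via resampling (not provided).
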