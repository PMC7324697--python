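# Methods

## Measurement model

A scanned transverse profile is treated as one-dimensional: relative dose
versus off-axis distance x (mm), central axis (CAX) at x = 0, normalized so
the CAX value is 1. The chamber measurement is modeled as the true profile
convolved with a Gaussian detector response function (DRF),
`P_m = P_t ⊗ K_σ`, plus additive noise. The Gaussian DRF is the standard
one-parameter approximation for cylindrical chambers; non-Gaussian or 2-D
response models are out of scope. The diode reference is treated as the
true profile (its volume averaging is negligible at the 1 mm working
resolution); an explicit diode width is not modeled.

## Profile processing

* **Grid.** All operations assume a uniform grid containing a node at
  x = 0. `resample_to_grid` uses monotone piecewise-cubic (PCHIP)
  interpolation — it cannot overshoot on the steep penumbra, unlike an
  unconstrained cubic spline.
* **Smoothing.** Savitzky–Golay, default window 5 points / order 2.
  Endpoints are handled by evaluating the terminal window's fitted
  polynomial (`mode="interp"`), so inputs that are globally polynomial of
  degree ≤ order pass through exactly. Synthetic pipelines skip smoothing:
  the generator's noise level is controlled.
* **Penumbra width.** For each edge, the 20% and 80% crossings of the
  CAX-normalized profile are located by scanning from the outermost sample
  inward and linearly interpolating inside the first bracketing interval;
  scanning outside-in makes the metric insensitive to in-field noise dips.
  The reported width of a profile is the mean of its left and right edge
  widths, and the penumbra width difference (PWD) is the signed difference
  of two profiles' mean widths. The 20/80 levels are relative to CAX for
  flattened and unflattened beams alike. On a 1 mm grid, linear
  interpolation biases the width of an erf edge by a few hundredths of a
  millimetre; this cancels in PWD comparisons made on a common grid, and
  tests that check the closed-form erf-edge width use dense sampling.

## DRF estimation

`σ̂ = argmin_σ ‖P_m − P_t ⊗ K_σ‖²` over the full common grid (not only the
penumbra region), minimized by bounded Brent search on [0.05, 10] mm with
1e-4 mm tolerance; the objective is smooth and unimodal in practice on this
profile family, so no multi-start is used. The kernel is discretized on the
profile grid, truncated at ±4σ (mass lost before renormalization < 1e-4)
and renormalized to unit sum; convolution uses replicate padding, which is
exact on scans that end on flat tails. When the measurement carries no
broadening the objective is flat at the noise floor below some σ; the
estimate is then pinned at the lower bound and a warning is issued rather
than reporting an arbitrary point of the flat region.

## Network and training

Architecture 15–5–1: window length 15 (±7 mm of context, comparable to the
spatial extent of chamber blur at σ ≈ 3 mm), 5 tanh hidden units, linear
output, 86 parameters. No input features beyond the window — in
particular, no energy/modality labels, so a pooled network treats all its
training conditions identically.

Levenberg–Marquardt with the analytic Jacobian of the output with respect
to all 86 parameters (verified against central finite differences in the
tests). Damping μ·I with μ₀ = 1e-3; one epoch tries steps with μ growing
tenfold until the summed squared error decreases (then μ shrinks tenfold),
so accepted steps never increase the training loss. Stopping: 400 epochs,
gradient ∞-norm < 1e-10, or μ > 1e10 (converged to machine precision).

Initialization is uniform(−1, 1) for every weight and bias, seeded per
restart as `seed + restart`; window inputs lie in [0, ~1.1], keeping tanh
pre-activations in a trainable range. Ten restarts by default; the kept
network is the one with the smallest *validation* MSE, where validation is
a seeded 80/20 sample-level split of the pooled training windows — sample-
rather than profile-level because all training profiles come from the same
grid and the network sees windows, not profiles. Deconvolution
replicate-pads the measured profile by half a window so the output covers
the full grid; outputs are not clipped or rescaled (evaluation normalizes
to CAX before computing PWD).

## Synthetic generator

The generator emulates a water-tank scan session, not transport physics.
The true profile is the classic two-edge error-function model

    B(x) = ½ [erf((W/2 − x)/(√2 λ)) + erf((W/2 + x)/(√2 λ))]

with a constant out-of-field transmission tail (default 1.5% of CAX)
blended as `B + tail·(1 − B)`, and, for FFF beams, an in-field linear cone
`(1 − c|x|)` with c = 0.0015 per mm. Edge softness grows linearly with
depth, λ(d) = 1.0 mm + 0.005·d, giving the expected monotone penumbra
growth over the 1.5–20 cm depth range. Geometry defaults are the standard
small-field grid: square fields of 20–100 mm side at depths 15/50/100/200
mm (28 geometries); scans span the field half-width plus 40 mm so every
scan ends on a flat tail. An optional geometric magnification of the
projected field width with depth exists but is off by default.

Chamber scans are the true profile convolved with the chamber's DRF
(defaults CC04 1.3 mm, CC13 2.6 mm, FC65-P 2.9 mm — the CC13 value follows
published characterizations of that chamber, the others are scaled by
chamber size so penumbra broadening orders as CC04 < CC13 < FC65-P), plus
i.i.d. Gaussian noise of 0.002 of CAX added *after* convolution
(detector + electrometer noise), then renormalized to CAX = 1. The diode
reference gets the same noise model with zero blur. Noise seeds derive
deterministically from the configuration seed per geometry and detector.

What the generator does **not** emulate: flattening-filter horns and
shoulders at large fields, electron contamination, dose-rate/ion-
recombination effects, measurement positioning errors, or non-Gaussian
chamber response. Passing the end-to-end tests therefore shows the method
recovers profiles whose blur really is Gaussian and whose shape family the
network has seen — the intended self-consistency check — not that it
corrects arbitrary measured clinic data.

## Evaluation protocol

The 28 geometries split by rule into 12 training/validation scans (field
sizes 20/40/60/100 mm at depths 15/100/200 mm) and 16 test scans (all of
depth 50 mm plus the remaining field sizes elsewhere). A *separate* network
is trained per (energy, modality, chamber) condition; a *combined* network
pools the training windows of several conditions of the same chamber
(pooling across chambers is rejected — the kernel being inverted is the
chamber's). Reports give per-geometry PWD before and after deconvolution
versus the diode reference (and versus the noise-free truth, available
synthetically), with means of |PWD| over the train subset, test subset, and
all geometries — the absolute value is taken per profile before averaging
so over- and under-shoots cannot cancel.

At the default conditions the separate network reduces mean |PWD| from
~2.6 mm to well under 0.15 mm and the pooled FF+FFF network stays under
0.20 mm per condition; `scripts/acceptance.py` recomputes both numbers from
scratch at full protocol scale (10 restarts × 400 epochs, 28 geometries per
condition), which runs in well under a minute on one CPU. Unit tests that
probe training properties (determinism, realizability, loss monotonicity)
use reduced grids and shorter schedules, since those properties do not
depend on the protocol scale.

## Known limitations

* The Gaussian-DRF generator matches the network's implicit assumption;
  real chambers deviate from Gaussian response in the tails.
* Penumbra widths on the working 1 mm grid carry a small positive
  interpolation bias (cancels in PWD on a common grid).
* A network is only valid for inputs inside the span of its training data;
  pooled networks must include every energy/modality they will deconvolve.
* Vendor water-tank file formats are not parsed; profiles enter as
  `position_mm,value` CSV with a JSON metadata sidecar.
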