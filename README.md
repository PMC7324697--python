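# beamdeconv

Removal of ionization-chamber volume averaging from scanned photon beam
profiles with a small sliding-window neural network.

## The problem

Transverse dose profiles for linac commissioning and QA are usually scanned
with a finite-size ionization chamber (IC). Signal integration over the
chamber's active volume — the volume averaging effect (VAE) — broadens the
field penumbra by 1–3 mm, which matters most for the small fields used in
IMRT/VMAT. The measured profile is well modeled as

    P_m(x) = P_t(x) ⊗ K_σ(x)

where `P_t` is the true profile, `K_σ` a Gaussian detector response function
(DRF) with shape parameter σ (mm), and `⊗` convolution. Direct Fourier
deconvolution amplifies noise exactly where the penumbra lives, so this
package instead trains a three-layer perceptron to invert the blur
point-by-point: a sliding window of `L_sw = 15` consecutive measured samples
(1 mm spacing) feeds 5 tanh hidden units and one linear output,

    O = b_o + Σ_k w_k^o · tanh( Σ_j w_jk^h s_j + b_k^h ),

the deconvolved dose at the window's center — 86 free parameters in all.
Training pairs chamber scans with reference scans from a small-area diode
(negligible VAE) and minimizes the mean squared output error with
Levenberg–Marquardt, restarting from random weights 10 times × 400 epochs
and keeping the restart with the lowest validation MSE.

Performance is judged by the penumbra width difference
`PWD = W_o − W_r`, where `W` is the lateral distance between the 20% and
80% relative-dose levels of an edge.

The package also provides:

* **DRF estimation** — `σ = argmin_σ ‖P_m − P_t ⊗ K_σ‖²` by bounded scalar
  minimization, per geometry or surveyed over a grid (`GaussianResponseModel`).
* **A synthetic water-tank generator** — error-function field edges
  (with a linear cone for FFF beams), Gaussian chamber blur, and additive
  noise over the standard 7-field × 4-depth grid, so the entire protocol is
  reproducible without measured data.
* **The evaluation protocol** — the 12/16 train/test geometry split,
  chamber-specific ("separate") and pooled FF+FFF ("combined") network
  training, and PWD/MSE report tables.

## Worked example

```python
from beamdeconv import (SyntheticConfig, make_condition, run_separate,
                        estimate_sigma)

cfg = SyntheticConfig(seed=1)                      # 7 fields x 4 depths
cond = make_condition(cfg, "FF", "CC13")           # CC13-scanned 6 MV FF beam

# how wide is this chamber's response kernel?
entry = cond.entries[14]                           # 5x5 cm^2 at 10 cm depth
fit = estimate_sigma(entry.measured["CC13"], entry.reference)
print(fit.summary())

# train the deconvolution network and evaluate
rep = run_separate(cond, restarts=10, max_epochs=400, seed=1)
print(rep.summary())
```

prints

```
Gaussian detector response fit
  sigma            2.5643 mm
  residual     1.8975e-03
  bounds       [0.05, 10] mm
Condition 6MVFF_CC13 (separate network)
  geometries        28 (12 train / 16 test)
  |PWD| train  before  2.56 ± 0.39 mm   after  0.06 ± 0.04 mm
  |PWD| test   before  2.67 ± 0.31 mm   after  0.05 ± 0.04 mm
  |PWD| all    before  2.62 ± 0.34 mm   after  0.06 ± 0.04 mm
```

The σ fit recovers the generator's configured CC13 response width (2.6 mm)
to within the noise, and deconvolution shrinks the mean penumbra-width error
from ~2.6 mm to ~0.06 mm — including on the 16 geometries the network never
saw. `run_combined` trains one network on FF and FFF conditions pooled and
evaluates each separately; `report` writes the per-geometry and summary
tables as CSV/Markdown.

A `beamdeconv` console script wraps the same steps
(`simulate`, `estimate-sigma`, `train`, `deconvolve`, `evaluate`); see
`beamdeconv --help`.

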