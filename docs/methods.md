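# Methods

This note records the mathematical model, the parameter choices and their
defaults, what the synthetic data generator does and does not emulate, the
numerical design decisions, and the known limitations of `nactct`.

## Problem and model

We reconstruct a 2-D image `f` (nonnegative attenuation map, `N x N` pixels)
from sparse-view parallel pencil-beam projections

```
p = A f (+ e),
```

where `A` is the system matrix whose row `(m, d)` holds the exact
intersection lengths of ray `d` of view `m` with each pixel, and `e` is
optional Gaussian noise. The reconstruction problem is posed as

```
min_f  ||f||_TV + || Phi f ||_1    s.t.  || A f - p ||_2^2 < sigma^2,
```

with `Phi` a non-aliasing contourlet transform (NACT), solved by a
Split-Bregman splitting: auxiliary variables `d_x, d_y, d_phi` carry the L1
channels, Bregman variables `b_x, b_y, b_phi` accumulate the splitting
errors, and the quadratic subproblem in `f` is attacked by normalized
gradient-descent steps interleaved with ART (Kaczmarz) data passes.

### Two-loop structure

Each outer iteration `n` (default 50):

1. one sequential Kaczmarz sweep over all rays in view order, then a
   positivity clamp;
2. record `d(n) = || f_before - f_after ||_2`, the natural step scale;
3. `K` inner iterations (default 10), each sweeping the views `m` and taking
   a step `f <- f - a d(n) g/||g||` along the subproblem gradient

   ```
   g = 2 lambda A_m^T (A_m f - p_m)
     - 2 gamma grad_x^T (d_x - grad_x f - b_x)
     - 2 gamma grad_y^T (d_y - grad_y f - b_y)
     - 2 mu    Phi^T   (d_phi - Phi f - b_phi),
   ```

   followed by the positivity clamp and the shrinkage/Bregman updates
   `d = shrink(grad f + b, t)`, `b <- b + grad f - d` per channel.

ART and ART-TV baselines are the same engine with, respectively, both
regularization channels removed and only the contourlet channel removed, so
comparisons isolate each ingredient.

## Parameters

| Parameter | Default | Role and rationale |
|---|---|---|
| `lambda_` | 1000 | data-fidelity weight; large so data consistency dominates the inner subproblem |
| `gamma` | 30 | TV channel weight |
| `mu` | 30 | contourlet channel weight; equal to `gamma` so neither prior dominates |
| `step_a` | 0.2 | descent step as a fraction of the ART update size `d(n)`; keeps inner steps subordinate to the data pass |
| `k_inner` | 10 | inner Split-Bregman iterations per outer iteration |
| `n_outer` | 50 | outer iterations; the standard study length |
| `sigma` | `None` | optional stopping tolerance on `||Af - p||`; disabled by default so run length is deterministic |
| `threshold_convention` | `"as_printed"` | shrinkage thresholds `1/lambda` (gradient channels) and `1/mu` (contourlet); the alternative `"weight_consistent"` uses `1/(2 gamma)`, `1/(2 mu)`, the values implied by the quadratic weights |
| `cache_regularization` | `False` | evaluate the regularization gradient once per inner iteration instead of once per view; at small scale the two agree to ~1e-3 RMSE while the cached variant is ~20x faster at full scale |

NACT defaults: 3 levels with (4, 8, 8) directional subbands, anti-aliasing
parameter `a = 0.2 pi`. The first pyramid stage is undecimated; later stages
decimate by 2 via central spectrum cropping, which is exact because the
stopband edge of the second-stage lowpass is kept strictly inside the
alias-free box `|omega| < pi/2` (measured in the max-norm radial variable).

Geometry defaults: 200x200 phantom, `n_detectors = 200`, detector spacing 1
pixel, 60 views. The view angles follow a two-arc schedule: views
`i = 1..N/2` at `1 + 360 (i-1)/N` degrees and views `i = N/2+1..N` at
`182 + 360 (i - N/2)/N` degrees, giving an interleaved double coverage of the
half circle.

## Synthetic data: what it does and does not show

The generator rasterizes the standard modified (contrast-enhanced)
Shepp-Logan ellipse set on `[-1, 1]^2` by pixel-center membership and
projects it with the same discrete operator `A` used for reconstruction
(an "inverse-crime" setup). Consequences:

- Results demonstrate the relative behavior of the regularizers under
  identical, idealized conditions — not absolute clinical image quality.
- Because data are generated by `A` itself, plain ART converges faster and
  further than it would on data from a mismatched (analytic or finer-grid)
  forward model; absolute ART errors here are optimistic.
- Noise is zero-mean white Gaussian added to the sinogram. Two power
  conventions are provided: `reference="signal"` scales noise to a measured
  SNR relative to the sinogram's mean-square value, and `reference="unit"`
  interprets the dB figure against unit power (noise variance
  `10^(-snr/10)`), matching a common simulation idiom in which "10 dB noise"
  means variance 0.1. The experiment configuration defaults to `"unit"`;
  the physically conventional `"signal"` reading produces noise two orders
  of magnitude stronger at these sinogram amplitudes.
- No beam hardening, scatter, detector blur, Poisson statistics, or motion.

## Numerical choices

- **System matrix**: Siddon-style exact ray/pixel intersection lengths,
  assembled once as a sparse CSR matrix; rows grouped by view for the
  per-view inner steps. Pixel (0,0) is top-left, angles in degrees,
  counterclockwise.
- **ART**: row-sequential Kaczmarz with precomputed inverse row norms; zero
  rows (rays missing the image) are skipped.
- **NACT**: implemented entirely in the FFT domain as a Parseval tight
  frame. The pyramid lowpass/highpass pairs satisfy the complementary-
  magnitude conditions `D0^2 + L0^2 = 1` and `D1^2 + L1^2/4 = 1` exactly
  (Meyer-style polynomial transitions). The directional stage uses
  undecimated angular wedge windows whose squares partition unity,
  symmetrized across the Nyquist row/column so real inputs give real
  subbands. A ladder-structured (pkva-type) directional bank was
  deliberately not used: it is biorthogonal, and the solver relies on the
  adjoint being the exact inverse (`Phi^T Phi = I`), which only a tight
  frame provides. Perfect reconstruction holds to ~1e-15; the adjoint and
  the inverse coincide.
- **Shrinkage**: the scalar soft-threshold applied elementwise, including
  to contourlet coefficient objects.
- **Metrics**: RMSE over all pixels and the global universal quality index
  (UQI) with `(n-1)` variance normalization.
- **Divergence guard**: solvers abort if the data residual grows tenfold
  over its starting value.

## Limitations

- Parallel-beam, single-pixel detectors, 2-D only; no fan/cone beam.
- The inverse-crime evaluation flatters all methods, plain ART most of all;
  on analytically projected or finer-grid data the regularized methods'
  advantage narrows and parameters would need retuning.
- The printed-threshold convention (`1/lambda`, `1/mu`) ties the TV
  shrinkage strength to the data weight; with very different `lambda` the
  `weight_consistent` convention may behave better.
- Runtime is dominated by the per-view inner loop; with
  `cache_regularization=False` the full-scale contourlet run recomputes
  `Phi f` 30,000 times (~15 min on one CPU). The cached variant (~1 min) is
  recommended and used in the package's own studies.
- With unit-reference 10 dB noise, ART-TV at the default parameters can
  fall below plain ART in RMSE on some noise draws; the TV weight was not
  retuned per noise level.
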