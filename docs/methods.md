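# Methods

This note records the models implemented in `mirrorscan`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
scanner does and does not emulate.

## Timing model

The per-line time is additive:
`T_line = T_exp + T_rx + T_api + T_mcpy + T_act + T_rand`, with
`T_extra = T_rx + T_api + T_mcpy + T_act` constant for a fixed
configuration and `T_rand` a non-negative random OS-scheduling delay.
Transfer time is `T_rx = h·w·b·Ω/R_b` (sensor height × width × bit depth ×
protocol overhead / link bitrate).  Efficiency is `ε = T_exp/T_line`,
bounded by 1.

- **T_rand law.** Only "stochastic" is known about real scheduler delays.
  The simulator default is *exponential* (non-negative, heavier-tailed,
  the usual minimal model for interrupt-like delays), selectable as
  `exponential | half_normal | none`; the scale parameter is the
  exponential mean or the half-normal σ.
- **Overhead estimator.** `fit_extra_delay` performs nonlinear least
  squares of the *measured line rates* (1/wall time) against
  `1/(T_exp + T_extra)`, i.e. the fit is done in LPS space, where such
  data are conventionally plotted and fitted; residual wall-time spread is
  reported as the random-delay signature.  With `T_rand` present the
  estimator converges to `T_extra + E[T_rand]`, the effective constant
  overhead — this is the quantity that matters for throughput prediction.
- **Image time.** `image_time` computes `T_img = N_lines·T_line/ε_avg` in
  its conventional benchmark form.  When `t_line` already contains the
  overhead this double-counts it; the algebraically non-double-counting
  alternative `N_lines·T_exp/ε_avg` is available via `formula="exposure"`.
- **Empirical efficiency** per exposure level is `t_exp / mean(wall)`,
  matching how efficiency scatter data are constructed from logs.

## Mirror geometry

With mirror angle θ measured against the object-plane normal and
`γ = π/2 − 2θ` (positive γ ⇒ positive object position):

- line position `y_d = r·tan γ`;
- path elongation `Δr = r(√(1 + 1/tan²2θ) − 1) = r(1/sin 2θ − 1)`;
- in-line width scale `h(θ) = 1/sin 2θ` (≥ 1, equal to 1 at θ = π/4).

The radical reading of the elongation/width expressions is asserted by a
property test via the identity `r(h − 1) ≡ Δr`, and is the reading
consistent with a ray of length `r/cos γ`: at γ = π/8 it gives
Δr/r = 1/cos(π/8) − 1 = 8.24%, the familiar "≤ 8%" linear-range bound.

Conventions, where a choice had to be made:

- rows are 0-based, the normal-row index `y_pi4` may be fractional and may
  lie outside the frame; pixel centers carry coordinates;
- the in-line coordinate `x` in `pixel_to_object` is a *signed offset in
  pixels from the central column*; the scan image's own column index is
  converted by subtracting `(n_cols − 1)/2`;
- `linear_range(tol)` inverts the edge condition `1/cos γ − 1 = tol`
  in closed form (`γ_half = arccos(1/(1 + tol))`), valid for
  `tol < √2 − 1`;
- rectification resamples a uniform object-plane grid by inverse-mapping
  through the tangential model with bilinear interpolation and an explicit
  validity mask; there is no extrapolation.

The spec sheet's "rotation range π/8 rad" is exposed simply as the γ
half-width parameter; the package takes no position on whether a degree
figure elsewhere was intended, since the half-width is user-settable.

### Geometry estimation

`fit_geometry` maps detected grid-line rows through the tangential model
and adjusts `(r, y_pi4, grid offset)` by Levenberg–Marquardt so the mapped
positions match a uniform ladder of known pitch.  It assumes the detected
edges are *consecutive* grid lines; targets whose line width is below the
object-plane row pitch can drop lines and must be detected with a
different strategy.  The fit is exact (machine precision) on noiseless
inputs and its residual series feeds the noise analysis.

`residual_noise_sigma` separates a smooth deterministic component (e.g. a
cosine-like misalignment trace) from Gaussian noise: Fourier bins whose
power exceeds 3× the median bin power are attributed to the trend and
their amplitude is clipped down to the average noise power density
(estimated from the unclipped bins, phase preserved); a Gaussian PDF is
then fitted to the histogram of the remainder.  Clipping to the noise
floor rather than zeroing, plus an analytic correction for the power a
*pure-noise* signal loses when its own exponential-tail bins are clipped,
keeps the estimator unbiased under the no-trend null — plain zeroing
removes ≈30% of the noise power at this threshold and biases σ̂ low by
≈16%.  The 3× factor itself is a robustness choice: low enough to catch a
trend concentrated in very few bins, high enough that only the tail of the
noise distribution is touched.

## Spectral and radiometric calibration

- **Wavelength axis**: ordinary least-squares polynomial
  `λ(p) = a₀ + a₁p + … + a_d p^d` on (pixel, nm) peak pairs; exact
  interpolation at `d + 1` pairs; monotonicity over the sensor range is
  checked and non-monotone fits are flagged rather than rejected.
- **Peak detection**: `scipy.signal.find_peaks` with a prominence
  threshold expressed as a fraction of the spectrum's dynamic range,
  refined by 3-point parabolic interpolation.  Whether a close doublet
  splits depends on that threshold; both behaviours are tested.
- **Peak ↔ known-line matching**: greedy one-to-one nearest-neighbour in
  wavelength (ties broken by peak intensity), with the match radius set to
  half the line separation under test.  The exact identification protocol
  used at a real calibration bench is instrument-specific; this matcher is
  a reasonable stand-in and is exercised only on synthetic spectra.
- **Resolution bound**: the smallest separation among adjacent known-line
  pairs for which two *distinct* matched peaks exist, returned with the
  witness pair.  With ~3 nm optical blur a 2.1 nm doublet merges, so the
  bound lands at the next-wider pair — mirroring how a physical bound is
  established.
- **Channel counts**: nearest-integer rounding, half away from zero
  (1088 px / 5 px per channel → 218; 600 nm / 3 nm → 200).
- **Dark model**: per-pixel closed-form OLS of counts against exposure;
  pixels with slope above 5× the median slope are flagged hot (a
  robust-relative threshold; absolute slopes depend on sensor gain).
  Subtraction clamps at zero and is deliberately not idempotent.
- **Reflectance**: `(raw − dark)/(white − dark)` with masking where the
  white reference does not exceed the dark prediction — the standard
  flat-field form; the choice of formula is ours, as only the required
  references (two white captures) are conventionally specified.
- **SNR**: `10·log₁₀(μ̂/σ̂²)` per (exposure, wavelength) cell, with the
  maximum-likelihood (1/N) variance by default (`ddof` switchable).  Note
  the estimator divides a mean by a variance, so its value depends on the
  intensity scale — it is used as a *relative* quality profile across
  exposure and wavelength, not as an absolute power ratio.  Zero-variance
  cells carry an infinite-SNR sentinel and are excluded from aggregates.
- **Stability**: linear trend over the tail half of the trace (skipping
  warm-up); "stable" means |slope| below 10⁻⁴ of the tail mean per
  second, i.e. under ~1% drift over a 100 s scan.

## The synthetic scanner

The signal chain is the minimal model linear in exposure time:

```
counts = clip(round(gain·T_exp·reflectance·illuminant + a_ij·T_exp + b_ij + N(0, σ²)), 0, 2^b − 1)
```

with per-line mirror angle `θ_row + N(0, σ_step²)`, optional cosine
misalignment in object coordinates, hot-pixel planes (a random fraction of
sensor pixels with large dark slope), 8- or 12-bit quantization, and
per-line wall times drawn from the timing model.  One global seed spawns
deterministic per-component substreams (`numpy` `SeedSequence`), so a
fixed seed yields bit-identical cubes and logs.

Defaults mirror a representative built device: 19 200 steps per mirror
revolution, 1200×1200 frame whose 1200 rows at one step per row sweep γ
over exactly [−π/8, +π/8], r = 348.73 mm, Δx = 0.1 mm, Ω = 1.019, 8/12-bit
depth.  Tests and examples use reduced row counts with the microstep
factor scaled by `1200/n_rows` so the angular span — and therefore the
distortion regime — is unchanged; typical sizes are 240–480 rows × 32–64
columns × 1–8 channels, which keep the full suite in seconds.

- **Area sampling.** Each line averages the scene over `antialias = 8`
  sub-row mirror angles, emulating the sensor's integration over the line
  dwell.  Pointwise sampling would snap scene edges to the row grid and
  destroy the sub-pixel edge information that the geometry fits rely on;
  with area sampling, edge positions land in the gray levels and
  half-level edge interpolation recovers them to a small fraction of a
  row.
- **Gain.** No count-per-watt law is modeled; `gain_counts` (counts per
  second per unit reflectance·illuminant) is a free parameter, not a claim
  about any device.
- The misalignment term is an optional cosine of one period across the
  scan — a stand-in for slowly varying mechanical misalignment of
  unspecified functional form, present so the trend-separation estimator
  has something realistic to remove.

What the simulator does **not** emulate — and what passing recovery tests
therefore do not show about real hardware: optical PSF/defocus (the path
elongation is computed but not rendered as blur), lens intrinsic
distortion, backlash hysteresis (assumed minimized by drive design; only
Gaussian jitter remains), photon shot noise (noise is additive and
signal-independent), nonlinear hot-pixel behaviour, spectrograph smile and
keystone, motion artifacts of living subjects, and real OS/driver delay
distributions.

## Color

CIE 1931 2° color matching functions are evaluated from the published
piecewise-Gaussian analytic approximation (Wyman, Sloan & Shirley 2013),
accurate to about 1% of peak — ample for qualitative color
reconstruction.  XYZ is a rectangle-rule integral on the cube's native
wavelength axis; the image is normalized per-channel in linear RGB so that
the chosen white reference maps exactly to RGB white (the flat-field
convention; it also sidesteps the E-vs-D65 white-point mismatch for
synthetic flat spectra), then converted with the standard D65 XYZ→sRGB
matrix, gamma-encoded and clipped.

## File formats

ENVI (text `.hdr` + raw binary), the de facto hyperspectral exchange
format: BIL/BIP/BSQ read, BIL written, uint8/uint16/int16/float32/float64
bodies, wavelength array and acquisition metadata carried in the header.
Timing logs are CSV with fixed columns
(`t_exp_s, wall_s, t_rx_s, t_api_s, t_mcpy_s, t_act_s, bit_depth,
scenario`); peak tables are 2-column CSV; geometry configs are TOML or
JSON; the spec-sheet report is JSON (snake_case keys with `_units`
companions, absent sections reported as null, never fabricated) or
markdown.

## Known limitations

- `fit_geometry` requires consecutive detected grid lines and at least 3
  of them; identifiability of `r` versus the grid offset rests on the
  tangential curvature, so edges confined to a nearly-linear neighbourhood
  of the normal point yield ill-conditioned fits.
- `detect_grid_rows` assumes line-dominated profiles with a bimodal
  intensity distribution; textured scenes need a different detector.
- The SNR figure inherits the scale-dependence of mean/variance; compare
  cells only within a consistently calibrated profile.
- The rectifier interpolates intensities; it does not conserve flux.
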