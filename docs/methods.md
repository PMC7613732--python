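# Methods

## The measurement chain

Interference reflection microscopy (IRM) encodes the distance `h` between
the basal plasma membrane and the coverslip in the reflected intensity via
two-beam thin-film interference,

    I(h) = i_mid − amp · cos(4π n h / λ),

with `i_mid = (i_max + i_min)/2`, `amp = (i_max − i_min)/2`, medium
refractive index `n` (default 1.337) and illumination wavelength `λ`
(default 546 nm, a green interference filter).  `I` rises monotonically
from `i_min` at contact to `i_max` at the *first-branch* edge
`h_b = λ/(4n) ≈ 102 nm` and reverses beyond, so only first-branch pixels
are invertible.  Because net reflectivity differs from cell to cell, a
bank of `(i_min, i_max)` calibration curves is kept and the nearest one
(Euclidean distance on the intensity extremes, ties to the lowest index)
is selected per cell.

Inversion policy: a pixel whose intensity leaves `[i_min, i_max]` in *any*
frame is masked for the entire series — masking rather than clamping,
because clamping would bias fluctuation amplitudes downward.  All temporal
statistics therefore operate on complete series.

## Fluctuation amplitudes

Analysis is tiled into first-branch regions (FBRs): square pixel blocks
(4, 12 or 24 px; 12 px default) fully in-branch for the whole movie, with
abnormally quiet or noisy pixels excluded by quantile thresholds on the
per-pixel temporal SD (defaults 0.05/0.95; the field's practice excludes
focal adhesions and interior organelle signal this way but publishes no
numbers).  Two amplitudes are computed with the sample (n−1) convention:

* `SD_time` — per-pixel SD over frames, averaged over the tile (nm);
* `SD_space` — per-frame SD over the tile's pixels, averaged over the
  first 20 frames (nm).

Intracellular heterogeneity is summarised as the SD of a per-FBR statistic
and its mean-normalized SD (SD divided by the mean), which removes the
effect of a shifting mean when comparing conditions.

## Spectral model

The temporal power spectral density of the height at a point, for a
membrane with bending rigidity `κ`, tension `σ`, harmonic confinement `γ`
and effective medium viscosity `η_eff`, driven at `A` times the thermal
level, is a superposition of Lorentzians over spatial modes `q`:

    PSD(f) = (4 η_eff A k_B T / π) ∫_{q_min}^{q_max} dq /
             [ (4 η_eff · 2πf)² + E(q)² ],
    E(q)   = κq³ + σq + γ/q ,

each mode relaxing at `E(q)/(4 η_eff)`.  We read this as the one-sided
density; with that convention the per-mode stationary variance consistent
with the integral is `A·k_BT / (2 L² (κq⁴ + σq² + γ))` on a patch of area
`L²` — half the equipartition value, i.e. the amplitude convention is
absorbed into `A`, which is a fitted scale anyway.  The confinement term
`γ/q` (not `γq`, which would merely duplicate the tension term) flattens
the low-frequency spectrum; a `confinement_form` switch retains the
alternative.  `κ` is held at 15 k_BT and `T` at 310.15 K
(k_BT = 4.28e−21 J) throughout; neither is fitted.

Limits used as oracles: with `κ = γ = 0` and an unbounded `q` range the
integral collapses to `A k_B T / (4π σ f)` (log–log slope −1); with only
`κ` active the spectrum scales as `f^(−5/3)`.  The "exponent" statistic —
the slope of log power vs log frequency over 0–10 Hz — interpolates
between these and becomes shallower at low frequency as confinement grows.

### Numerical evaluation

The `q` integral is evaluated by Gauss–Legendre quadrature in `log q`
(default 200 nodes; 128 inside fits), vectorised jointly over frequencies
and nodes; against a 10⁶-node trapezoid it agrees to better than 1e−8
relative, far inside the 0.1 % target, at about three orders of magnitude
less cost than adaptive quadrature per frequency — which is what makes
per-pixel tension maps practical.

### Finite fields of view

A patch of N pixels has discrete undulation modes; when N is small the
handful of low-`q` modes is misrepresented by the continuum integral (up
to ~25 % at the lowest frequencies for a 32-pixel patch in a
tension-dominated state).  `model_psd_modes` therefore provides the
lattice-sum counterpart (degenerate modes grouped by |q|), optionally with
the exact camera sampling/exposure transfer folded in, and `fit_psd` can
fit it by passing the patch geometry.  The continuum form remains the
default and the published-model reference.

## PSD estimation

`estimate_psd_fft` is a one-sided boxcar periodogram of the mean-removed
series (optionally Welch segment-averaged); `sum(power)·Δf` equals the
series variance exactly (Parseval).  `estimate_psd_ar` fits an AR model by
conditional least squares (the covariance method) and evaluates its
rational spectrum on the same frequency grid; unstable fits raise rather
than returning a spectrum.  The 0 Hz bin is excluded everywhere.

Cameras integrate over the exposure window, attenuating the spectrum by
`sinc²(f·t_exp)`; `exposure_correct` divides it back out.  The correction
is exact for slow modes and degrades only in the top half-octave below
Nyquist.  White detection noise enters *after* integration, so in
exposure-corrected spectra it rises as `1/sinc²`; fits accept a fixed
noise-floor term (nm²/Hz) computed from the camera noise SD and the
calibration slope at mid-branch (`2·dt·(noise_sd/(dI/dh))²`), the way a
dark-frame calibration would supply it.  Fitting the floor as a free
parameter is supported but discouraged — at single-FBR signal-to-noise it
destabilises the fit.

## Fitting and identifiability

Fits minimise least squares on `log10(power)` over 0.1–10 Hz (the
spectrum spans decades; the log residual weighs them evenly), with
parameters in log space to enforce positivity, three canned starts
spanning the physiological range, and the active temperature initialised
by matching geometric-mean power (it is a pure prefactor).  By default the
spectrum is averaged into log-spaced bands (16 per decade) before
fitting; the model is averaged over the *same* member frequencies, so
binning introduces no systematic offset between data and model.  Raw-bin
fitting (`bins_per_decade=None`) is statistically preferable when bin
noise is independent, e.g. for model-curve replicates.

The four-parameter family has an exact soft direction: rescaling
`(σ, γ, η_eff, A)` by a common factor leaves the spectrum unchanged
wherever the fixed-`κ` term is negligible.  Absolute parameters are
therefore identifiable only when the tension→bending crossover
(`q_t = √(σ/κ)`, crossing at frequency `σ q_t / (2 η_eff · 2π)`) lies
inside the fitted band.  Even then, correlated low-frequency noise slides
single-region estimates along the soft direction by tens of percent while
leaving ratios such as `σ/η_eff` tight.  Tension *maps* consequently use a
global-then-local strategy (`global_medium`, default on): the medium
parameters `(γ, η_eff, A)` are fitted once on the pooled movie spectrum,
then only `σ` is refit per pixel or block (`fit_sigma_only`).  Relative
tension between regions is then insensitive to the global scale
uncertainty; the map's absolute scale inherits it.  `r²` is computed in
log space and map entries below the acceptance threshold (default 0.8)
are left missing.

## The synthetic-data generator

Movies are synthesised mode by mode on periodic patches: each spatial
Fourier mode is an independent complex Ornstein–Uhlenbeck process with the
relaxation rate and stationary variance given above, sampled exactly in
its stationary state and advanced by the exact discrete-time update.
Hermitian symmetry (a real height field) is maintained by driving the
update with FFTs of white real-space noise.  Recorded frames are the exact
time averages over the exposure window (OU-bridge decomposition), matching
what an integrating detector sees; instantaneous sampling is available and
demonstrates the aliasing such a detector avoids.  Multi-region scenes
tile the grid with independent patches (modes do not couple across
seams) — physically, domains pinned at micrometre scale.

Default study conditions: σ = 1.2e−5 N/m, γ = 1e5 N/m³, η_eff = 4 Pa·s,
A = 1, κ = 15 k_BT, 180-nm pixels, 20 frames/s, 2048 frames, mean height
50 nm (mid-branch).  These place the membrane in a tensed adherent state
whose tension→bending crossover sits near 4 Hz — inside the acquisition
band, hence identifiable — and whose per-pixel SD (≈ 9.6 nm) keeps
±4.7 SD inside the first branch so movies render and invert without
masking loss.  The camera model is additive Gaussian noise (SD 0.5 camera
units against a 100-unit branch swing); rendering applies the physical
cosine at any height when asked (`strict=False`), so the rare excursion
past the branch folds back by its small overshoot exactly as in real
recordings, while the strict default refuses to render out-of-branch
fields.

Puncta scenes plant non-overlapping disks (centres at least one diameter
plus two pixels apart, rejection-sampled with a bounded retry budget) of
given amplitude on a uniform background, Gaussian-blur the puncta layer
(blur conserves total added intensity, emulating cluster diffusion) and
add noise.  Cohorts draw per-cell lognormal baseline tensions (CV 0.3
about 2e−7 N/m), plant 24-h dips (fold change 0.55–0.75, 80 % recovering
above baseline by 48 h), drift non-dipped cells mildly upward, couple fate
to dips with a configurable probability, and apply multiplicative
measurement noise (CV 0.05 by default — per-cell medians pool thousands of
FBRs and are tight).  All generators are bit-reproducible from their seed.

What the generator does not emulate: frequency-dependent (non-equilibrium
burst) activity, focal adhesions or organelle-induced heterogeneity within
a patch, photobleaching, shot noise, drift, or live↔fixed registration
error.  Passing tests therefore validate the measurement and inference
chain under the stated model, not robustness to those real-data effects.

## Validation experiment sizes

The bundled experiments (`memfluct.experiments`, reported by
`scripts/acceptance.py`) use: 50 model-curve replicates at 5 %
multiplicative noise for parameter recovery; one 64×64×2048-frame
two-region movie (σ vs 2σ) analysed by per-region pooled fits plus 256
σ-only FBR refits for the tension-contrast ratio; 20 random parameter sets
against the 10⁶-node quadrature oracle; 20 random 64-frame series against
the direct DFT; a 12-disk planted puncta scene at noise SD 5; and a
200-cell cohort at dip prevalence 0.6 and dip–fate coupling 0.8.

## Known limitations

* Absolute mechanical parameters from a single small region carry the
  soft-direction uncertainty described above; treat map scales as
  relative unless the pooled fit is well anchored.
* The exposure correction and the sampled-model transfer disagree with
  reality in the top half-octave below Nyquist; fits weight that region
  like any other, which is visible only when the crossover sits there.
* `γ` is reported but effectively unconstrained whenever its knee
  `√(γ/σ)` falls below the smallest resolved wave number.
* The AR estimator inherits the order-selection problem; the default
  order (24) suits 2048-frame series and smooth spectra.
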