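# memfluct

Membrane fluctuation spectroscopy from interference reflection microscopy
(IRM) movies — for cell biophysicists quantifying how plasma-membrane
mechanics change during processes such as myoblast fusion.

IRM encodes the height `h` of the basal membrane above the coverslip in
the reflected intensity, `I(h) = i_mid − amp·cos(4πnh/λ)`, which is
invertible on the first interference branch (0 to λ/4n ≈ 100 nm).
`memfluct` converts intensity movies to height movies, quantifies
temporal fluctuations (SD_time) and spatial undulations (SD_space) on
first-branch regions (FBRs), and extracts membrane mechanics by fitting
the height power spectral density with a Helfrich-based model

    PSD(f) = (4 η_eff A k_B T / π) ∫ dq / [ (4 η_eff 2πf)² + (κq³ + σq + γ/q)² ]

for the fluctuation tension σ (N/m), confinement γ (N/m³), effective
viscosity η_eff (Pa·s) and active temperature A, with the bending
rigidity κ fixed at 15 k_BT.  On top of that sit per-pixel tension maps,
fluorescence puncta (cluster) quantification with cluster-to-background
intensity ratios, region-wise tension–fluorescence rank correlations, and
longitudinal cohort metrics (fusion index, per-cell normalisation, 24-h
tension "dips", dip-by-fate tables).  A ground-truth synthetic-data
generator — exact Ornstein–Uhlenbeck synthesis of every membrane mode,
rendered through the IRM relation with camera noise — validates the whole
chain end to end.

## Worked example

Simulate a tensed membrane patch, image it through the IRM chain, and
recover its mechanics:

```python
import math
import numpy as np
from memfluct import (
    CalibrationCurve, SceneSpec, simulate_height_movie, render_irm,
    build_height_movie, select_fbrs, sd_time, sd_space,
    exposure_correct, fit_psd,
)
from memfluct.spectra import estimate_psd_fft_stack

# synthetic ground truth: a tensed membrane patch imaged at 20 frames/s
spec = SceneSpec(grid=(24, 24), n_frames=2048, seed=7)
truth = spec.param_regions[0][1]
movie, _ = simulate_height_movie(spec)

# render to IRM intensities with camera noise, invert back to heights
curve = CalibrationCurve(i_min=100.0, i_max=200.0)
stack = render_irm(movie, curve, noise_sd=0.5, seed=8, strict=False)
heights = build_height_movie(stack, curve, dt=spec.dt, pixel_size=spec.pixel_size)

# fluctuation amplitudes on 12x12-pixel first-branch regions
fbrs = select_fbrs(heights, tile_size=12, low_q=0.0, high_q=1.0)
tile = fbrs.tiles[0]
print(f"FBRs selected: {len(fbrs)}")
print(f"SD_time  = {sd_time(heights, tile):5.2f} nm")
print(f"SD_space = {sd_space(heights, tile):5.2f} nm")

# tile-averaged PSD, exposure-corrected, fitted with the finite-patch
# Helfrich model plus the known camera noise floor
px = np.asarray(heights.heights[:, :12, :12]).reshape(2048, -1)
psd = exposure_correct(estimate_psd_fft_stack(px, spec.dt), spec.dt)
didh = curve.amplitude * 4 * math.pi * curve.refractive_index / curve.wavelength
floor = 2 * spec.dt * (0.5 / didh) ** 2
fit = fit_psd(psd, mode_shape=spec.grid, pixel_size=spec.pixel_size,
              sampled=True, noise_floor=floor)
print(f"exponent (0-10 Hz)  = {fit.exponent:6.2f}")
print(f"tension sigma       = {fit.sigma:.2e} N/m  (truth {truth.sigma:.2e})")
print(f"viscosity eta_eff   = {fit.eta_eff:6.2f} Pa s   (truth {truth.eta_eff:.2f})")
print(f"active temperature  = {fit.a_active:6.2f}        (truth {truth.a_active:.2f})")
print(f"fit r^2             = {fit.r2:6.3f}")
```

Output:

```
FBRs selected: 4
SD_time  =  7.85 nm
SD_space =  6.02 nm
exponent (0-10 Hz)  =  -1.23
tension sigma       = 1.19e-05 N/m  (truth 1.20e-05)
viscosity eta_eff   =   3.90 Pa s   (truth 4.00)
active temperature  =   0.97        (truth 1.00)
fit r^2             =  0.997
```

The membrane fluctuates with ~8-nm temporal amplitude; the spectrum's
log–log slope of −1.23 sits between the tension-dominated (−1) and
bending-dominated (−5/3) limits; and the fit recovers the planted tension
of 1.2e−5 N/m within 1 %.  `docs/methods.md` details the model, the
estimators, the identifiability structure of the four-parameter fit and
the generator's assumptions.

A `memfluct` command-line tool wraps the same library:
`calibrate`, `analyze` (FBR statistics), `map` (tension maps),
`clusters` (puncta), `cohort` (dip/fate metrics) and `simulate`.

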