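# Methods

## The measurement this package models

When a donor fluorophore transfers its excitation to an acceptor by FRET,
the emission of that *sensitized* acceptor is polarized along the acceptor
emission dipole, while the photoselection happened along the donor
absorption dipole. The fundamental anisotropy of the sensitized emission
therefore encodes the angle β between the two dipoles,

    r0 = 0.4 · (3 cos²β − 1) / 2,

independently of donor–acceptor distance. Measuring it cleanly requires
(i) efficient FRET despite a dim donor, (ii) removal of instrument
polarization bias, (iii) removal of rotational depolarization, and
(iv) removal of donor bleed-through into the acceptor detection band. Each
correction is a module here; the composition (observed anisotropy →
bleed-through compensation → Perrin → angle) is the package's core
pipeline.

## TCSPC reconvolution fitting (`faded.tcspc`)

Model: expected counts per channel are

    F_k = S · Σᵢ αᵢ (IRF ⊛ e^(−t/τᵢ))_k + B,

a discrete convolution of the measured, unit-normalised IRF with the
multi-exponential impulse response on the histogram grid. A timing offset
("shift", bounded to ±5 channels) displaces the IRF by linear
interpolation; Σαᵢ = 1 is enforced by fitting n−1 free fractions plus one
overall scale S, which removes the amplitude/intensity degeneracy.
Minimisation is Poisson-weighted least squares (per-channel variance
max(counts, 1)) via Levenberg–Marquardt (lmfit), over all channels.

Deterministic initialisation: the lifetime seed comes from log-linear
regression on the decay tail (the last 60% of post-peak channels above 1%
of the peak); multi-component seeds spread geometrically around it (×0.5/×2
for two components, ×0.25/×1/×4 for three); amplitudes start uniform; the
background starts at the mean of the pre-rise channels; the shift at zero.
Identical data therefore always produce identical fits.

Goodness of fit uses the Neyman statistic
χ²_red = Σ(obs−exp)²/max(obs,1) / (N_used − p). Channels with fewer than 10
expected counts are excluded from the statistic (not from the fit): direct
enumeration of E[(x−λ)²/max(x,1)] for Poisson x shows the Neyman weight is
biased low below λ ≈ 1 (≈0.6 at λ = 1) and high around λ ≈ 5 (≈1.6),
settling near 1 only above tens of counts, so near-empty channels would
corrupt the statistic even for the true model. The floor is a parameter of
`reduced_chi_square`.

Default grids mirror the two acquisition regimes: 4096 channels over
20 ns (or 40 ns) for cuvette work, 3125 channels × 16 ps for the
microscope. Discretisation note: the histogram convolution sums whole bins,
so its continuous counterpart is the exponentially-modified Gaussian
evaluated at the trailing bin edge; on a steeply rising edge the two differ
at sub-bin scale, which is irrelevant in practice because generator and
fitter share the same discrete operator. No scatter (zero-lifetime)
component is modelled; vendor binary formats and MLE variants are out of
scope.

## FRET arithmetic (`faded.photophysics`)

All lifetimes entering the efficiency are amplitude-weighted averages
τ̄ = Σαᵢτᵢ (intensity-weighted averages are not used anywhere). The
efficiency E = 1 − τ_dᴬ/τ_d⁰ and transfer time τ_T = (1/τ_dᴬ − 1/τ_d⁰)⁻¹
are algebraically linked through E = k_T/(k_T + 1/τ_d⁰); the package keeps
both forms and tests their identity. Rate constants use k_r = Φ/τ and
k_nr = 1/τ − k_r with lifetimes carried in ns and converted to s⁻¹ only at
this boundary. Only *relative* Förster-distance scaling
(R₀,a/R₀,b)⁶ = (κ²n⁻⁴Q_D J)_a/(κ²n⁻⁴Q_D J)_b is provided; absolute R₀ from
spectra is out of scope.

## Anisotropy and corrections (`faded.anisotropy`)

Steady-state and per-channel anisotropy use
r = f_corr·(I∥ − G·I⊥)/(I∥ + 2G·I⊥). G is measured on a reference dye of
zero anisotropy (G = I∥/I⊥); f_corr, the high-NA depolarization factor, is
the ratio of a low-NA reference measurement over the high-NA one. When both
f_corr and bleed-through compensation apply, f_corr is applied inside the
anisotropy formula first and compensation afterwards — an ordering
assumption, flagged here because the two operations do not commute.

Time-resolved anisotropy propagates shot noise to first order:
var(r) = (3Gf/T²)²·(Q²P + P²Q) with T = P + 2GQ, and masks channels whose
summed intensity falls below a threshold (default 10 counts) because the
variance diverges there. The rotational-correlation fit is a σ_r-weighted
mono-exponential r(t) = A·e^(−t/θ) restricted to t ≥ t_start (default 5 ns
after the pulse), excluding the fast FRET-displacement phase that is below
the instrument's time resolution; associated (per-species) anisotropy and
wobbling-in-cone models are out of scope. θ is bounded above at 10⁴ ns and
a fit at the bound is reported as "no decay detected".

Bleed-through compensation inverts the exact intensity-weighted mixing
r_obs = r_d·f_d + r_a·(1−f_d), giving r_a = (r_obs − r_d·f_d)/(1−f_d). The
default donor anisotropy is r_d = 0.35, the measured steady-state value of
the free dim donor across its emission band; default donor fractions come
from cumulative spectral unmixing above 530 nm (0.20 Ca²⁺-free, 0.09
Ca²⁺-bound for the high-affinity sensor). All are overridable.

The angle inversion uses the collinear-dipole prefactor 0.4 even though the
free donor measures r0 ≈ 0.35; the published angular displacements are
defined against the theoretical limit, and the discrepancy is stated here
as a known caveat rather than absorbed into the formula. Angles are
reported in degrees. Note the Perrin/angle chain is exactly invertible, so
round-trip identities are tested to numerical precision — except within
~0.01° of 0° and 90°, where dr0/dβ vanishes and double precision limits the
round trip to ~√ε.

## Spectral unmixing (`faded.unmixing`)

Two-endmember non-negative least squares (scipy NNLS) after resampling the
reference spectra onto the measured grid by linear interpolation (default
acquisition step 5 nm). Non-negativity is physically required even though
unconstrained least squares would often coincide. No baseline term by
default (cuvette spectra are baseline-corrected upstream); a constant
offset column is available by flag. The cumulative donor fraction over a
band is ∫c_d·D / ∫(c_d·D + c_a·A) by trapezoid with interpolated band
edges; the imaging channel band is 530–560 nm, the spectrograph band
530–620 nm, and the band is always an explicit argument. More than two
endmembers and phasor analysis are out of scope.

## Hill calibration (`faded.calibration`)

r(c) = r_free + (r_bound − r_free)·cⁿ/(K′_dⁿ + cⁿ), fitted by bounded
Levenberg–Marquardt with deterministic initialisation: r_free/r_bound from
the data extremes, K′_d from the concentration nearest the midpoint
response, n = 1. The fit is orientation-agnostic (rising or falling
titrations); concentrations are in nM throughout, and the fit is
equivariant under unit rescaling. Inversion
c = K′_d·((r_free − r)/(r − r_bound))^(1/n) is exact; read-outs at or
beyond the plateaus clamp to 0 or ∞ (the calibration cannot resolve
concentrations outside its dynamic range). Deep into saturation the forward
curve flattens, so float round-trips there are conditioned to ~10⁻⁶
relative rather than 10⁻⁹. Two bundled calibrations describe the
high-affinity (n = 1.9, K′_d = 71 nM, r 0.10 → −0.03) and low-affinity
(n = 1.6, K′_d = 502 nM, r 0.10 → −0.02) sensor variants; the bound-state
plateau of the high-affinity sensor is quoted as −0.02 or −0.03 in
different summaries of the same titration, and the bundled value −0.03 is
the one consistent with the compensated-anisotropy worked numbers. In-situ
titrations reuse the same fit; converting CaEGTA steps to free Ca²⁺ is the
caller's responsibility (buffer-kit tables).

## Imaging (`faded.imaging`)

Per-pixel anisotropy maps apply the corrected ratio formula per frame and
mask pixels with total intensity below 50 counts (below which anisotropy
variance explodes). ROI traces are computed from the corrected ratio of
ROI-*summed* intensities, not the mean of per-pixel anisotropies — the
ratio-of-sums is the lower-variance estimator and avoids low-count bias;
for this reason `roi_trace` operates on the raw polarized stack. Pixel
coordinates are 0-based row-major; frames are 0-based. Bleed-through
compensation and calibration inversion are applied at the trace level (a
per-pixel donor fraction is unobservable with a single spectral channel).

Display processing upsamples frames ×2 (200×200 → 400×400), then applies a
spatio-temporal Gaussian (σ = 0.75 post-resize pixels, 2 frames) with
reflective boundaries to avoid dark rims; masked pixels are handled by
normalised convolution so valid regions are not darkened by their masked
neighbours. IMD rendering maps anisotropy clipped to [0, 0.12] linearly
onto hue (span 0–2/3 of the wheel, red → blue, keeping the map
single-valued), full saturation, and brightness from the mean-intensity
frame, so zero-signal pixels are black regardless of anisotropy. Channel
SNR is the mean over temporal standard deviation of the ROI-summed signal
(infinite, flagged, for noiseless input). Segmentation, channel
registration and photobleaching correction are out of scope; ROIs are
supplied by the user or the generator.

## Synthetic data (`faded.simulate`)

The generators reproduce the statistical structure the analyses assume, at
the instrument's stated operating conditions:

* **IRF**: Gaussian, FWHM 42 ps, Poisson-sampled; zero width requests an
  ideal delta. Pulse position defaults to 10% into the window.
* **Decays**: the same convolution operator as the fitter, scaled to 10⁴
  peak counts (10⁵ for anisotropy pairs), Poisson-sampled.
* **Polarized pairs**: total intensity I(t) splits as I·(1+2r(t))/3
  parallel and I·(1−r(t))/3 perpendicular with r(t) = r0·e^(−t/θ) — the
  definitional inverse of the anisotropy formula, so G = f_corr = 1
  recovers the programmed r exactly in expectation; the measured
  perpendicular channel is divided by G. Note the depolarisation clock
  starts at the pulse, so the observed trace is r0·e^(−(t−t0)/θ).
* **Spectra**: Gaussian bands (donor peak 510 nm σ 18 nm, acceptor 528 nm
  σ 14 nm); the mixing weight is solved by bisection so the cumulative
  donor fraction over a requested band hits its target. No attempt is made
  to mimic real fluorescent-protein vibronic structure — the unmixing math
  is shape-agnostic, so tests on Gaussians say nothing about reference-
  spectrum quality in real experiments.
* **Titrations**: log-spaced concentrations, Hill curve plus Gaussian
  anisotropy noise (default σ_r = 0.003, 12 points over 1 nM–10 µM).
* **Cell movies**: elliptical cells on a dark background, 200×200 px with
  stimulus at t = 120 s by default; each cell follows an anisotropy program
  (rest 0.10 → stimulated 0.02, step or oscillation) converted to a free-
  Ca²⁺ program through the bundled calibration; pixels emit the polarized
  split plus uniform background, Poisson-sampled. No photobleaching, dark
  states, cell motion or focus drift are simulated, so passing recovery
  tests demonstrate correctness of the estimators under shot noise, not
  robustness to those real-world effects.

Every generator consumes a single seeded NumPy Generator, so identical
configurations produce identical data bit-for-bit.

## Test problem sizes

Recovery suites run at the real acquisition scales for decays
(4096-channel and 3125-channel grids, 50 seeds for lifetime recovery, 100
synthetic titrations for the Hill suite). Cell-movie tests use a 64×64
field with 40–80 frames — smaller than the 200×200 default, which changes
only the number of averaged pixels, not the per-pixel statistics.
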