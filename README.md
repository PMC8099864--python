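# faded

Quantifying FRET-induced **angular displacement** from sensitized-acceptor
fluorescence anisotropy, with a dim fluorescent donor suppressing
bleed-through.

Conventional FRET read-outs (intensity ratio, donor lifetime) report on
donor–acceptor *proximity*. The anisotropy of the *sensitized acceptor* —
the acceptor emission excited via energy transfer — instead encodes the
angle β between the donor absorption and acceptor emission transition
dipoles. This package implements the full analysis chain for that
measurement, as used with the dim Sapphire mutant "Geuda Sapphire"
(Φ ≈ 0.12, amplitude-weighted τ ≈ 0.92 ns) as donor, Venus-family acceptors,
and calmodulin-based Ca²⁺ sensors built on that pair:

* **TCSPC decay analysis** (`faded.tcspc`): multi-exponential reconvolution
  fitting of photon-count histograms against a measured instrument response,
  Poisson-weighted, with reduced-χ² diagnostics and amplitude-weighted
  lifetimes τ̄ = Σᵢ αᵢτᵢ.
* **FRET photophysics** (`faded.photophysics`): E = 1 − τ_dᴬ/τ_d⁰,
  τ_T = (1/τ_dᴬ − 1/τ_d⁰)⁻¹, rate-constant decomposition k_r = Φ/τ,
  k_nr = 1/τ − k_r, and relative Förster-distance scaling
  R₀ ∝ (κ²n⁻⁴Q_D J)^{1/6}.
* **Anisotropy** (`faded.anisotropy`): corrected steady-state anisotropy
  r = f_corr·(I∥ − G·I⊥)/(I∥ + 2G·I⊥), time-resolved r(t) with shot-noise
  error bars, mono-exponential rotational-correlation tail fits
  r(t) = A·e^(−t/θ), the Perrin relation r = r₀/(1 + τ/θ), donor
  bleed-through compensation r_a = (r_obs − r_d·f_d)/(1 − f_d), and the
  dipole-angle inversion r₀ = 0.4·(3cos²β − 1)/2.
* **Spectral unmixing** (`faded.unmixing`): non-negative least-squares
  decomposition of emission spectra into donor + acceptor references;
  per-wavelength donor fractions and the cumulative donor bleed-through f_d
  above a cutoff (the quantity that contaminates acceptor anisotropy).
* **Ca²⁺ calibration** (`faded.calibration`): four-parameter Hill fits
  r(c) = r_free + (r_bound − r_free)·cⁿ/(K′_dⁿ + cⁿ) of anisotropy
  titrations, and the exact inverse mapping anisotropy → free [Ca²⁺].
* **Anisotropy imaging** (`faded.imaging`): two-channel polarized image
  stacks → per-pixel anisotropy maps, intensity-modulated display (IMD)
  renders, ROI time traces from summed intensities, calibrated Ca²⁺ traces,
  and channel SNR.
* **Synthetic data** (`faded.simulate`): generators for every input kind at
  the instrument's operating conditions (10⁴ peak counts, ~42 ps FWHM IRF,
  4096-channel/20 ns and 3125-channel/50 ns grids, Hill-shaped titrations,
  shot-noise-limited polarized cell movies), all seed-deterministic.

Fitted models follow a Model-class / Results-object pattern (`DecayModel`,
`RotationalDiffusionModel`, `HillModel`, `SpectralUnmixer`; each `fit()`
returns a results object with estimates, uncertainties and `summary()`);
the closed-form operations are plain functions.

## Worked example

```python
from faded import *
from faded.simulate import *

# simulate a dim-donor decay at 10,000 peak counts and fit it
cfg = SimulationConfig(seed=7)
irf = make_irf(cfg)
decay = make_decay(GEUSAP_MODEL, irf, cfg)
print(DecayModel(decay, irf, n_components=2).fit().summary())

lt = FretLifetimes(tau_d0=0.92, tau_dA=0.22)
print(f"FRET efficiency: {fret_efficiency(lt):.2%}   transfer time: {transfer_time(lt):.2f} ns")

r0 = perrin_fundamental(compensate_bleed_through(-0.03, r_d=0.35, f_d=0.09),
                        tau=3.0, theta=33.0)
print(f"compensated bound-state r0 = {r0:.3f}  ->  beta = {angle_from_fundamental(r0):.1f} deg")
```

prints

```
Reconvolution decay fit
===============================================
components: 2    chi2_red: 1.054    converged: True
param              value       std err
-----------------------------------------------
alpha1            0.6831        0.0019
tau1 (ns)         0.5665        0.0024
alpha2            0.3169        0.0019
tau2 (ns)         1.6592        0.0036
shift (ns)       -0.0000        0.0001
background        0.0000        0.0194
-----------------------------------------------
amplitude-weighted lifetime: 0.9128 ns

FRET efficiency: 76.09%   transfer time: 0.29 ns
compensated bound-state r0 = -0.074  ->  beta = 62.7 deg
```

The fit recovers the generating bi-exponential (0.58 ns at 70%, 1.7 ns at
30%; τ̄ = 0.92 ns) within statistical error at χ²_red ≈ 1. The second block
is the dim-donor FRET arithmetic: a donor quenched from 0.92 ns to 0.22 ns
transfers 76% of its excitations with a 0.29 ns time constant. The third
block removes 9% residual donor bleed-through from a Ca²⁺-bound sensor's
acceptor anisotropy, undoes rotational depolarization via Perrin
(τ = 3.0 ns, θ = 33 ns), and inverts the fundamental anisotropy to the
donor→acceptor dipole displacement of 62.7°.

## Command line

```bash
faded simulate decay --out sim/            # synthetic decay + IRF + ground truth
faded fit-decay --decay sim/decay.tsv --irf sim/irf.tsv --n 2 --out report.json
faded fret --tau-d0 0.92 --tau-da 0.22
faded anisotropy steady --ipar 200 --iperp 100 --g 1.0 --fcorr 1.0
faded anisotropy decay --parallel p.tsv --perpendicular q.tsv --tail-start 5 --out rot.json
faded anisotropy angle --r0 -0.074
faded unmix --measured m.tsv --donor d.tsv --acceptor a.tsv --band 530:620 --out unmix.json
faded titrate --in titration.tsv --out cal.json
faded image --parallel p.tif --perpendicular q.tif --roi roi.json --out outdir/
```

Decays, spectra, titrations and traces travel as two-column delimited text;
image stacks as multi-frame TIFF; fit reports and calibrations as JSON.

## Documentation

`docs/methods.md` describes the models, their assumptions, default
parameters, numerical choices, and what the synthetic generators do and do
not emulate.
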