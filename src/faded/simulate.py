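"""Synthetic data generators for every input kind the toolkit analyses.

Each generator reproduces the statistical structure of the corresponding
measurement: Poisson-count TCSPC histograms convolved with a ~42 ps FWHM
Gaussian instrument response at 10,000 peak counts (10^5 for anisotropy
pairs), Gaussian-band emission spectra mixed to a requested donor
bleed-through fraction, Hill-shaped anisotropy titrations with Gaussian
read-out noise, and shot-noise-limited polarized image stacks of cells whose
cytosolic Ca2+ follows a programmed time course.

The defaults are the measurement conditions of the system the toolkit was
built around (dim-donor FRET constructs and their Ca2+ sensors); every
generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .anisotropy import CorrectionFactors
from .calibration import GEUSAPVC260_CALIBRATION, HillCalibration, TitrationTable, hill_model, invert_calibration
from .tcspc import (
    CUVETTE_GRID_20NS,
    DecayHistogram,
    InstrumentResponse,
    MultiExpModel,
    convolve_model,
)
from .unmixing import EmissionSpectrum, SpectralUnmixer, donor_fraction_cumulative

__all__ = [
    "SimulationConfig",
    "make_irf",
    "make_decay",
    "make_polarized_pair",
    "make_spectra",
    "make_titration",
    "make_cell_movie",
    "CellMovieConfig",
    "CellMovieTruth",
    "GEUSAP_MODEL",
    "SAPPHIRE_MODEL",
]

#: Bi-exponential decay of the dim donor (Geuda Sapphire): 0.58 ns (70%),
#: 1.7 ns (30%); amplitude-weighted lifetime 0.92 ns.
GEUSAP_MODEL = MultiExpModel(amplitudes=(0.7, 0.3), lifetimes=(0.58, 1.7))

#: Mono-exponential decay of the parent Sapphire: 3.3 ns.
SAPPHIRE_MODEL = MultiExpModel(amplitudes=(1.0,), lifetimes=(3.3,))

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SimulationConfig:
    """Shared generator settings; defaults mirror the cuvette acquisition."""

    seed: int = 0
    counts_peak: int = 10_000
    n_channels: int = CUVETTE_GRID_20NS[0]
    dwell: float = CUVETTE_GRID_20NS[1]
    irf_fwhm: float = 0.042
    irf_center: float | None = None  # default: 10% into the window
    irf_total_counts: int = 1_000_000

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def window(self) -> float:
        return self.n_channels * self.dwell

    @property
    def t0(self) -> float:
        return 0.1 * self.window if self.irf_center is None else self.irf_center


def _gaussian_irf_profile(config: SimulationConfig) -> np.ndarray:
    t = np.arange(config.n_channels) * config.dwell
    if config.irf_fwhm <= 0:
        profile = np.zeros(config.n_channels)
        profile[int(round(config.t0 / config.dwell))] = 1.0
        return profile
    sigma = config.irf_fwhm * FWHM_TO_SIGMA
    profile = np.exp(-0.5 * ((t - config.t0) / sigma) ** 2)
    return profile / profile.sum()


def make_irf(config: SimulationConfig, noiseless: bool = False) -> InstrumentResponse:
    """Gaussian instrument response (default FWHM 42 ps), Poisson-sampled.

    ``irf_fwhm = 0`` requests an ideal single-channel delta.  A FWHM below the
    channel dwell is badly sampled and triggers a warning.
    """
    if 0 < config.irf_fwhm < config.dwell:
        import warnings

        warnings.warn("IRF FWHM below one channel dwell: profile is under-sampled")
    profile = _gaussian_irf_profile(config) * config.irf_total_counts
    counts = profile if noiseless or config.irf_fwhm == 0 else config.rng().poisson(profile)
    return InstrumentResponse(
        counts=np.asarray(counts, dtype=float),
        dwell=config.dwell,
        fwhm_estimate=config.irf_fwhm,
    )


def make_decay(
    model: MultiExpModel,
    irf: InstrumentResponse,
    config: SimulationConfig,
    noiseless: bool = False,
) -> DecayHistogram:
    """Reconvolved multi-exponential histogram scaled to ``counts_peak`` at its
    maximum, then Poisson-sampled."""
    curve = convolve_model(model, irf, scale=1.0)
    shape = curve - model.background
    peak_target = config.counts_peak - model.background
    expected = shape * (peak_target / shape.max()) + model.background
    counts = expected if noiseless else config.rng().poisson(np.clip(expected, 0, None))
    return DecayHistogram(counts=np.asarray(counts, dtype=float), dwell=config.dwell)


def make_polarized_pair(
    total_model: MultiExpModel,
    r0_fast: float,
    theta: float,
    config: SimulationConfig,
    corr: CorrectionFactors = CorrectionFactors(),
    irf: InstrumentResponse | None = None,
    noiseless: bool = False,
) -> tuple[DecayHistogram, DecayHistogram]:
    """Polarized decay pair for an anisotropy r(t) = r0_fast exp(-t/theta).

    The total (magic-angle) intensity decay follows ``total_model``; the
    channels split as I_par = I (1 + 2r)/3 and I_perp = I (1 - r)/3, with the
    detection-efficiency asymmetry applied to the measured perpendicular
    channel (divided by G).  Each impulse-response channel is convolved with
    the IRF separately and Poisson-sampled.  ``counts_peak`` sets the peak of
    the parallel channel.
    """
    if abs(r0_fast) > 0.4:
        raise ValueError("fundamental anisotropy magnitude cannot exceed 0.4")
    if theta <= 0:
        raise ValueError("rotational correlation time must be positive")
    if irf is None:
        irf = make_irf(replace(config, seed=config.seed + 101))
    t = irf.time_axis
    kernel = irf.normalized()
    intensity = np.zeros_like(t)
    for alpha, tau in zip(total_model.amplitudes, total_model.lifetimes):
        intensity += alpha * np.exp(-t / tau)
    r_t = r0_fast * np.exp(-t / theta)
    n = t.size
    par = fftconvolve(kernel, intensity * (1.0 + 2.0 * r_t) / 3.0)[:n]
    perp = fftconvolve(kernel, intensity * (1.0 - r_t) / 3.0)[:n] / corr.G
    scale = config.counts_peak / par.max()
    par, perp = np.clip(par * scale, 0, None), np.clip(perp * scale, 0, None)
    if not noiseless:
        rng = config.rng()
        par = rng.poisson(par).astype(float)
        perp = rng.poisson(perp).astype(float)
    return (
        DecayHistogram(counts=par, dwell=config.dwell),
        DecayHistogram(counts=perp, dwell=config.dwell),
    )


# -- emission spectra ----------------------------------------------------

def _gaussian_band(grid, peak, sigma):
    return np.exp(-0.5 * ((grid - peak) / sigma) ** 2)


def make_spectra(
    target_donor_fraction: float = 0.20,
    band: tuple = (530.0, 620.0),
    grid: np.ndarray | None = None,
    donor_peak: float = 510.0,
    donor_sigma: float = 18.0,
    acceptor_peak: float = 528.0,
    acceptor_sigma: float = 14.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[EmissionSpectrum, EmissionSpectrum, EmissionSpectrum]:
    """(donor_ref, acceptor_ref, mixture) Gaussian-band spectra.

    The mixture weight is solved by bisection so that the cumulative donor
    fraction of the mixture over ``band`` equals ``target_donor_fraction``.
    The default 5 nm grid step matches spectral-imaging acquisition.
    """
    if not 0 <= target_donor_fraction <= 1:
        raise ValueError("target donor fraction must lie in [0, 1]")
    if grid is None:
        grid = np.arange(440.0, 681.0, 5.0)
    donor = EmissionSpectrum(grid, _gaussian_band(grid, donor_peak, donor_sigma), "donor")
    acceptor = EmissionSpectrum(
        grid, _gaussian_band(grid, acceptor_peak, acceptor_sigma), "acceptor"
    )

    def band_fraction(w: float) -> float:
        mix = EmissionSpectrum(grid, w * donor.intensities + (1 - w) * acceptor.intensities)
        res = SpectralUnmixer(mix, donor, acceptor).fit()
        return donor_fraction_cumulative(res, *band)

    lo, hi = 0.0, 1.0
    if target_donor_fraction <= 0:
        w = 0.0
    elif target_donor_fraction >= 1:
        w = 1.0
    else:
        for _ in range(60):
            w = 0.5 * (lo + hi)
            if band_fraction(w) < target_donor_fraction:
                lo = w
            else:
                hi = w
        w = 0.5 * (lo + hi)
    mixture = w * donor.intensities + (1 - w) * acceptor.intensities
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        mixture = np.clip(
            mixture + rng.normal(0.0, noise_sigma * mixture.max(), mixture.size), 0, None
        )
    return donor, acceptor, EmissionSpectrum(grid, mixture, "mixture")


# -- titrations ----------------------------------------------------------

def make_titration(
    cal: HillCalibration = GEUSAPVC260_CALIBRATION,
    n_points: int = 12,
    conc_range: tuple = (1.0, 10_000.0),
    sigma_r: float = 0.003,
    seed: int = 0,
) -> TitrationTable:
    """Log-spaced Hill-model titration with Gaussian anisotropy noise."""
    conc = np.logspace(np.log10(conc_range[0]), np.log10(conc_range[1]), n_points)
    r = hill_model(conc, cal)
    if sigma_r > 0:
        r = r + np.random.default_rng(seed).normal(0.0, sigma_r, n_points)
    sigma = np.full(n_points, sigma_r) if sigma_r > 0 else None
    return TitrationTable(concentrations=conc, anisotropies=r, sigma=sigma)


# -- cell movies ---------------------------------------------------------

@dataclass
class CellMovieTruth:
    """Ground truth accompanying a synthetic movie: per-cell ROI masks and programs."""

    roi_masks: list
    r_programs: np.ndarray  # (n_cells, n_frames)
    conc_programs: np.ndarray  # (n_cells, n_frames), nM
    times: np.ndarray


@dataclass(frozen=True)
class CellMovieConfig:
    """Scenario for a stimulated-cell movie (defaults: 200x200 px, stimulus at 120 s)."""

    seed: int = 0
    shape: tuple = (200, 200)
    n_frames: int = 150
    frame_interval: float = 2.0
    n_cells: int = 3
    stimulus_time: float = 120.0
    r_rest: float = 0.10
    r_stim: float = 0.02
    oscillation_period: float = 0.0  # s; 0 = plain step
    cell_intensity: float = 1000.0  # expected total counts/pixel/frame inside a cell
    background: float = 5.0
    corrections: CorrectionFactors = field(default_factory=CorrectionFactors)
    calibration: HillCalibration = field(default_factory=lambda: GEUSAPVC260_CALIBRATION)


def _cell_program(cfg: CellMovieConfig, times: np.ndarray, rng) -> np.ndarray:
    """Anisotropy time course: rest, then step (optionally oscillating) after stimulus."""
    r = np.full(times.size, cfg.r_rest)
    after = times >= cfg.stimulus_time
    if cfg.oscillation_period > 0:
        phase = 2 * np.pi * (times[after] - cfg.stimulus_time) / cfg.oscillation_period
        mod = 0.5 * (1 - np.cos(phase))  # 0 at stimulus, swings between rest and stim
        r[after] = cfg.r_rest + (cfg.r_stim - cfg.r_rest) * mod
    else:
        r[after] = cfg.r_stim
    return r


def make_cell_movie(cfg: CellMovieConfig = CellMovieConfig()):
    """Shot-noise-limited polarized movie of elliptical cells with programmed Ca2+.

    Each cell's anisotropy program is converted to a free-Ca2+ program through
    the configured Hill calibration (the ground truth carries both).  Per
    frame, the cell interior emits ``cell_intensity`` expected total counts
    per pixel split as (1 + 2r)/3 parallel and (1 - r)/3 perpendicular; the
    measured perpendicular channel is divided by G; both channels are
    Poisson-sampled over a uniform autofluorescence background.

    Returns ``(stack, truth)``.
    """
    from .imaging import PolarizedImageStack  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    times = np.arange(cfg.n_frames) * cfg.frame_interval
    yy, xx = np.mgrid[0:h, 0:w]

    masks, programs = [], []
    occupied = np.zeros((h, w), dtype=bool)
    for _ in range(cfg.n_cells):
        cy, cx = rng.uniform(0.2 * h, 0.8 * h), rng.uniform(0.2 * w, 0.8 * w)
        ay, ax = rng.uniform(0.08, 0.16) * h, rng.uniform(0.08, 0.16) * w
        mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        if (mask & occupied).any():
            import warnings

            warnings.warn("synthetic cells overlap; traces from shared pixels will mix")
        occupied |= mask
        masks.append(mask)
        programs.append(_cell_program(cfg, times, rng))
    r_prog = np.asarray(programs)
    conc_prog = np.asarray([invert_calibration(p, cfg.calibration) for p in r_prog])

    G = cfg.corrections.G
    par = np.full((cfg.n_frames, h, w), cfg.background / 3.0 * 1.0)
    perp = np.full((cfg.n_frames, h, w), cfg.background / 3.0 / G)
    for mask, prog in zip(masks, r_prog):
        for k in range(cfg.n_frames):
            r = prog[k]
            par[k][mask] += cfg.cell_intensity * (1.0 + 2.0 * r) / 3.0
            perp[k][mask] += cfg.cell_intensity * (1.0 - r) / 3.0 / G
    stack = PolarizedImageStack(
        parallel=rng.poisson(par).astype(float),
        perpendicular=rng.poisson(perp).astype(float),
        frame_interval=cfg.frame_interval,
        corrections=cfg.corrections,
    )
    truth = CellMovieTruth(
        roi_masks=masks, r_programs=r_prog, conc_programs=conc_prog, times=times
    )
    return stack, truth
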