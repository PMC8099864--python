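"""Steady-state and time-resolved fluorescence anisotropy.

Anisotropy is computed from polarised intensity pairs with two instrument
corrections,

    r_corr = f_corr * (I_par - G * I_perp) / (I_par + 2 G I_perp),

where G compensates the unequal detection efficiency of the two polarisation
channels (measured on a zero-anisotropy reference dye) and f_corr undoes the
depolarisation introduced by high-NA objectives.  Rotational diffusion
depolarises the emission as r(t) = r0 exp(-t/theta); the Perrin equation
r = r0 / (1 + tau/theta) links the steady-state value to the fundamental
anisotropy r0, which in a FRET system encodes the angular displacement beta
between the donor absorption and acceptor emission dipoles through
r0 = 0.4 (3 cos^2 beta - 1)/2.

Donor bleed-through into the acceptor band mixes the donor anisotropy r_d
into the observed value with its intensity fraction f_d; the exact inverse
is r_a = (r_obs - r_d f_d) / (1 - f_d).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

from .tcspc import DecayHistogram

__all__ = [
    "PolarizedSignal",
    "CorrectionFactors",
    "AnisotropyDecay",
    "RotationalDiffusionResult",
    "RotationalDiffusionModel",
    "steady_state_anisotropy",
    "estimate_g_factor",
    "estimate_na_correction",
    "anisotropy_decay",
    "fit_rotational_correlation",
    "perrin_fundamental",
    "perrin_steady",
    "compensate_bleed_through",
    "angle_from_fundamental",
    "fundamental_from_angle",
    "DEFAULT_DONOR_ANISOTROPY",
    "DEFAULT_TAIL_START_NS",
    "THETA_UPPER_BOUND_NS",
]

#: Steady-state anisotropy of the free dim donor over its main emission band;
#: the default r_d for bleed-through compensation (overridable everywhere).
DEFAULT_DONOR_ANISOTROPY = 0.35

#: Start of the mono-exponential tail window for rotational-correlation fits,
#: ns; excludes the sub-resolution fast depolarisation phase after FRET.
DEFAULT_TAIL_START_NS = 5.0

#: theta values at or above this bound (ns) are reported as "no decay detected".
THETA_UPPER_BOUND_NS = 1e4

#: Collinear-dipole limit of the fundamental anisotropy used in the
#: angle inversion.  The free donor measures r0 ~= 0.35, but the angular
#: displacement formula uses the theoretical 0.4 prefactor; results carry
#: this as a stated caveat.
R0_PREFACTOR = 0.4


@dataclass(frozen=True)
class CorrectionFactors:
    """Instrument corrections: detection-efficiency ratio G and high-NA factor f_corr."""

    G: float = 1.0
    f_corr: float = 1.0

    def __post_init__(self):
        if self.G <= 0:
            raise ValueError("G must be positive")
        if self.f_corr <= 0:
            raise ValueError("f_corr must be positive")


@dataclass(frozen=True)
class PolarizedSignal:
    """A parallel/perpendicular intensity pair (counts or a.u.)."""

    I_parallel: float
    I_perpendicular: float

    def __post_init__(self):
        if self.I_parallel < 0 or self.I_perpendicular < 0:
            raise ValueError("intensities must be non-negative")


def steady_state_anisotropy(
    signal: PolarizedSignal, corr: CorrectionFactors = CorrectionFactors()
) -> float:
    """r = f_corr (I_par - G I_perp) / (I_par + 2 G I_perp)."""
    total = signal.I_parallel + 2.0 * corr.G * signal.I_perpendicular
    if total <= 0:
        raise ValueError("zero total intensity")
    return corr.f_corr * (signal.I_parallel - corr.G * signal.I_perpendicular) / total


def estimate_g_factor(reference_parallel: float, reference_perpendicular: float) -> float:
    """G from a reference fluorophore of true anisotropy zero: G = I_par/I_perp."""
    if reference_parallel <= 0 or reference_perpendicular <= 0:
        raise ValueError("reference intensities must be positive")
    return reference_parallel / reference_perpendicular


def estimate_na_correction(r_lowNA: float, r_highNA_obs: float) -> float:
    """f_corr from the same sample measured with low- and high-NA objectives."""
    if r_highNA_obs == 0:
        raise ValueError("observed high-NA anisotropy must be non-zero")
    return r_lowNA / r_highNA_obs


@dataclass
class AnisotropyDecay:
    """Per-channel anisotropy trace with Poisson-propagated uncertainty.

    Channels whose summed intensity falls below the construction threshold
    are masked (``mask`` True = usable).
    """

    time: np.ndarray
    r: np.ndarray
    sigma_r: np.ndarray
    total_intensity: np.ndarray
    mask: np.ndarray

    def usable(self, t_start: float = 0.0):
        sel = self.mask & (self.time >= t_start)
        return self.time[sel], self.r[sel], self.sigma_r[sel]


def anisotropy_decay(
    parallel: DecayHistogram,
    perpendicular: DecayHistogram,
    corr: CorrectionFactors = CorrectionFactors(),
    min_total: float = 10.0,
) -> AnisotropyDecay:
    """Per-channel r(t) from a polarised decay pair with shot-noise errors.

    The variance follows first-order propagation of independent Poisson counts
    through the anisotropy ratio:
    dr/dI_par = 3 G I_perp / T^2, dr/dI_perp = -3 G I_par / T^2 with
    T = I_par + 2 G I_perp (each scaled by f_corr).
    """
    if parallel.n_channels != perpendicular.n_channels or not np.isclose(
        parallel.dwell, perpendicular.dwell
    ):
        raise ValueError("parallel and perpendicular decays must share the same grid")
    P = parallel.counts
    Q = perpendicular.counts
    G, f = corr.G, corr.f_corr
    total = P + 2.0 * G * Q
    mask = total >= max(min_total, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = f * (P - G * Q) / total
        var = (3.0 * G * f / total**2) ** 2 * (Q**2 * P + P**2 * Q)
    r[~mask] = np.nan
    sigma = np.sqrt(var)
    sigma[~mask] = np.nan
    return AnisotropyDecay(
        time=parallel.time_axis,
        r=r,
        sigma_r=sigma,
        total_intensity=total,
        mask=mask,
    )


@dataclass
class RotationalDiffusionResult:
    """Mono-exponential tail fit r(t) = A exp(-t/theta)."""

    r_amplitude: float
    theta: float
    r_amplitude_stderr: float | None
    theta_stderr: float | None
    t_start: float
    n_channels_used: int
    no_decay_detected: bool

    def summary(self) -> str:
        theta_txt = (
            "no decay detected (theta at bound)"
            if self.no_decay_detected
            else f"{self.theta:.2f} ns"
        )
        return (
            "Rotational-correlation tail fit\n"
            f"  window start: {self.t_start:g} ns  ({self.n_channels_used} channels)\n"
            f"  amplitude A : {self.r_amplitude:.4f}"
            f" +/- {_fmt(self.r_amplitude_stderr)}\n"
            f"  theta       : {theta_txt} +/- {_fmt(self.theta_stderr)}"
        )


def _fmt(v):
    return "--" if v is None else f"{v:.3g}"


class RotationalDiffusionModel:
    """Weighted mono-exponential model for the slow depolarisation tail.

    Only channels after ``t_start`` enter the fit, excluding the
    sub-resolution fast phase caused by FRET angular displacement.
    """

    MIN_CHANNELS = 20

    def __init__(self, decay: AnisotropyDecay, t_start: float = DEFAULT_TAIL_START_NS):
        self.decay = decay
        self.t_start = t_start
        t, r, s = decay.usable(t_start)
        good = np.isfinite(r) & np.isfinite(s) & (s > 0)
        self.t, self.r, self.sigma = t[good], r[good], s[good]
        if self.t.size < self.MIN_CHANNELS:
            raise ValueError(
                f"insufficient usable channels after t_start ({self.t.size} < {self.MIN_CHANNELS})"
            )

    def _seed(self) -> tuple[float, float]:
        a0 = float(self.r[: max(self.t.size // 20, 3)].mean())
        pos = self.r > 0 if a0 >= 0 else self.r < 0
        if pos.sum() >= 5:
            slope = np.polyfit(self.t[pos], np.log(np.abs(self.r[pos])), 1)[0]
            theta0 = -1.0 / slope if slope < 0 else THETA_UPPER_BOUND_NS / 10
        else:
            theta0 = 20.0
        return a0, float(np.clip(theta0, 0.1, THETA_UPPER_BOUND_NS))

    def fit(self) -> RotationalDiffusionResult:
        a0, theta0 = self._seed()
        params = lmfit.Parameters()
        params.add("amplitude", value=a0 if a0 != 0 else 0.01, min=-0.5, max=1.0)
        params.add("theta", value=theta0, min=1e-3, max=THETA_UPPER_BOUND_NS)

        def residual(p):
            model = p["amplitude"].value * np.exp(-self.t / p["theta"].value)
            return (model - self.r) / self.sigma

        out = lmfit.minimize(residual, params, method="leastsq")
        if not out.success:
            raise RuntimeError(f"rotational-correlation fit did not converge: {out.message}")
        theta = out.params["theta"].value
        no_decay = theta >= 0.99 * THETA_UPPER_BOUND_NS
        if no_decay:
            warnings.warn("no anisotropy decay detected within the window (theta at bound)")
        return RotationalDiffusionResult(
            r_amplitude=out.params["amplitude"].value,
            theta=theta,
            r_amplitude_stderr=out.params["amplitude"].stderr,
            theta_stderr=out.params["theta"].stderr,
            t_start=self.t_start,
            n_channels_used=self.t.size,
            no_decay_detected=no_decay,
        )


def fit_rotational_correlation(
    decay: AnisotropyDecay, t_start: float = DEFAULT_TAIL_START_NS
) -> tuple[float, float]:
    """Tail fit returning (r_amplitude, theta in ns); see :class:`RotationalDiffusionModel`."""
    res = RotationalDiffusionModel(decay, t_start=t_start).fit()
    return res.r_amplitude, res.theta


# -- Perrin conversion, bleed-through compensation, angle inversion -------

def perrin_fundamental(r: float, tau: float, theta: float) -> float:
    """Fundamental anisotropy r0 = r (1 + tau/theta) from the Perrin equation."""
    if theta <= 0:
        raise ValueError("rotational correlation time must be positive")
    if tau < 0:
        raise ValueError("lifetime must be non-negative")
    return r * (1.0 + tau / theta)


def perrin_steady(r0: float, tau: float, theta: float) -> float:
    """Steady-state anisotropy r = r0 / (1 + tau/theta); inverse of perrin_fundamental."""
    if theta <= 0:
        raise ValueError("rotational correlation time must be positive")
    if tau < 0:
        raise ValueError("lifetime must be non-negative")
    return r0 / (1.0 + tau / theta)


def compensate_bleed_through(
    r_obs: float, r_d: float = DEFAULT_DONOR_ANISOTROPY, f_d: float = 0.0
) -> float:
    """Pure sensitized-acceptor anisotropy r_a = (r_obs - r_d f_d) / (1 - f_d).

    Exact inverse of the intensity-weighted mixing
    r_obs = r_d f_d + r_a (1 - f_d), where f_d is the donor intensity
    fraction within the acceptor detection band.
    """
    if not 0 <= f_d < 1:
        raise ValueError("donor fraction must lie in [0, 1)")
    return (r_obs - r_d * f_d) / (1.0 - f_d)


def angle_from_fundamental(r0: float) -> float:
    """Dipole angle beta (degrees) from r0 = 0.4 (3 cos^2 beta - 1)/2.

    Only r0 in [-0.2, 0.4] maps to a real angle; 0.4 -> 0 deg, 0 -> magic
    angle 54.7 deg, -0.2 -> 90 deg.
    """
    if not -0.5 * R0_PREFACTOR <= r0 <= R0_PREFACTOR:
        raise ValueError("r0 outside [-0.2, 0.4]: no real dipole angle")
    cos2 = (2.0 * r0 / R0_PREFACTOR + 1.0) / 3.0
    return math.degrees(math.acos(math.sqrt(cos2)))


def fundamental_from_angle(beta: float) -> float:
    """r0 = 0.4 (3 cos^2 beta - 1)/2 for beta in degrees within [0, 90]."""
    if not 0.0 <= beta <= 90.0:
        raise ValueError("beta must lie in [0, 90] degrees")
    c = math.cos(math.radians(beta))
    return R0_PREFACTOR * (3.0 * c * c - 1.0) / 2.0
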