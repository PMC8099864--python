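"""Time-correlated single-photon-counting decay histograms and reconvolution fitting.

A measured fluorescence decay is the convolution of the true multi-exponential
impulse response with the instrument response function (IRF), plus a constant
background.  Fitting therefore re-convolves a trial model with the measured
IRF on the histogram grid at every iteration ("iterative reconvolution") and
minimises Poisson-weighted residuals.

Two acquisition regimes are built in as default grids:

* cuvette mode — 4096 channels over a 20 ns (or 40 ns) window;
* microscope mode — 3125 channels at 16 ps/channel (50 ns window).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "DecayHistogram",
    "InstrumentResponse",
    "MultiExpModel",
    "DecayFitResult",
    "DecayModel",
    "convolve_model",
    "fit_decay",
    "amplitude_weighted_lifetime",
    "reduced_chi_square",
    "CUVETTE_GRID_20NS",
    "CUVETTE_GRID_40NS",
    "MICROSCOPE_GRID",
]

#: (n_channels, dwell in ns) presets for the two acquisition regimes.
CUVETTE_GRID_20NS = (4096, 20.0 / 4096)
CUVETTE_GRID_40NS = (4096, 40.0 / 4096)
MICROSCOPE_GRID = (3125, 0.016)

#: Channels with fewer expected counts than this are excluded from the
#: reduced-chi-square statistic.  The Neyman weight 1/max(obs, 1) is strongly
#: biased at low occupancy (expectation ~0.6 at 1 count, ~1.6 at 5 counts,
#: within a few percent of 1 only above ~50), so near-empty channels would
#: distort the goodness-of-fit even for a perfect model.
CHI2_EXPECTED_FLOOR = 10.0


def _uniform_axis(n_channels: int, dwell: float) -> np.ndarray:
    return np.arange(n_channels) * dwell


@dataclass(frozen=True)
class DecayHistogram:
    """Binned photon arrival-time histogram on a uniform time axis (ns)."""

    counts: np.ndarray
    dwell: float

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size < 2:
            raise ValueError("counts must be a 1-D array with >= 2 channels")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and non-negative")
        if not (self.dwell > 0):
            raise ValueError("dwell must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def n_channels(self) -> int:
        return self.counts.size

    @property
    def time_axis(self) -> np.ndarray:
        return _uniform_axis(self.n_channels, self.dwell)

    @property
    def window(self) -> float:
        """Total time window in ns."""
        return self.n_channels * self.dwell

    @classmethod
    def from_columns(cls, time_ns, counts) -> "DecayHistogram":
        """Build from explicit (time, counts) columns, validating uniformity."""
        t = np.asarray(time_ns, dtype=float)
        steps = np.diff(t)
        if t.size < 2 or np.any(steps <= 0):
            raise ValueError("time axis must be strictly increasing")
        dwell = float(np.median(steps))
        if not np.allclose(steps, dwell, rtol=1e-3, atol=1e-9):
            raise ValueError("time axis must have a constant step")
        return cls(counts=np.asarray(counts, dtype=float), dwell=dwell)


@dataclass(frozen=True)
class InstrumentResponse:
    """Measured instrument response on the same grid as the decay it pairs with."""

    counts: np.ndarray
    dwell: float
    fwhm_estimate: float | None = None

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("IRF counts must be finite and non-negative")
        if counts.sum() <= 0:
            raise ValueError("IRF must integrate to a positive total")
        if not (self.dwell > 0):
            raise ValueError("dwell must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def n_channels(self) -> int:
        return self.counts.size

    @property
    def time_axis(self) -> np.ndarray:
        return _uniform_axis(self.n_channels, self.dwell)

    def normalized(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @classmethod
    def delta(cls, n_channels: int, dwell: float, channel: int = 0) -> "InstrumentResponse":
        """Idealised delta-function response (all weight in one channel)."""
        counts = np.zeros(n_channels)
        counts[channel] = 1.0
        return cls(counts=counts, dwell=dwell, fwhm_estimate=0.0)


@dataclass(frozen=True)
class MultiExpModel:
    """Multi-exponential impulse response: sum of alpha_i * exp(-t / tau_i).

    Amplitude fractions sum to one; components are stored sorted by ascending
    lifetime.  ``shift`` is the IRF-to-decay timing offset in ns and
    ``background`` a constant count level per channel.
    """

    amplitudes: tuple
    lifetimes: tuple
    shift: float = 0.0
    background: float = 0.0

    def __post_init__(self):
        amps = np.asarray(self.amplitudes, dtype=float)
        taus = np.asarray(self.lifetimes, dtype=float)
        if amps.shape != taus.shape or amps.ndim != 1 or amps.size < 1:
            raise ValueError("amplitudes and lifetimes must be matching 1-D tuples")
        if np.any(taus <= 0) or not np.all(np.isfinite(taus)):
            raise ValueError("lifetimes must be positive and finite")
        if np.any(amps < 0) or not np.isclose(amps.sum(), 1.0, atol=1e-6):
            raise ValueError("amplitudes must be non-negative fractions summing to 1")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        order = np.argsort(taus)
        object.__setattr__(self, "amplitudes", tuple(amps[order] / amps.sum()))
        object.__setattr__(self, "lifetimes", tuple(taus[order]))

    @property
    def n_components(self) -> int:
        return len(self.lifetimes)


def amplitude_weighted_lifetime(model: MultiExpModel) -> float:
    """Amplitude-weighted average lifetime sum(alpha_i * tau_i) in ns.

    For pre-normalised amplitude fractions this is the standard summary used
    to compare multi-exponential decays (e.g. 0.70*0.58 + 0.30*1.7 = 0.92 ns).
    """
    return float(np.dot(model.amplitudes, model.lifetimes))


def convolve_model(
    model: MultiExpModel,
    irf: InstrumentResponse,
    n_channels: int | None = None,
    scale: float = 1.0,
) -> np.ndarray:
    """Expected counts per channel: scale * sum_i alpha_i (IRF (*) exp(-t/tau_i)) + background.

    The discrete convolution is carried out on the histogram grid; the model's
    ``shift`` displaces the IRF (positive shift = IRF arrives later) via linear
    interpolation.  The multi-exponential part is normalised so its convolution
    carries unit peak amplitude of the exponential sum before scaling, i.e. a
    delta IRF with ``scale=1`` returns sum_i alpha_i exp(-t/tau_i) exactly.
    """
    if n_channels is None:
        n_channels = irf.n_channels
    if n_channels != irf.n_channels:
        raise ValueError("grid mismatch between requested length and IRF")
    params = list(model.amplitudes) + list(model.lifetimes) + [model.shift, model.background]
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite model parameters")
    t = irf.time_axis
    kernel = irf.normalized()
    if model.shift != 0.0:
        kernel = np.interp(t - model.shift, t, kernel, left=0.0, right=0.0)
        total = kernel.sum()
        if total > 0:
            kernel = kernel / total
    curve = np.zeros(n_channels)
    for alpha, tau in zip(model.amplitudes, model.lifetimes):
        decay = np.exp(-t / tau)
        curve += alpha * fftconvolve(kernel, decay)[:n_channels]
    return scale * np.clip(curve, 0.0, None) + model.background


def reduced_chi_square(
    observed: np.ndarray,
    expected: np.ndarray,
    n_free_params: int,
    expected_floor: float = CHI2_EXPECTED_FLOOR,
) -> float:
    """Neyman reduced chi-square: sum (obs-exp)^2 / max(obs, 1) over used channels.

    Channels whose expected counts fall below ``expected_floor`` are excluded
    (see :data:`CHI2_EXPECTED_FLOOR`); the sum is divided by
    (channels used - n_free_params).
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have equal length")
    use = exp >= expected_floor
    n_used = int(use.sum())
    if n_used <= n_free_params:
        raise ValueError("no usable channels above the expected-count floor")
    resid2 = (obs[use] - exp[use]) ** 2 / np.maximum(obs[use], 1.0)
    return float(resid2.sum() / (n_used - n_free_params))


@dataclass
class DecayFitResult:
    """Converged reconvolution fit of a decay histogram."""

    model: MultiExpModel
    chi2_reduced: float
    weighted_residuals: np.ndarray
    amplitude_weighted_lifetime: float
    parameter_uncertainties: dict
    scale: float
    success: bool
    message: str
    n_free_params: int

    def summary(self) -> str:
        lines = [
            "Reconvolution decay fit",
            "=" * 47,
            f"components: {self.model.n_components}    "
            f"chi2_red: {self.chi2_reduced:.3f}    converged: {self.success}",
            f"{'param':<12}{'value':>12}{'std err':>14}",
            "-" * 47,
        ]
        for i, (a, tau) in enumerate(zip(self.model.amplitudes, self.model.lifetimes), 1):
            sa = self.parameter_uncertainties.get(f"alpha{i}")
            st = self.parameter_uncertainties.get(f"tau{i}")
            lines.append(f"{f'alpha{i}':<12}{a:>12.4f}{_fmt_err(sa):>14}")
            lines.append(f"{f'tau{i} (ns)':<12}{tau:>12.4f}{_fmt_err(st):>14}")
        lines.append(f"{'shift (ns)':<12}{self.model.shift:>12.4f}"
                     f"{_fmt_err(self.parameter_uncertainties.get('shift')):>14}")
        lines.append(f"{'background':<12}{self.model.background:>12.4f}"
                     f"{_fmt_err(self.parameter_uncertainties.get('background')):>14}")
        lines.append("-" * 47)
        lines.append(f"amplitude-weighted lifetime: "
                     f"{self.amplitude_weighted_lifetime:.4f} ns")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_components": self.model.n_components,
            "amplitudes": list(self.model.amplitudes),
            "lifetimes_ns": list(self.model.lifetimes),
            "shift_ns": self.model.shift,
            "background": self.model.background,
            "scale": self.scale,
            "chi2_reduced": self.chi2_reduced,
            "amplitude_weighted_lifetime_ns": self.amplitude_weighted_lifetime,
            "parameter_uncertainties": {
                k: (None if v is None else float(v))
                for k, v in self.parameter_uncertainties.items()
            },
            "converged": self.success,
            "message": self.message,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _fmt_err(v):
    return "--" if v is None else f"{v:.4f}"


class FitConvergenceError(RuntimeError):
    """Raised when the reconvolution fit fails to converge."""


class DecayModel:
    """Reconvolution model bound to a (decay, IRF) pair; ``fit()`` returns results.

    Parameters
    ----------
    decay, irf : on the same uniform grid.
    n_components : 1, 2 or 3 exponential components.
    fit_shift : allow an IRF timing offset, bounded to +-5 channels.
    fit_background : free constant background, seeded from pre-rise channels.
    """

    MAX_COMPONENTS = 3
    _TAU_SPREAD = {1: (1.0,), 2: (0.5, 2.0), 3: (0.25, 1.0, 4.0)}

    def __init__(
        self,
        decay: DecayHistogram,
        irf: InstrumentResponse,
        n_components: int = 1,
        fit_shift: bool = True,
        fit_background: bool = True,
    ):
        if decay.n_channels != irf.n_channels or not np.isclose(decay.dwell, irf.dwell):
            raise ValueError("decay and IRF must share the same grid")
        if not 1 <= n_components <= self.MAX_COMPONENTS:
            raise ValueError(f"n_components must be in 1..{self.MAX_COMPONENTS}")
        self.decay = decay
        self.irf = irf
        self.n_components = n_components
        self.fit_shift = fit_shift
        self.fit_background = fit_background

    # -- deterministic initialisation ------------------------------------
    def _tail_lifetime_seed(self) -> float:
        """Log-linear regression on the tail: last 60% of post-peak channels
        that stay above 1% of the peak count."""
        counts = self.decay.counts
        t = self.decay.time_axis
        peak = int(np.argmax(counts))
        above = np.nonzero(counts[peak:] > 0.01 * counts[peak])[0] + peak
        if above.size < 5:
            return max(self.decay.window / 10.0, self.decay.dwell)
        tail = above[int(0.4 * above.size):]
        y = np.log(np.maximum(counts[tail], 0.5))
        slope = np.polyfit(t[tail], y, 1)[0]
        if slope >= 0:
            return self.decay.window
        return float(np.clip(-1.0 / slope, self.decay.dwell, 10 * self.decay.window))

    def _background_seed(self) -> float:
        """Mean count level of the channels before the pulse rise."""
        counts = self.decay.counts
        rise = np.nonzero(counts > 0.05 * counts.max())[0]
        if rise.size == 0 or rise[0] < 5:
            return 0.0
        return float(counts[: max(rise[0] - 2, 1)].mean())

    def _initial_params(self, init: MultiExpModel | None) -> lmfit.Parameters:
        n = self.n_components
        dwell = self.decay.dwell
        params = lmfit.Parameters()
        if init is not None:
            taus = list(init.lifetimes)
            fracs = list(init.amplitudes)
            background = init.background
            shift = init.shift
            if len(taus) != n:
                raise ValueError("init model has wrong number of components")
        else:
            tau_seed = self._tail_lifetime_seed()
            taus = [tau_seed * s for s in self._TAU_SPREAD[n]]
            fracs = [1.0 / n] * n
            background = self._background_seed()
            shift = 0.0
        # the convolved unit-amplitude sum peaks near 1, so the data peak
        # (minus background) seeds the linear scale well
        params.add("scale", value=max(float(self.decay.counts.max()) - background, 1.0),
                   min=1e-6)
        for i in range(n):
            params.add(f"tau{i + 1}", value=taus[i],
                       min=dwell / 10.0, max=50 * self.decay.window)
        # n-1 free fractions; the last is 1 - sum (clipped at evaluation)
        for i in range(n - 1):
            params.add(f"f{i + 1}", value=fracs[i], min=0.0, max=1.0)
        params.add("shift", value=shift, min=-5 * dwell, max=5 * dwell,
                   vary=self.fit_shift)
        params.add("background", value=background, min=0.0,
                   vary=self.fit_background)
        return params

    def _params_to_model(self, params) -> tuple[MultiExpModel, float]:
        n = self.n_components
        taus = [params[f"tau{i + 1}"].value for i in range(n)]
        fracs = [params[f"f{i + 1}"].value for i in range(n - 1)]
        last = max(1.0 - sum(fracs), 0.0)
        amps = np.asarray(fracs + [last])
        amps = amps / amps.sum() if amps.sum() > 0 else np.full(n, 1.0 / n)
        model = MultiExpModel(
            amplitudes=tuple(amps),
            lifetimes=tuple(taus),
            shift=params["shift"].value,
            background=params["background"].value,
        )
        return model, params["scale"].value

    def _expected(self, params) -> np.ndarray:
        model, scale = self._params_to_model(params)
        return convolve_model(model, self.irf, scale=scale)

    def _residuals(self, params, weights):
        return (self._expected(params) - self.decay.counts) * weights

    def fit(self, init: MultiExpModel | None = None, max_nfev: int = 2000) -> DecayFitResult:
        """Weighted least squares with per-channel variance max(counts, 1)."""
        weights = 1.0 / np.sqrt(np.maximum(self.decay.counts, 1.0))
        params = self._initial_params(init)
        minimizer = lmfit.Minimizer(self._residuals, params, fcn_args=(weights,),
                                    max_nfev=max_nfev)
        out = minimizer.minimize(method="leastsq")
        if not out.success:
            raise FitConvergenceError(f"reconvolution fit did not converge: {out.message}")
        model, scale = self._params_to_model(out.params)
        expected = convolve_model(model, self.irf, scale=scale)
        n_free = int(out.nvarys)
        chi2 = reduced_chi_square(self.decay.counts, expected, n_free)
        uncertainties = self._map_uncertainties(out, model)
        message = out.message
        if out.covar is None and n_free > 1:
            message += " [degenerate covariance: model may be over-parameterised]"
        return DecayFitResult(
            model=model,
            chi2_reduced=chi2,
            weighted_residuals=(self.decay.counts - expected) * weights,
            amplitude_weighted_lifetime=amplitude_weighted_lifetime(model),
            parameter_uncertainties=uncertainties,
            scale=scale,
            success=bool(out.success),
            message=message,
            n_free_params=n_free,
        )

    def _map_uncertainties(self, out, model: MultiExpModel) -> dict:
        """Relabel stderr estimates to follow the ascending-lifetime ordering."""
        n = self.n_components
        raw_taus = [out.params[f"tau{i + 1}"].value for i in range(n)]
        order = np.argsort(raw_taus)
        unc: dict = {}
        for rank, idx in enumerate(order, 1):
            unc[f"tau{rank}"] = out.params[f"tau{idx + 1}"].stderr
            if idx < n - 1:
                unc[f"alpha{rank}"] = out.params[f"f{idx + 1}"].stderr
            else:
                # last fraction is derived; propagate as quadrature of the free ones
                errs = [out.params[f"f{i + 1}"].stderr for i in range(n - 1)]
                unc[f"alpha{rank}"] = (
                    float(np.sqrt(sum(e ** 2 for e in errs))) if errs and None not in errs
                    else (0.0 if n == 1 else None)
                )
        unc["shift"] = out.params["shift"].stderr
        unc["background"] = out.params["background"].stderr
        unc["scale"] = out.params["scale"].stderr
        return unc


def fit_decay(
    decay: DecayHistogram,
    irf: InstrumentResponse,
    n_components: int,
    init: MultiExpModel | None = None,
    **kwargs,
) -> DecayFitResult:
    """Functional front-end to :class:`DecayModel`."""
    return DecayModel(decay, irf, n_components, **kwargs).fit(init=init)
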