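"""Hill calibration of sensor anisotropy against free Ca2+ concentration.

The dose-response of the sensitized-acceptor anisotropy follows a
four-parameter Hill function

    r(c) = r_free + (r_bound - r_free) * c^n / (K'd^n + c^n),

with apparent dissociation constant K'd (nM) and Hill coefficient n.  The
fitted calibration is monotone and therefore invertible, so live-cell
anisotropy read-outs can be mapped back to concentrations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "TitrationTable",
    "HillCalibration",
    "HillModel",
    "hill_model",
    "fit_hill",
    "invert_calibration",
    "GEUSAPVC260_CALIBRATION",
    "GEUSAPVC360_CALIBRATION",
]


@dataclass(frozen=True)
class TitrationTable:
    """Anisotropy vs free-Ca2+ titration (concentrations in nM)."""

    concentrations: np.ndarray
    anisotropies: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.anisotropies, dtype=float)
        if conc.shape != r.shape or conc.ndim != 1:
            raise ValueError("concentrations and anisotropies must be matching 1-D arrays")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != conc.shape or np.any(s <= 0):
                raise ValueError("sigma must match the table and be positive")
            object.__setattr__(self, "sigma", s)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "anisotropies", r)

    def validate_for_fit(self):
        pos = self.concentrations[self.concentrations > 0]
        if self.concentrations.size < 5:
            raise ValueError("need at least 5 titration points to fit")
        if pos.size < 2 or pos.max() / pos.min() < 10:
            raise ValueError("titration must span at least one decade of concentration")


@dataclass
class HillCalibration:
    """Fitted Hill parameters mapping anisotropy <-> free Ca2+ (nM)."""

    n_hill: float
    Kd_app: float
    r_free: float
    r_bound: float
    uncertainties: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None
    residuals: np.ndarray | None = None

    def __post_init__(self):
        if self.n_hill <= 0 or self.Kd_app <= 0:
            raise ValueError("Hill coefficient and K'd must be positive")
        if self.r_free == self.r_bound:
            raise ValueError("r_free and r_bound must differ")

    def summary(self) -> str:
        def fmt(name, val):
            err = self.uncertainties.get(name)
            return f"{val:.4g}" + ("" if err is None else f" +/- {err:.2g}")

        return (
            "Hill calibration (anisotropy vs free Ca2+)\n"
            f"  n       : {fmt('n_hill', self.n_hill)}\n"
            f"  K'd (nM): {fmt('Kd_app', self.Kd_app)}\n"
            f"  r_free  : {fmt('r_free', self.r_free)}\n"
            f"  r_bound : {fmt('r_bound', self.r_bound)}"
        )

    def to_dict(self) -> dict:
        return {
            "n_hill": self.n_hill,
            "Kd_app_nM": self.Kd_app,
            "r_free": self.r_free,
            "r_bound": self.r_bound,
            "uncertainties": {k: (None if v is None else float(v))
                              for k, v in self.uncertainties.items()},
            "covariance": None if self.covariance is None else np.asarray(self.covariance).tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HillCalibration":
        with open(path) as fh:
            d = json.load(fh)
        cov = d.get("covariance")
        return cls(
            n_hill=d["n_hill"], Kd_app=d["Kd_app_nM"],
            r_free=d["r_free"], r_bound=d["r_bound"],
            uncertainties=d.get("uncertainties", {}),
            covariance=None if cov is None else np.asarray(cov),
        )


#: In-vitro calibrations of the two sensor variants (anisotropy falls from
#: r_free to r_bound with rising Ca2+).
GEUSAPVC260_CALIBRATION = HillCalibration(
    n_hill=1.9, Kd_app=71.0, r_free=0.10, r_bound=-0.03
)
GEUSAPVC360_CALIBRATION = HillCalibration(
    n_hill=1.6, Kd_app=502.0, r_free=0.10, r_bound=-0.02
)


def hill_model(conc, cal: HillCalibration):
    """Anisotropy at concentration(s) ``conc`` (nM) under calibration ``cal``."""
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    cn = np.power(c, cal.n_hill)
    out = cal.r_free + (cal.r_bound - cal.r_free) * cn / (cal.Kd_app ** cal.n_hill + cn)
    return float(out) if np.isscalar(conc) else out


class HillModel:
    """Four-parameter Hill dose-response model bound to a titration table."""

    def __init__(self, table: TitrationTable):
        table.validate_for_fit()
        self.table = table

    def _initial_params(self) -> lmfit.Parameters:
        conc = self.table.concentrations
        r = self.table.anisotropies
        order = np.argsort(conc)
        r_lo, r_hi = float(r[order[0]]), float(r[order[-1]])
        midpoint = 0.5 * (r_lo + r_hi)
        pos = conc > 0
        kd0 = float(conc[pos][np.argmin(np.abs(r[pos] - midpoint))])
        span = abs(r_hi - r_lo)
        params = lmfit.Parameters()
        params.add("n_hill", value=1.0, min=0.05, max=20.0)
        params.add("Kd_app", value=max(kd0, 1e-6), min=1e-9)
        params.add("r_free", value=r_lo, min=r_lo - 5 * span - 1e-3,
                   max=r_lo + 5 * span + 1e-3)
        params.add("r_bound", value=r_hi, min=r_hi - 5 * span - 1e-3,
                   max=r_hi + 5 * span + 1e-3)
        return params

    def fit(self) -> HillCalibration:
        conc = self.table.concentrations
        robs = self.table.anisotropies
        sigma = self.table.sigma if self.table.sigma is not None else np.ones_like(robs)

        def residual(p):
            cal = HillCalibration(
                n_hill=p["n_hill"].value, Kd_app=p["Kd_app"].value,
                r_free=p["r_free"].value,
                r_bound=p["r_bound"].value
                if p["r_bound"].value != p["r_free"].value
                else p["r_free"].value + 1e-12,
            )
            return (hill_model(conc, cal) - robs) / sigma

        out = lmfit.minimize(residual, self._initial_params(), method="leastsq")
        if not out.success:
            raise RuntimeError(f"Hill fit did not converge: {out.message}")
        kd = out.params["Kd_app"].value
        pos = conc[conc > 0]
        if not pos.min() < kd < pos.max():
            warnings.warn("fitted K'd lies outside the titrated concentration range")
        cal = HillCalibration(
            n_hill=out.params["n_hill"].value,
            Kd_app=kd,
            r_free=out.params["r_free"].value,
            r_bound=out.params["r_bound"].value,
            uncertainties={k: out.params[k].stderr
                           for k in ("n_hill", "Kd_app", "r_free", "r_bound")},
            covariance=out.covar,
            residuals=np.asarray(out.residual),
        )
        return cal


def fit_hill(table: TitrationTable) -> HillCalibration:
    """Functional front-end to :class:`HillModel`."""
    return HillModel(table).fit()


def invert_calibration(r, cal: HillCalibration, clamp: bool = True):
    """Free Ca2+ (nM) from anisotropy: c = K'd ((r_free - r)/(r - r_bound))^(1/n).

    Values outside the open interval between r_free and r_bound are clamped to
    0 or inf (nearer bound) when ``clamp`` is true, else raise.
    """
    scalar = np.isscalar(r)
    rr = np.atleast_1d(np.asarray(r, dtype=float))
    lo, hi = sorted((cal.r_free, cal.r_bound))
    outside = (rr <= lo) | (rr >= hi)
    if np.any(outside) and not clamp:
        raise ValueError("anisotropy outside the calibration range")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (cal.r_free - rr) / (rr - cal.r_bound)
        conc = cal.Kd_app * np.power(ratio, 1.0 / cal.n_hill)
    # at/beyond the bounds: r_free-side -> 0, r_bound-side -> inf
    at_free = np.isclose(rr, cal.r_free) | ((rr - cal.r_free) * (cal.r_free - cal.r_bound) > 0)
    at_bound = np.isclose(rr, cal.r_bound) | ((cal.r_bound - rr) * (cal.r_free - cal.r_bound) > 0)
    conc = np.where(outside & at_free, 0.0, conc)
    conc = np.where(outside & at_bound, np.inf, conc)
    return float(conc[0]) if scalar else conc
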