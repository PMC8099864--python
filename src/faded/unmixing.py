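"""Linear unmixing of emission spectra into donor and acceptor contributions.

A measured spectrum is modelled as a non-negative combination
c_d * D(lambda) + c_a * A(lambda) of reference spectra; the coefficients are
found by non-negative least squares.  From the fitted components the
per-wavelength donor fraction and the cumulative donor bleed-through above a
cutoff (the quantity that contaminates sensitized-acceptor anisotropy) are
derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "EmissionSpectrum",
    "UnmixResult",
    "SpectralUnmixer",
    "unmix",
    "donor_fraction_cumulative",
    "peak_ratio",
]


@dataclass(frozen=True)
class EmissionSpectrum:
    """Intensity on a strictly increasing wavelength grid (nm, a.u.)."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if wl.shape != inten.shape or wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelengths and intensities must be matching 1-D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(inten < 0) or not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite and non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)

    def resampled_to(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``grid``; zero outside the measured range."""
        return np.interp(grid, self.wavelengths, self.intensities, left=0.0, right=0.0)

    def at(self, wavelength: float) -> float:
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not lo <= wavelength <= hi:
            raise ValueError(f"wavelength {wavelength} nm outside grid [{lo}, {hi}]")
        return float(np.interp(wavelength, self.wavelengths, self.intensities))


@dataclass
class UnmixResult:
    """Fitted donor/acceptor coefficients and derived per-wavelength fractions."""

    coeff_donor: float
    coeff_acceptor: float
    wavelengths: np.ndarray
    donor_component: np.ndarray
    acceptor_component: np.ndarray
    residual_norm: float
    offset: float = 0.0

    @property
    def fitted(self) -> np.ndarray:
        return self.donor_component + self.acceptor_component + self.offset

    def donor_fraction(self) -> np.ndarray:
        """Donor share of the fitted signal per wavelength (NaN where the fit is zero)."""
        total = self.donor_component + self.acceptor_component
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(total > 0, self.donor_component / total, np.nan)
        return frac

    def summary(self) -> str:
        return (
            "Linear spectral unmixing (NNLS)\n"
            f"  donor coefficient   : {self.coeff_donor:.5g}\n"
            f"  acceptor coefficient: {self.coeff_acceptor:.5g}\n"
            f"  residual norm       : {self.residual_norm:.5g}\n"
            f"  grid                : {self.wavelengths[0]:g}-{self.wavelengths[-1]:g} nm,"
            f" {self.wavelengths.size} points"
        )


class SpectralUnmixer:
    """Two-endmember unmixing model bound to (measured, donor ref, acceptor ref)."""

    def __init__(
        self,
        measured: EmissionSpectrum,
        donor_ref: EmissionSpectrum,
        acceptor_ref: EmissionSpectrum,
        fit_offset: bool = False,
    ):
        self.measured = measured
        grid = measured.wavelengths
        self.donor_basis = donor_ref.resampled_to(grid)
        self.acceptor_basis = acceptor_ref.resampled_to(grid)
        self.fit_offset = fit_offset
        overlap = (self.donor_basis > 0) | (self.acceptor_basis > 0)
        if overlap.sum() < 3:
            raise ValueError("reference spectra barely overlap the measured grid")
        db, ab = self.donor_basis[overlap], self.acceptor_basis[overlap]
        nd, na = np.linalg.norm(db), np.linalg.norm(ab)
        if nd == 0 or na == 0:
            raise ValueError("a reference spectrum is zero on the measured grid")
        if abs(float(db @ ab) / (nd * na)) > 1 - 1e-9:
            raise ValueError("reference spectra are proportional: unmixing unidentifiable")

    def fit(self) -> UnmixResult:
        cols = [self.donor_basis, self.acceptor_basis]
        if self.fit_offset:
            cols.append(np.ones_like(self.donor_basis))
        design = np.column_stack(cols)
        coeffs, rnorm = nnls(design, self.measured.intensities)
        offset = float(coeffs[2]) if self.fit_offset else 0.0
        return UnmixResult(
            coeff_donor=float(coeffs[0]),
            coeff_acceptor=float(coeffs[1]),
            wavelengths=self.measured.wavelengths,
            donor_component=coeffs[0] * self.donor_basis,
            acceptor_component=coeffs[1] * self.acceptor_basis,
            residual_norm=float(rnorm),
            offset=offset,
        )


def unmix(
    measured: EmissionSpectrum,
    donor_ref: EmissionSpectrum,
    acceptor_ref: EmissionSpectrum,
    fit_offset: bool = False,
) -> UnmixResult:
    """Functional front-end to :class:`SpectralUnmixer`."""
    return SpectralUnmixer(measured, donor_ref, acceptor_ref, fit_offset=fit_offset).fit()


def donor_fraction_cumulative(
    result: UnmixResult, lambda_min: float, lambda_max: float
) -> float:
    """Integrated donor share of the fitted signal over [lambda_min, lambda_max].

    Trapezoidal integration on the fit grid, with the band edges inserted by
    linear interpolation, of integral(c_d D) / integral(c_d D + c_a A).
    """
    wl = result.wavelengths
    if lambda_min >= lambda_max:
        raise ValueError("empty integration band")
    lo = max(lambda_min, wl[0])
    hi = min(lambda_max, wl[-1])
    if lo >= hi:
        raise ValueError("band does not overlap the fitted grid")
    inner = wl[(wl > lo) & (wl < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    donor = np.interp(grid, wl, result.donor_component)
    total = donor + np.interp(grid, wl, result.acceptor_component)
    denom = np.trapezoid(total, grid)
    if denom <= 0:
        return 0.0
    return float(np.trapezoid(donor, grid) / denom)


def peak_ratio(spectrum: EmissionSpectrum, lambda_a: float, lambda_b: float) -> float:
    """Interpolated intensity ratio I(lambda_a) / I(lambda_b)."""
    denom = spectrum.at(lambda_b)
    if denom == 0:
        raise ValueError(f"zero intensity at {lambda_b} nm")
    return spectrum.at(lambda_a) / denom
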