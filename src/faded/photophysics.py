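"""Closed-form FRET and photophysical arithmetic.

Energy transfer competes with the donor's radiative and non-radiative decay;
for an intramolecular donor-acceptor pair the transfer efficiency follows
directly from the amplitude-weighted donor lifetimes measured with and
without the acceptor:

    E = 1 - tau_dA / tau_d0        tau_T = 1 / (1/tau_dA - 1/tau_d0)

All lifetimes are amplitude-weighted averages and carried in ns; conversion
to s^-1 happens only at the rate-constant boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "FretLifetimes",
    "PhotophysicalRates",
    "ForsterContext",
    "fret_efficiency",
    "transfer_time",
    "rate_constants",
    "forster_scale_factor",
    "fret_rate",
    "extinction_coefficient_alkaline",
    "folding_ratio",
    "relative_quantum_yield",
    "ALKALINE_REFERENCE_EXTINCTION",
]

#: Extinction coefficient of the alkaline-denatured GFP chromophore at 447 nm
#: (M^-1 cm^-1), the reference for the NaOH denaturation concentration assay.
ALKALINE_REFERENCE_EXTINCTION = 44_000.0

NS_TO_S = 1e-9


@dataclass(frozen=True)
class FretLifetimes:
    """Amplitude-weighted donor lifetimes without (tau_d0) and with (tau_dA) acceptor, ns."""

    tau_d0: float
    tau_dA: float

    def __post_init__(self):
        if self.tau_d0 <= 0 or self.tau_dA <= 0:
            raise ValueError("lifetimes must be positive")
        if self.tau_dA > self.tau_d0:
            warnings.warn(
                "tau_dA > tau_d0: pair is not FRET-active (negative efficiency)",
                stacklevel=3,
            )


@dataclass(frozen=True)
class PhotophysicalRates:
    """Quantum yield, lifetime (ns) and the radiative/non-radiative split (s^-1)."""

    phi: float
    tau: float
    k_r: float
    k_nr: float

    def __post_init__(self):
        if self.k_r < 0 or self.k_nr < 0:
            raise ValueError("rate constants must be non-negative")
        total = self.k_r + self.k_nr
        if abs(self.phi - self.k_r / total) > 1e-9:
            raise ValueError("phi inconsistent with k_r/(k_r + k_nr)")
        if abs(1.0 / (self.tau * NS_TO_S) - total) / total > 1e-9:
            raise ValueError("tau inconsistent with 1/(k_r + k_nr)")


@dataclass(frozen=True)
class ForsterContext:
    """Factors entering the Forster distance: R0 ~ (kappa^2 n^-4 Q_D J)^(1/6)."""

    kappa2: float
    refractive_index: float
    overlap_integral: float
    quantum_yield: float

    def __post_init__(self):
        vals = (self.kappa2, self.refractive_index, self.overlap_integral, self.quantum_yield)
        if any(v <= 0 for v in vals):
            raise ValueError("all Forster factors must be positive")
        if not 0 <= self.kappa2 <= 4:
            raise ValueError("orientation factor kappa^2 must lie in [0, 4]")

    @property
    def r0_sixth_power(self) -> float:
        return (self.kappa2 * self.refractive_index ** -4
                * self.quantum_yield * self.overlap_integral)


def fret_efficiency(lifetimes: FretLifetimes) -> float:
    """Transfer efficiency E = 1 - tau_dA/tau_d0 (fraction; negative if flagged inactive)."""
    return 1.0 - lifetimes.tau_dA / lifetimes.tau_d0


def transfer_time(lifetimes: FretLifetimes) -> float:
    """FRET time constant tau_T = 1/(1/tau_dA - 1/tau_d0) in ns.

    Undefined when the donor is not quenched (tau_dA >= tau_d0).
    """
    if lifetimes.tau_dA >= lifetimes.tau_d0:
        raise ValueError("transfer time undefined: tau_dA >= tau_d0 (non-positive FRET rate)")
    return 1.0 / (1.0 / lifetimes.tau_dA - 1.0 / lifetimes.tau_d0)


def rate_constants(phi: float, tau: float) -> PhotophysicalRates:
    """Decompose (quantum yield, lifetime in ns) into k_r = phi/tau and k_nr = 1/tau - k_r."""
    if not 0 < phi <= 1:
        raise ValueError("quantum yield must lie in (0, 1]")
    if tau <= 0:
        raise ValueError("lifetime must be positive")
    tau_s = tau * NS_TO_S
    k_r = phi / tau_s
    k_nr = 1.0 / tau_s - k_r
    return PhotophysicalRates(phi=phi, tau=tau, k_r=k_r, k_nr=k_nr)


def forster_scale_factor(context_a: ForsterContext, context_b: ForsterContext) -> float:
    """Ratio R0_a/R0_b from the one-sixth-power scaling of the Forster distance."""
    return (context_a.r0_sixth_power / context_b.r0_sixth_power) ** (1.0 / 6.0)


def fret_rate(k_D: float, R: float, R0: float) -> float:
    """Transfer rate k_T = k_D (R0/R)^6 from the donor's intrinsic decay rate."""
    if k_D <= 0 or R <= 0 or R0 <= 0:
        raise ValueError("rate and distances must be positive")
    return k_D * (R0 / R) ** 6


def extinction_coefficient_alkaline(
    A_native_400: float,
    A_denatured_447: float,
    path: float = 1.0,
    reference_extinction: float = ALKALINE_REFERENCE_EXTINCTION,
) -> float:
    """Molar extinction coefficient at 400 nm via NaOH denaturation.

    The denatured chromophore absorbance at 447 nm fixes the concentration of
    properly folded protein through the 44,000 M^-1 cm^-1 reference; the
    native 400 nm absorbance then yields epsilon_400.
    """
    if A_native_400 < 0 or A_denatured_447 < 0:
        raise ValueError("absorbances must be non-negative")
    if path <= 0:
        raise ValueError("path length must be positive")
    if A_denatured_447 == 0:
        raise ValueError("denatured absorbance must be positive")
    concentration = A_denatured_447 / (reference_extinction * path)
    return A_native_400 / (concentration * path)


def folding_ratio(conc_alkaline: float, conc_280nm_theoretical: float) -> float:
    """Fraction of properly folded protein: alkaline-method over 280 nm concentration."""
    if conc_alkaline <= 0 or conc_280nm_theoretical <= 0:
        raise ValueError("concentrations must be positive")
    return conc_alkaline / conc_280nm_theoretical


def relative_quantum_yield(
    integrated_sample: float, integrated_ref: float, phi_ref: float
) -> float:
    """Comparative quantum yield at matched optical density.

    phi = phi_ref * (integrated sample emission / integrated reference emission);
    the caller is responsible for the matched-OD condition.
    """
    if integrated_sample < 0 or integrated_ref <= 0:
        raise ValueError("integrated intensities must be positive (sample >= 0)")
    if not 0 < phi_ref <= 1:
        raise ValueError("reference quantum yield must lie in (0, 1]")
    return phi_ref * integrated_sample / integrated_ref


def _efficiency_from_rates(lifetimes: FretLifetimes) -> float:
    """E written through the transfer rate: (1/tau_T)/(1/tau_T + 1/tau_d0).

    Algebraically identical to :func:`fret_efficiency`; kept for the
    rate-picture consistency check.
    """
    k_T = 1.0 / transfer_time(lifetimes)
    return k_T / (k_T + 1.0 / lifetimes.tau_d0)
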