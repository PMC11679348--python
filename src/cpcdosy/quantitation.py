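"""qNMR internal-standard quantitation and 1D spectral-change metrics.

Concentrations are obtained by the primary ratio method against an internal
standard of known concentration (TSP at 100 uM in the reference workflow):

    C_analyte = C_std * (I_analyte / I_std) * (N_std / N_analyte)

where I are peak integrals and N proton counts.  Signal attenuation and
FWHM line broadening on HEC addition are simple before/after differences;
both report restricted mobility of the guest and plateau in practice, so
they are kept as raw metrics rather than modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PeakRecord",
    "qnmr_concentration",
    "signal_attenuation_pct",
    "line_broadening_hz",
    "cpc_free_concentration",
    "TSP_STANDARD_CONC_M",
    "CPC_H1_PROTONS",
    "TSP_PROTONS",
]

#: Internal-standard concentration of the reference workflow, M (100 uM TSP).
TSP_STANDARD_CONC_M = 100e-6
#: Pyridinium H1 reporter of CPC: 2 equivalent protons at 8.9 ppm.
CPC_H1_PROTONS = 2
#: TSP trimethylsilyl singlet: 9 equivalent protons at 0 ppm.
TSP_PROTONS = 9


@dataclass(frozen=True)
class PeakRecord:
    """One resonance in a peak table: shift, integral, width, proton count."""

    shift_ppm: float
    integral: float
    fwhm_hz: float
    n_protons: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.integral < 0:
            raise ValueError("integral must be non-negative")
        if self.fwhm_hz <= 0:
            raise ValueError("FWHM must be positive")
        if self.n_protons < 1:
            raise ValueError("proton count must be >= 1")


def qnmr_concentration(
    analyte: PeakRecord, standard: PeakRecord, standard_conc: float = TSP_STANDARD_CONC_M
) -> float:
    """Analyte molarity from the integral ratio to the internal standard."""
    if standard.integral <= 0:
        raise ValueError("standard integral must be positive")
    if standard_conc <= 0:
        raise ValueError("standard concentration must be positive")
    return (
        standard_conc
        * (analyte.integral / standard.integral)
        * (standard.n_protons / analyte.n_protons)
    )


def signal_attenuation_pct(integral_before: float, integral_after: float) -> float:
    """Percent loss of integral between conditions: 100·(before−after)/before."""
    if integral_before <= 0:
        raise ValueError("reference integral must be positive")
    return 100.0 * (integral_before - integral_after) / integral_before


def line_broadening_hz(fwhm_before: float, fwhm_after: float) -> float:
    """Signed FWHM change in Hz (negative = narrowing, preserved as-is)."""
    if fwhm_before <= 0 or fwhm_after <= 0:
        raise ValueError("FWHM values must be positive")
    return fwhm_after - fwhm_before


def cpc_free_concentration(total_cpc: float, free_fraction: float) -> float:
    """Free-monomer concentration [CPC]_f = total × free fraction."""
    if total_cpc < 0:
        raise ValueError("total concentration must be non-negative")
    if not 0.0 <= free_fraction <= 1.0:
        raise ValueError("free fraction must lie in [0, 1]")
    return total_cpc * free_fraction
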