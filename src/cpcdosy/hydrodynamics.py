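"""Viscosity correction, Stokes-Einstein sizing and two-site free fractions.

Observed diffusion coefficients are first normalised for bulk-viscosity
differences between formulations using the TSP internal reference (TSP is
water-soluble and does not partition into micelles, so any change in its
diffusion reflects solvent viscosity alone).  Corrected coefficients are
then converted to hydrodynamic diameters via Stokes-Einstein,

    d_H = k T / (3 pi eta D),

and, under fast two-site exchange between free monomer and micelle, to the
free mole fraction x with D_obs = x*D_free + (1-x)*D_micelle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "BOLTZMANN_K",
    "WATER_VISCOSITY_298K",
    "TSP_REFERENCE_D",
    "SolventContext",
    "viscosity_correction",
    "stokes_einstein_diameter",
    "volume_ratio",
    "free_fraction",
]

#: Boltzmann constant, J/K (exact, SI 2019).
BOLTZMANN_K = 1.380649e-23
#: Dynamic viscosity of water at 298 K, Pa s.
WATER_VISCOSITY_298K = 8.904e-4
#: Literature-scale placeholder for TSP diffusion in neat aqueous solvent at
#: 298 K, m^2/s.  Calibrate against your own spectrometer; this default is a
#: small-molecule order-of-magnitude anchor, not a certified value.
TSP_REFERENCE_D = 5.0e-10


@dataclass(frozen=True)
class SolventContext:
    """Solvent conditions for sizing: temperature, viscosity, TSP anchor."""

    temperature: float = 298.0
    viscosity: float = WATER_VISCOSITY_298K
    tsp_reference_D: float = TSP_REFERENCE_D
    boltzmann_k: float = BOLTZMANN_K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0 Pa s")
        if self.tsp_reference_D <= 0:
            raise ValueError("tsp_reference_D must be > 0")


def viscosity_correction(
    D_analyte_obs: float, D_tsp_obs: float, ctx: SolventContext = SolventContext()
) -> float:
    """Rescale an observed D by the TSP internal-reference ratio.

    corrected D = D_obs × (D_TSP,reference / D_TSP,observed).  When the TSP
    diffuses at its reference value the analyte D is returned unchanged.
    """
    if D_analyte_obs <= 0:
        raise ValueError("analyte diffusion coefficient must be > 0")
    if D_tsp_obs <= 0:
        raise ValueError("observed TSP diffusion coefficient must be > 0")
    return D_analyte_obs * (ctx.tsp_reference_D / D_tsp_obs)


def stokes_einstein_diameter(D: float, ctx: SolventContext = SolventContext()) -> float:
    """Hydrodynamic diameter d_H = kT/(3πηD), in metres."""
    if D <= 0:
        raise ValueError("diffusion coefficient must be > 0")
    import math

    return ctx.boltzmann_k * ctx.temperature / (3.0 * math.pi * ctx.viscosity * D)


def volume_ratio(
    D_before: float, D_after: float, ctx: SolventContext = SolventContext()
) -> float:
    """Sphere-volume ratio implied by two diffusion coefficients.

    Stokes-Einstein diameters scale as 1/D, so volume scales as D^-3 and
    the ratio V_after/V_before = (D_before/D_after)^3.  A diffusion decrease
    by 4^(1/3) therefore reads out as a four-fold micelle-volume increase.
    """
    if D_before <= 0 or D_after <= 0:
        raise ValueError("diffusion coefficients must be > 0")
    return (D_before / D_after) ** 3


def free_fraction(
    D_obs: float,
    D_free: float,
    D_micelle: float,
    clamp_tolerance: float = 0.05,
) -> float:
    """Free-monomer mole fraction under fast two-site exchange.

    x = (D_obs − D_micelle)/(D_free − D_micelle).  Noise can push D_obs
    slightly outside [D_micelle, D_free]; values within ``clamp_tolerance``
    of the range are clamped with a warning, larger excursions are rejected
    as inconsistent endpoints.
    """
    if D_free <= D_micelle:
        raise ValueError("D_free must exceed D_micelle")
    x = (D_obs - D_micelle) / (D_free - D_micelle)
    if x < -clamp_tolerance or x > 1.0 + clamp_tolerance:
        raise ValueError(
            f"D_obs={D_obs:.3e} outside [D_micelle, D_free] by more than "
            f"tolerance {clamp_tolerance}: free fraction {x:.3f}"
        )
    if x < 0.0 or x > 1.0:
        warnings.warn(
            f"free fraction {x:.3f} outside [0, 1]; clamped (noise at an endpoint)",
            stacklevel=2,
        )
        x = min(max(x, 0.0), 1.0)
    return x
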