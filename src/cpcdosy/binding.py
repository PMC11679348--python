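"""1:1 host-guest binding from observed diffusion (HEC as a DRA proxy).

Hydroxyethyl cellulose (HEC) stands in for the cellulose disk of the disk
retention assay: the fraction of CPC bound to HEC in solution is read out
from the population-weighted diffusion coefficient under fast exchange,

    D_obs = X_G * D_G + X_HG * D_HG,            (X_G = 1 - X_HG)

and converted to a 1:1 association constant by mass action,

    K_a = X_HG / ((1 - X_HG) * ([H]0 - X_HG * [G]0)).

The host (HEC) is polymeric and assumed to diffuse unchanged on binding, so
D_HG is taken equal to the host's own diffusion coefficient unless
overridden.  Host "concentration" for HEC is a binding-site molarity; the
conversion from mg/mL uses a configurable mass per site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .hydrodynamics import free_fraction as _clamped_fraction

__all__ = [
    "BindingSystem",
    "BindingResult",
    "KaFit",
    "predict_D_obs",
    "bound_fraction",
    "association_constant",
    "solve_bound_fraction",
    "fit_Ka_titration",
    "hec_diffusion_shift",
    "hec_sites_molar",
]


@dataclass(frozen=True)
class BindingSystem:
    """Endpoint diffusion coefficients and total concentrations of a 1:1 pair."""

    D_G: float
    D_HG: float
    host_total: float
    guest_total: float

    def __post_init__(self) -> None:
        if not (self.D_G > self.D_HG > 0):
            raise ValueError("need D_G > D_HG > 0")
        if self.host_total <= 0 or self.guest_total <= 0:
            raise ValueError("total concentrations must be > 0")


@dataclass(frozen=True)
class BindingResult:
    X_HG: float
    K_a: float
    percent_bound: float


@dataclass(frozen=True)
class KaFit:
    """Titration fit: K_a with bootstrap percentile CI and per-point fractions."""

    K_a: float
    ci_low: float | None
    ci_high: float | None
    bound_fractions: tuple[float, ...]
    residual_sse: float


def hec_sites_molar(hec_mg_per_ml: float, mass_per_site_g_per_mol: float = 250.0) -> float:
    """Convert an HEC loading in mg/mL to a binding-site molarity.

    HEC is polymeric with no single molar mass; the effective binding-site
    concentration is the mass loading divided by a configurable mass per
    site (default 250 g/mol, roughly one substituted anhydroglucose unit).
    """
    if hec_mg_per_ml < 0:
        raise ValueError("HEC loading must be non-negative")
    if mass_per_site_g_per_mol <= 0:
        raise ValueError("mass per site must be > 0")
    return hec_mg_per_ml / mass_per_site_g_per_mol  # (mg/mL == g/L) / (g/mol) = M


def predict_D_obs(X_HG: float, system: BindingSystem) -> float:
    """Population-weighted observed diffusion for bound fraction X_HG."""
    if not 0.0 <= X_HG <= 1.0:
        raise ValueError("X_HG must lie in [0, 1]")
    return (1.0 - X_HG) * system.D_G + X_HG * system.D_HG


def bound_fraction(
    D_obs: float, system: BindingSystem, clamp_tolerance: float = 0.05
) -> float:
    """Invert the fast-exchange average: X_HG = (D_G − D_obs)/(D_G − D_HG).

    Clamped with a warning when noise pushes D_obs marginally outside
    [D_HG, D_G]; rejected beyond ``clamp_tolerance``.
    """
    # same clamping contract as the micelle free fraction, mirrored axis
    x_free = _clamped_fraction(D_obs, system.D_G, system.D_HG, clamp_tolerance)
    return 1.0 - x_free


def association_constant(X_HG: float, system: BindingSystem) -> float:
    """1:1 mass-action association constant from the bound fraction.

    K_a = X_HG / ((1−X_HG)·([H]₀ − X_HG·[G]₀)), in M⁻¹.  Unidentifiable at
    the endpoints X_HG ∈ {0, 1}; invalid when the bound guest would exceed
    the available host.
    """
    if not 0.0 < X_HG < 1.0:
        raise ValueError("K_a is unidentifiable at X_HG = 0 or 1")
    free_host = system.host_total - X_HG * system.guest_total
    if free_host <= 0:
        raise ValueError(
            "invalid stoichiometry: bound guest exceeds total host "
            f"([H]0={system.host_total:.3e}, X_HG*[G]0={X_HG * system.guest_total:.3e})"
        )
    return X_HG / ((1.0 - X_HG) * free_host)


def solve_bound_fraction(K_a: float, host_total: float, guest_total: float) -> float:
    """Forward 1:1 equilibrium: bound fraction from K_a and totals.

    Solves K_a·c² − (K_a([H]₀+[G]₀)+1)·c + K_a[H]₀[G]₀ = 0 for the complex
    concentration c and returns X_HG = c/[G]₀ (the physical root in [0, 1]).
    """
    if K_a < 0:
        raise ValueError("K_a must be non-negative")
    if host_total < 0 or guest_total <= 0:
        raise ValueError("concentrations must be valid (host >= 0, guest > 0)")
    if K_a == 0 or host_total == 0:
        return 0.0
    a = K_a
    b = -(K_a * (host_total + guest_total) + 1.0)
    c0 = K_a * host_total * guest_total
    disc = b * b - 4.0 * a * c0
    if disc < 0:
        raise ValueError("no real equilibrium root: inconsistent inputs")
    # smaller root is the physical one (complex cannot exceed either total)
    complex_conc = (-b - np.sqrt(disc)) / (2.0 * a)
    x = complex_conc / guest_total
    if not -1e-12 <= x <= 1.0 + 1e-12:
        raise ValueError(f"equilibrium root {x:.4f} outside [0, 1]")
    return float(min(max(x, 0.0), 1.0))


def binding_result(D_obs: float, system: BindingSystem) -> BindingResult:
    """Bundle bound fraction, K_a and percent bound for one observation."""
    x = bound_fraction(D_obs, system)
    ka = association_constant(x, system)
    return BindingResult(X_HG=x, K_a=ka, percent_bound=100.0 * x)


def fit_Ka_titration(
    host_concs,
    D_obs,
    D_G: float,
    D_HG: float,
    guest_total: float,
    bootstrap: int = 0,
    seed: int = 0,
) -> KaFit:
    """Least-squares K_a over a titration of host loadings.

    Fits log10(K_a) by minimising the residuals between observed diffusion
    coefficients and the 1:1 isotherm prediction.  A single titration point
    reduces exactly to the direct inversion via
    :func:`association_constant`.  ``bootstrap`` > 0 adds a residual-
    resampling percentile CI (95%).
    """
    h = np.asarray(host_concs, dtype=float)
    d = np.asarray(D_obs, dtype=float)
    if h.size == 0 or h.size != d.size:
        raise ValueError("need >= 1 paired (host_conc, D_obs) point")

    def predict(log10_ka: float) -> np.ndarray:
        ka = 10.0**log10_ka
        xs = np.array([solve_bound_fraction(ka, hi, guest_total) for hi in h])
        return (1.0 - xs) * D_G + xs * D_HG

    if h.size == 1:
        system = BindingSystem(D_G=D_G, D_HG=D_HG, host_total=float(h[0]), guest_total=guest_total)
        x = bound_fraction(float(d[0]), system)
        ka = association_constant(x, system)
        return KaFit(K_a=ka, ci_low=None, ci_high=None, bound_fractions=(x,), residual_sse=0.0)

    span = D_G - D_HG
    x_seen = (D_G - d) / span
    if np.all(x_seen > 0.98):
        raise ValueError("all titration points at saturation: K_a unidentifiable")

    def solve(data):
        def r(p):
            return (predict(p[0]) - data) / span

        sol = least_squares(r, x0=[3.0], bounds=([-6.0], [12.0]))
        return float(10.0 ** sol.x[0]), float(sol.fun @ sol.fun * span**2)

    ka_hat, sse = solve(d)

    ci_low = ci_high = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        fitted = predict(np.log10(ka_hat))
        residuals = d - fitted
        draws = []
        for _ in range(bootstrap):
            d_star = fitted + rng.choice(residuals, size=residuals.size, replace=True)
            try:
                ka_b, _ = solve(d_star)
            except ValueError:
                continue
            draws.append(ka_b)
        if draws:
            ci_low, ci_high = (float(q) for q in np.quantile(draws, [0.025, 0.975]))

    xs = tuple(
        float(np.clip((D_G - di) / span, 0.0, 1.0)) for di in d
    )
    return KaFit(K_a=ka_hat, ci_low=ci_low, ci_high=ci_high, bound_fractions=xs, residual_sse=sse)


def hec_diffusion_shift(D_without_HEC: float, D_with_HEC: float) -> tuple[float, float]:
    """Diffusion change on HEC addition: (ΔD, percent of the HEC-free value).

    ΔD = D_without − D_with; a positive value means HEC slowed the guest.
    """
    if D_without_HEC <= 0 or D_with_HEC <= 0:
        raise ValueError("diffusion coefficients must be > 0")
    delta = D_without_HEC - D_with_HEC
    return delta, 100.0 * delta / D_without_HEC
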