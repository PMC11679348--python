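"""Synthetic inputs with known ground truth for the whole pipeline.

No raw experimental data accompany the CPC availability study this package
models, so every pipeline input is generated here under the same
statistical assumptions the analysis makes:

* PGSE decays are mono-exponential in b with additive Gaussian noise (a
  fraction of I0 — the high-SNR regime of 1024-scan acquisitions; a Rician
  noise floor is deliberately out of scope).
* Fast two-site exchange: a single observed decay with
  D_obs = x·D_free + (1−x)·D_micelle.
* HEC binding follows a 1:1 isotherm; titrations solve the exact quadratic
  equilibrium for the bound fraction.
* qNMR peak integrals carry multiplicative noise.
* Plate counts are Poisson around surviving CFU × dilution factor.
* Formulation panels tie it together: dose and excipient flags set a latent
  free fraction, which sets D_obs and [CPC]_f, and the log10 kill increases
  with both (matching the sign structure the NMR assay is meant to predict),
  plus Gaussian replicate noise.  DRA responds to [CPC]_f with Michaelis-type
  saturation (the assay saturates near 0.3% CPC).

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binding import solve_bound_fraction
from .formulation import FormulationRecord
from .pgse import AcquisitionParams, DecayCurve
from .quantitation import PeakRecord

__all__ = [
    "GroundTruth",
    "PanelEffectConfig",
    "PanelSimulation",
    "DEFAULT_GRADIENTS",
    "simulate_decay",
    "simulate_two_site_decay",
    "simulate_binding_titration",
    "simulate_formulation_panel",
    "simulate_plate_counts",
    "simulate_peak_tables",
]

#: Default 16-step gradient ramp, T/m (2%..~95% of a 0.53 T/m max gradient).
DEFAULT_GRADIENTS = tuple(np.linspace(0.02, 0.50, 16))


@dataclass(frozen=True)
class GroundTruth:
    """Latent parameters a simulation is built from (and recovery is judged
    against)."""

    true_D_per_species: dict[str, float] = field(
        default_factory=lambda: {"cpc": 4.4e-10}
    )
    free_fraction: float = 1.0
    K_a: float = 1000.0  # M^-1
    host_conc: float = 1e-3  # M
    guest_conc: float = 1e-4  # M
    true_log_kill: float = 5.0
    noise_sd: float = 0.0  # fraction of I0

    def __post_init__(self) -> None:
        if not self.true_D_per_species:
            raise ValueError("need at least one species")
        if any(d <= 0 for d in self.true_D_per_species.values()):
            raise ValueError("diffusion coefficients must be positive")
        if not 0.0 <= self.free_fraction <= 1.0:
            raise ValueError("free_fraction must lie in [0, 1]")
        if self.K_a <= 0 or self.host_conc <= 0 or self.guest_conc <= 0:
            raise ValueError("K_a and concentrations must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _check_gradients(gradients) -> np.ndarray:
    g = np.asarray(gradients, dtype=float)
    if g.size == 0:
        raise ValueError("gradient list is empty")
    if g.size < 2 or np.unique(g).size < 2:
        raise ValueError("need at least 2 distinct gradient strengths")
    if np.any(g < 0):
        raise ValueError("gradient strengths must be non-negative")
    return g


def simulate_decay(
    truth: GroundTruth,
    acq: AcquisitionParams,
    gradients=DEFAULT_GRADIENTS,
    seed: int = 0,
    species: str | None = None,
    I0: float = 1.0,
) -> DecayCurve:
    """One Stejskal-Tanner decay for a species of ``truth``.

    Intensities are I0·exp(−b(g)·D) plus additive Gaussian noise of standard
    deviation ``truth.noise_sd × I0``.  ``species`` may be omitted when the
    ground truth holds a single species.
    """
    from .pgse import b_factor

    g = _check_gradients(gradients)
    if species is None:
        if len(truth.true_D_per_species) != 1:
            raise ValueError("multiple species in truth: pass species=")
        species = next(iter(truth.true_D_per_species))
    D = truth.true_D_per_species[species]
    rng = np.random.default_rng(seed)
    intensities = I0 * np.exp(-b_factor(acq, g) * D)
    if truth.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, truth.noise_sd * I0, size=g.size)
    return DecayCurve(g, intensities, peak_label=species)


def simulate_two_site_decay(
    D_free: float,
    D_micelle: float,
    free_fraction: float,
    acq: AcquisitionParams,
    gradients=DEFAULT_GRADIENTS,
    seed: int = 0,
    noise_sd: float = 0.0,
    I0: float = 1.0,
) -> DecayCurve:
    """Fast-exchange decay: mono-exponential at D_obs = x·D_f + (1−x)·D_m."""
    if not D_free > D_micelle > 0:
        raise ValueError("need D_free > D_micelle > 0")
    if not 0.0 <= free_fraction <= 1.0:
        raise ValueError("free_fraction must lie in [0, 1]")
    D_obs = free_fraction * D_free + (1.0 - free_fraction) * D_micelle
    truth = GroundTruth(true_D_per_species={"cpc_fast_exchange": D_obs}, noise_sd=noise_sd)
    return simulate_decay(truth, acq, gradients, seed=seed, I0=I0)


def simulate_binding_titration(
    K_a: float,
    D_G: float,
    D_H: float,
    guest_conc: float,
    host_concs,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """Observed guest diffusion across a host titration (1:1 isotherm).

    For each host concentration the exact quadratic equilibrium gives the
    bound fraction X_HG, and D_obs = (1−X_HG)·D_G + X_HG·D_H, with
    multiplicative Gaussian noise of relative sd ``noise_sd``.
    """
    if K_a <= 0:
        raise ValueError("K_a must be positive")
    if not D_G > D_H > 0:
        raise ValueError("need D_G > D_H > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    h = np.asarray(host_concs, dtype=float)
    if h.size == 0:
        raise ValueError("host concentration list is empty")
    xs = np.array([solve_bound_fraction(K_a, hi, guest_conc) for hi in h])
    d_obs = (1.0 - xs) * D_G + xs * D_H
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        d_obs = d_obs * (1.0 + rng.normal(0.0, noise_sd, size=h.size))
    return d_obs


# ---------------------------------------------------------------------------
# Formulation panel
# ---------------------------------------------------------------------------

#: Excipient flags with (sampling probability, latent free-fraction effect).
_EXCIPIENT_EFFECTS: dict[str, tuple[float, float]] = {
    "cremophor": (0.30, -0.35),
    "poloxamer_407": (0.30, -0.10),
    "paraben": (0.40, -0.12),
    "phosphate": (0.30, -0.08),
    "flavour": (0.50, -0.03),
}


@dataclass(frozen=True)
class PanelEffectConfig:
    """Generative settings of a formulation panel.

    Defaults describe a mouthwash-like panel: CPC doses bracketing the
    commercial 0.07–0.1% w/w and the DRA saturation point near 0.3%, free
    monomer and micelle endpoint diffusivities of a C16 surfactant, a 0.3
    log10 replicate noise on the time-kill readout and 1%-scale relative
    noise on NMR-derived quantities.
    """

    dose_pct_range: tuple[float, float] = (0.03, 0.30)
    cpc_molar_mass: float = 340.0  # g/mol
    D_free: float = 4.4e-10  # m^2/s, monomeric CPC
    D_micelle: float = 0.9e-10  # m^2/s, CPC micelle
    D_hec: float = 2.0e-11  # m^2/s, HEC polymer
    base_free_fraction: float = 0.85
    dose_micellisation_slope: float = 0.15  # extra micellisation across the dose range
    free_fraction_jitter_sd: float = 0.05
    # log_kill = a0 + a1*[CPC]_f(M) + a2*(log10 D_obs - log10 D_micelle) + eps
    activity_intercept: float = 1.5
    activity_coef_cpc_free: float = 550.0  # per M
    activity_coef_log10_D: float = 1.2  # per decade
    log_kill_noise_sd: float = 0.3
    diffusion_noise_sd: float = 0.01
    qnmr_noise_sd: float = 0.01
    # DRA: Michaelis-type in [CPC]_f, saturating around the 0.3% dose scale
    dra_max: float = 100.0
    dra_half_saturation: float = 1.5e-3  # M
    dra_noise_sd: float = 0.05
    # HEC binding latent: bound fraction rises as the free fraction falls
    hec_bound_base: float = 0.25
    hec_bound_slope: float = 0.40
    hec_bound_jitter_sd: float = 0.08
    excipient_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_EXCIPIENT_EFFECTS)
    )


@dataclass
class PanelSimulation:
    """A simulated panel: observable records plus the hidden ground truth."""

    records: list[FormulationRecord]
    truths: list[GroundTruth]
    latent_log_kill: np.ndarray
    latent_free_fraction: np.ndarray
    config: PanelEffectConfig


def _latent_activity(cfg: PanelEffectConfig, cpc_free: float, D_obs: float) -> float:
    return (
        cfg.activity_intercept
        + cfg.activity_coef_cpc_free * cpc_free
        + cfg.activity_coef_log10_D * (math.log10(D_obs) - math.log10(cfg.D_micelle))
    )


def simulate_formulation_panel(
    n: int,
    effect_config: PanelEffectConfig | None = None,
    seed: int = 0,
) -> PanelSimulation:
    """Generate ``n`` formulations with hidden ground truth.

    Dose and excipient flags determine a latent free fraction; the observed
    diffusion coefficient, [CPC]_f, DRA value and log10 kill follow from it
    with the configured noise.  Deterministic for a fixed seed.
    """
    if n < 2:
        raise ValueError("a panel needs at least 2 formulations")
    cfg = effect_config or PanelEffectConfig()
    rng = np.random.default_rng(seed)

    lo, hi = cfg.dose_pct_range
    records: list[FormulationRecord] = []
    truths: list[GroundTruth] = []
    latents = np.empty(n)
    latent_x = np.empty(n)
    for i in range(n):
        dose_pct = rng.uniform(lo, hi)
        flags = frozenset(
            name for name, (p, _) in cfg.excipient_effects.items() if rng.random() < p
        )
        x = cfg.base_free_fraction
        x += sum(eff for name, (_, eff) in cfg.excipient_effects.items() if name in flags)
        x -= cfg.dose_micellisation_slope * (dose_pct - lo) / max(hi - lo, 1e-12)
        x += rng.normal(0.0, cfg.free_fraction_jitter_sd) if cfg.free_fraction_jitter_sd else 0.0
        x = float(np.clip(x, 0.02, 0.98))

        total_cpc = dose_pct / 100.0 * 1000.0 / cfg.cpc_molar_mass  # %w/w -> g/L -> M
        D_true = x * cfg.D_free + (1.0 - x) * cfg.D_micelle
        cpc_free_true = x * total_cpc
        latent = _latent_activity(cfg, cpc_free_true, D_true)

        D_obs = D_true * (
            1.0 + (rng.normal(0.0, cfg.diffusion_noise_sd) if cfg.diffusion_noise_sd else 0.0)
        )
        cpc_free_obs = cpc_free_true * (
            1.0 + (rng.normal(0.0, cfg.qnmr_noise_sd) if cfg.qnmr_noise_sd else 0.0)
        )
        b = cfg.hec_bound_base + cfg.hec_bound_slope * (1.0 - x)
        b += rng.normal(0.0, cfg.hec_bound_jitter_sd) if cfg.hec_bound_jitter_sd else 0.0
        b = float(np.clip(b, 0.0, 0.95))
        D_with_hec = (1.0 - b) * D_obs + b * cfg.D_hec
        dra = cfg.dra_max * cpc_free_true / (cpc_free_true + cfg.dra_half_saturation)
        dra *= 1.0 + (rng.normal(0.0, cfg.dra_noise_sd) if cfg.dra_noise_sd else 0.0)
        log_kill = latent + (
            rng.normal(0.0, cfg.log_kill_noise_sd) if cfg.log_kill_noise_sd else 0.0
        )

        records.append(
            FormulationRecord(
                id=f"F{i + 1:03d}",
                cpc_dose_pct=dose_pct,
                cpc_free_conc=cpc_free_obs,
                D_obs=D_obs,
                D_obs_with_hec=D_with_hec,
                dra_value=float(dra),
                log_kill=float(log_kill),
                bound_percent=100.0 * b,
                excipient_flags=flags,
            )
        )
        truths.append(
            GroundTruth(
                true_D_per_species={"cpc_free": cfg.D_free, "cpc_micelle": cfg.D_micelle},
                free_fraction=x,
                true_log_kill=float(latent),
                noise_sd=cfg.diffusion_noise_sd,
            )
        )
        latents[i] = latent
        latent_x[i] = x
    return PanelSimulation(
        records=records,
        truths=truths,
        latent_log_kill=latents,
        latent_free_fraction=latent_x,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Plate counts and peak tables
# ---------------------------------------------------------------------------

def simulate_plate_counts(
    true_log_kill: float,
    initial_cfu_per_ml: float,
    dilutions=(-5, -4, -3, -2),
    seed: int = 0,
    plated_volume_ml: float = 1.0,
    n_plates: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson plate counts from a serial dilution of the survivors.

    Survivors are initial × 10^−log_kill CFU/mL; each of ``n_plates``
    duplicate plates at dilution exponent e receives an expected
    survivors × 10^e × plated volume colonies.  Returns parallel arrays of
    dilution exponents (one entry per plate) and colony counts.
    """
    if initial_cfu_per_ml <= 0:
        raise ValueError("initial CFU/mL must be positive")
    dil = np.asarray(dilutions, dtype=float)
    if dil.size == 0:
        raise ValueError("dilution list is empty")
    survivors = initial_cfu_per_ml * 10.0 ** (-true_log_kill)
    rng = np.random.default_rng(seed)
    exps = np.repeat(dil, n_plates)
    lam = survivors * 10.0**exps * plated_volume_ml
    counts = rng.poisson(lam)
    return exps, counts


def simulate_peak_tables(
    total_cpc_conc: float,
    standard_conc: float = 100e-6,
    attenuation_pct: float = 10.0,
    broadening_hz: float = 1.0,
    integral_noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[list[PeakRecord], list[PeakRecord]]:
    """Pre/post-HEC peak tables for the CPC aromatic reporters and TSP.

    Integrals are proportional to concentration × proton count with
    multiplicative Gaussian noise; the post-HEC table applies the given
    signal attenuation to the CPC peaks and adds the FWHM broadening.
    Returns (pre_hec, post_hec) lists with TSP last in each.
    """
    if total_cpc_conc <= 0 or standard_conc <= 0:
        raise ValueError("concentrations must be positive")
    if integral_noise_sd < 0:
        raise ValueError("integral noise must be non-negative")
    rng = np.random.default_rng(seed)
    unit = 1e4  # arbitrary integral units per (M * proton)
    peaks = [  # (label, shift, protons, fwhm)
        ("H1", 8.9, 2, 2.0),
        ("H3", 8.6, 1, 2.2),
        ("H2", 8.1, 2, 2.1),
    ]

    def noisy(value: float) -> float:
        if integral_noise_sd == 0:
            return value
        return value * (1.0 + float(rng.normal(0.0, integral_noise_sd)))

    pre: list[PeakRecord] = []
    post: list[PeakRecord] = []
    for label, shift, n_h, fwhm in peaks:
        area = total_cpc_conc * n_h * unit
        pre.append(PeakRecord(shift, noisy(area), fwhm, n_h, label=label))
        post.append(
            PeakRecord(
                shift,
                noisy(area * (1.0 - attenuation_pct / 100.0)),
                fwhm + broadening_hz,
                n_h,
                label=label,
            )
        )
    tsp_area = standard_conc * 9 * unit
    for table in (pre, post):
        table.append(PeakRecord(0.0, noisy(tsp_area), 1.5, 9, label="TSP"))
    return pre, post
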