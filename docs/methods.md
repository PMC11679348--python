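# Methods

`cpcdosy` models the *availability* of cetylpyridinium chloride (CPC) — a
cationic surfactant antimicrobial used in non-alcohol mouthwashes — from NMR
diffusion measurements. Only the free monomer, CPC_f, carries antimicrobial
action; CPC sequestered in micelles (CPC_m) or in mixed micelles with block
copolymers is largely inert and also escapes the traditional disk retention
assay (DRA). The pipeline turns pulsed-field-gradient (PGSE/DOSY) decay
tables and 1D peak tables into free-fraction, binding and activity
predictions. This note records the models, the defaults, and the choices
made where the design was genuinely open.

## Diffusion decay model

Signal attenuation in a PGSE experiment follows the Stejskal–Tanner law

    I(g) = I0 · exp(−γ² g² δ² (Δ − δ/3) · D) = I0 · exp(−b(g) · D)

with γ the gyromagnetic ratio (¹H default 2.6752218744×10⁸ rad s⁻¹ T⁻¹),
δ the effective gradient pulse duration, Δ the diffusion time and g the
gradient strength in T/m. Everything internal is SI.

**δ convention.** Bipolar gradient-pair sequences specify a single-lobe
pulse length (vendor parameter P30); the effective δ entering b is twice
that. `AcquisitionParams.from_bipolar` and the `delta_convention` config key
("bipolar" default, "monopolar" alternative) make the choice explicit
because the convention is a recurring source of factor-of-4 errors in b.
Defaults: pulse 0.75 ms (so δ_eff = 1.5 ms), Δ = 0.1 s, a 16-step gradient
ramp from 0.02 to 0.50 T/m. With these settings b_max ≈ 4.0×10⁹ s/m², which
attenuates a 4×10⁻¹⁰ m²/s species to ~20% — a well-conditioned design for
small-molecule D.

**Mono-exponential fitting** is nonlinear least squares on (I0, D),
initialised from the ordinary regression of ln I on b (non-positive
intensities are excluded from the initialisation only). The trust-region
solver is given explicit parameter scales: I0 and D differ by ~12 orders of
magnitude and an unscaled step policy cannot move D at all. Curves with no
attenuation raise `FitConvergenceError` rather than returning D ≈ 0: a
boundary solution is not a diffusion measurement.

**Two-component fitting** (needed where CPC and HEC peaks overlap) fits
I0·(w e^{−bD₁} + (1−w) e^{−bD₂}) in an unconstrained reparametrisation
(log I0, logit w, log D₁, log D₂) by Levenberg–Marquardt, which handles the
parameter scales and keeps positivity by construction. Sums of exponentials
have local minima, so five starts are used, jittered around the
mono-exponential estimate at log-spaced splits. The two-component model is
accepted only when the small-sample corrected information criterion (AICc,
SSE form) favours it; ties go to the simpler model. Two degeneracy guards
then apply:

* components closer than a factor 1.02 in D, or with weight < 10⁻⁶,
  collapse to the mono fit (an unidentifiable split);
* each component must retain an attenuation factor above 10⁻³ at three or
  more gradient points. A "component" visible at fewer points is a
  noise-spike absorber aliasing I0, not a resolvable species — without this
  guard a 1%-noise single-species curve occasionally sprouts a spurious
  ultra-fast component.

**Uncertainty** is a residual-resampling bootstrap: resample fitted
residuals, refit, take k × sd(D̂) as a percentage of D̂ (k = 2 gives ~95%
coverage, the usual expanded-uncertainty convention). Fitted residuals
understate the noise variance by (n−p)/n, so residuals are inflated by
√(n/(n−p)) before resampling; without this the k = 2 interval covers truth
in slightly under 90% of 1%-noise replicates, with it ~93%. B ≥ 100
replicates are required. For two-component fits the reported uncertainty is
that of the faster component.

## Viscosity correction and sizing

Bulk viscosity differs between formulations; TSP, the water-soluble
internal standard, does not partition into micelles, so its observed
diffusion tracks viscosity alone. Corrected analyte D = D_obs ×
(D_TSP,ref / D_TSP,obs). The reference TSP diffusion (`tsp_reference_D`,
default 5.0×10⁻¹⁰ m²/s) is a configuration constant at the literature scale
for a 172 g/mol molecule in water at 298 K — calibrate it per spectrometer;
it is deliberately never hard-coded inside computations.

Stokes–Einstein gives the hydrodynamic *diameter* d_H = kT/(3πηD)
(spherical species, stick boundary). Defaults: 298 K, η = 8.904×10⁻⁴ Pa·s
(water at 298 K). Micelle growth is reported as the implied sphere-volume
ratio (D_before/D_after)³, so a diffusion decrease by 4^(1/3) reads out as
a four-fold volume increase. Non-spherical shape factors and obstruction
corrections are out of scope.

## Two-site exchange and 1:1 binding

Above the CMC, free and micellised CPC interconvert fast on the NMR
timescale, so one population-weighted coefficient is observed:
D_obs = x·D_free + (1−x)·D_micelle, giving the free fraction
x = (D_obs − D_micelle)/(D_free − D_micelle). The endpoint values
D_free/D_micelle are calibration inputs (pure-CPC below/above CMC); noise
can push D_obs marginally outside the interval, so excursions within 0.05
of the valid range are clamped with a warning and larger ones rejected.

HEC (hydroxyethyl cellulose) serves as an in-solution mimic of the DRA's
cellulose disk. Binding is modelled as a 1:1 fast-exchange isotherm with
the host assumed to diffuse unchanged when bound (HEC is a polymer; a bound
CPC molecule does not slow it), so D_HG equals the host's own diffusion:

    D_obs = (1 − X_HG)·D_G + X_HG·D_HG
    K_a  = X_HG / ((1 − X_HG)·([H]₀ − X_HG·[G]₀))

K_a is unidentifiable at X_HG ∈ {0, 1} and invalid when bound guest would
exceed total host; both are signalled. The forward equilibrium solves the
quadratic K_a c² − (K_a([H]₀+[G]₀)+1)c + K_a[H]₀[G]₀ = 0 for the complex
concentration (smaller root). HEC has no molar mass, so a mg/mL loading is
converted to a binding-site molarity via a configurable mass per site
(default 250 g/mol ≈ one substituted anhydroglucose unit); the 10 mg/mL
standard loading is then 40 mM of sites. `fit_Ka_titration` generalises the
single-point inversion to multiple host loadings by least squares on
log₁₀K_a (bounded to [10⁻⁶, 10¹²] M⁻¹), reducing exactly to the direct
inversion for one point, with an optional residual-resampling percentile CI.

## qNMR and spectral-change metrics

Concentration by the primary ratio method:
C = C_std · (I_a/I_std) · (N_std/N_a), default reporters pyridinium H1
(8.9 ppm, 2 protons) against TSP (9 protons, 100 µM). Signal attenuation
(%) and FWHM broadening (Hz) on HEC addition are kept as raw before/after
differences — in practice they plateau (~1 Hz, ~10%) and are less
predictive than diffusion, so no model is fitted to them. [CPC]_f composes
the qNMR total with the two-site fraction: [CPC]_f = x · [CPC]_total. Both
pathways to a free concentration (pure qNMR of visible signal, and the
diffusion-partitioned fraction) are exposed, since which one a given
dataset supports depends on how its peak tables were integrated.

## Panel analytics

* **Regressions**: OLS with r² = squared Pearson correlation. Diffusion
  enters as log₁₀(D) — its physical meaning (size) is logarithmic and the
  raw values span decades.
* **Activity classifier**: a linear predictor of log₁₀ kill on
  ([CPC]_f, log₁₀ D_obs), fitted by least squares on complete records
  (`fit_activity_predictor`); a record is called acceptable when the
  prediction exceeds 5 log₁₀, vetoed whenever HEC-bound CPC ≥ 50%. The
  boundary coefficients are data-fitted, not constants: no published
  numeric region exists to freeze.
* **PCA**: per-variable z-scoring (mixed units demand scale invariance)
  then SVD. Records missing any selected variable are dropped and counted;
  zero-variance variables are dropped with a warning. Component signs are
  fixed by making each loading's largest-magnitude entry positive, so
  output is fully deterministic.
* **Time-kill arithmetic**: survivors/mL from plates within the 30–300
  colony countable window (standard plate-count practice), averaged across
  countable plates; log kill = log₁₀(initial) − log₁₀(survivors). An
  all-zero series is censored at the detection limit (one colony on the
  most concentrated plate) and flagged, never reported as infinite kill.

## Synthetic data: what it emulates, what it does not

The generators in `cpcdosy.synthetic` produce every input format the
pipeline reads, with the latent truth returned alongside. Default study
conditions, chosen once as realistic for this system:

| quantity | default | why |
|---|---|---|
| gradient ramp | 16 steps, 0.02–0.50 T/m | 16 increments in the diffusion dimension; b_max conditions small-molecule D |
| decay noise | additive Gaussian, sd = 1% of I0 | 1024-scan high-SNR regime |
| D_free / D_micelle / D_HEC | 4.4×10⁻¹⁰ / 0.9×10⁻¹⁰ / 0.2×10⁻¹⁰ m²/s | monomer ~1.2 nm, micelle ~5 nm, polymer slower still |
| CPC dose | U(0.03, 0.30) % w/w | brackets commercial 0.07–0.1% and the DRA saturation point |
| activity model | 1.5 + 550·[CPC]_f(M) + 1.2·Δlog₁₀D + ε | simplest monotone model with the observed sign structure |
| log-kill noise | sd 0.3 log₁₀ | typical suspension-test replicate scatter |
| DRA | 100·c/(c+1.5 mM), 5% noise | linear then saturating near the 0.3% dose scale |
| plate counts | Poisson, duplicate plates at 10⁻⁵…10⁻² | counting statistics of the dilution series |

Excipient flags (cremophor, poloxamer 407, parabens, phosphate, flavour)
subtract from a base free fraction of 0.85, and micellisation increases
with dose; the bound-to-HEC fraction rises as the free fraction falls.
Noise enters through one seeded `numpy` generator per call.

What the generator does **not** emulate: Rician noise floors, baseline and
phase errors, chemical-shift drift, peak overlap beyond the two-component
decay case, gelation of HEC above ~30 mg/mL, cooperative or higher-order
binding, and inter-batch formulation variability. Passing tests therefore
demonstrate that the *estimators invert their own generative assumptions*
at realistic noise — they cannot certify performance on spectrometer data
whose artefacts violate those assumptions.

## Numerical choices and limitations

* Fit tolerances are set to 10⁻¹⁴–10⁻¹⁵ (the fits are cheap; the round-trip
  contract is 0.01% on noiseless input).
* Model selection deliberately errs toward the mono-exponential model;
  a true second component closer than ~2% in D will not be reported.
* The bootstrap assumes exchangeable homoscedastic residuals; at very low
  SNR (attenuation into the noise floor) its coverage degrades.
* K_a from a single titration point inherits the full error of the endpoint
  calibration (D_G, D_HG); multi-point titrations average it down.
* The activity classifier is correlational; it ranks formulations within a
  chassis and flags HEC-sequestered CPC, it does not establish mechanism.

## Problem sizes

The test suite and the acceptance script run Monte-Carlo checks at 100–500
replicates per property (fit robustness 100–200 seeds with B = 100
bootstrap replicates, titration recovery 200 seeds, qNMR CV 500 seeds,
plate counts 500 seeds, panels of 200 formulations). These sizes give
binomial/median estimates tight enough for the stated tolerances while
keeping a full run in minutes on one core.
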