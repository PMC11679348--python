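# cpcdosy

NMR diffusion modelling of **cetylpyridinium chloride (CPC) availability**
in antimicrobial formulations.

CPC is the active in most non-alcohol mouthwashes, but only the free
monomer (CPC_f) kills bacteria — CPC locked in micelles or in mixed
micelles with block-copolymer excipients is largely inert, and it also
slips through the traditional disk retention assay (DRA). Diffusion NMR
sees this directly: free CPC diffuses fast, micellised CPC slowly, and
under fast exchange a single population-weighted coefficient is observed.
`cpcdosy` is the analysis chain that turns per-peak decay tables and peak
integrals into availability and activity predictions, for formulation
scientists screening CPC chassis without running a plate assay per variant.

The chain, in the order it runs:

1. **PGSE decay fitting** — Stejskal–Tanner model
   I(g) = I₀·exp(−γ²g²δ²(Δ−δ/3)·D), one or two components per peak,
   bootstrap expanded uncertainty (k = 2).
2. **Viscosity correction & sizing** — TSP internal-reference ratio, then
   Stokes–Einstein d_H = kT/(3πηD) and micelle volume ratios (D ∝ V^(−1/3)).
3. **Two-site free fraction** — x = (D_obs − D_m)/(D_f − D_m), so
   D_obs = x·D_f + (1−x)·D_m.
4. **HEC binding (DRA proxy)** — 1:1 fast-exchange isotherm
   D_obs = (1−X_HG)·D_G + X_HG·D_HG and
   K_a = X_HG/((1−X_HG)([H]₀ − X_HG[G]₀)), single-point or titration fits.
5. **qNMR** — C = C_std·(I_a/I_std)·(N_std/N_a) against 100 µM TSP;
   [CPC]_f = x·[CPC]_total.
6. **Panel analytics** — regressions of log₁₀ kill on [CPC]_f and log₁₀ D,
   z-scored PCA, a >5-log activity classifier with a 50% HEC-binding veto,
   and serial-dilution plate-count arithmetic.

A synthetic-data module generates every input with known ground truth
(decays, titrations, peak tables, formulation panels, plate counts), which
is what the tests and the acceptance script exercise end to end. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
from cpcdosy import (
    AcquisitionParams, GroundTruth, simulate_decay, fit_monoexponential,
    bootstrap_expanded_uncertainty, viscosity_correction,
    stokes_einstein_diameter, free_fraction, cpc_free_concentration,
    SolventContext,
)

# acquisition: bipolar pulse 0.75 ms (effective delta 1.5 ms), Delta 0.1 s
acq = AcquisitionParams.from_bipolar(0.75e-3, 0.1)

# a simulated H1 (8.9 ppm) decay at 1% intensity noise, true D = 3.1e-10
truth = GroundTruth(true_D_per_species={"H1 8.9 ppm": 3.1e-10}, noise_sd=0.01)
curve = simulate_decay(truth, acq, seed=42)

fit = fit_monoexponential(curve, acq)
u = bootstrap_expanded_uncertainty(curve, acq, fit, B=200, k=2.0, seed=42)
print(f"D = {fit.D[0]:.3e} m2/s  (expanded uncertainty k=2: {u:.1f}%)")

ctx = SolventContext()          # 298 K, water viscosity, TSP anchor
D_corr = viscosity_correction(fit.D[0], 4.6e-10, ctx)   # observed TSP D
print(f"viscosity-corrected D = {D_corr:.3e} m2/s")
print(f"hydrodynamic diameter = {stokes_einstein_diameter(D_corr, ctx)*1e9:.2f} nm")

x = free_fraction(D_corr, 4.4e-10, 0.9e-10)  # monomer / micelle endpoints
print(f"free CPC fraction x = {x:.3f}")
print(f"[CPC]_f = {cpc_free_concentration(2.06e-3, x)*1e3:.2f} mM")
```

prints

```
D = 3.083e-10 m2/s  (expanded uncertainty k=2: 2.3%)
viscosity-corrected D = 3.352e-10 m2/s
hydrodynamic diameter = 1.46 nm
free CPC fraction x = 0.700
[CPC]_f = 1.44 mM
```

Reading: the fitted coefficient is within 1% of the simulated truth and the
k = 2 interval covers it. After referencing against TSP the species sizes at
1.46 nm — monomer-like, not micellar — and sits at a free fraction of 0.70,
i.e. 1.44 mM of a 2.06 mM dose (0.07% w/w) is actually available.

The same stages are scriptable from a shell:

```sh
cpcdosy --out run1 simulate --d 4.4e-10 --noise-sd 0.01
cpcdosy --out run1 fit run1/decay.csv
cpcdosy --out run1 panel --simulate-n 100
```

Every output directory carries a `run_log.jsonl` with the config hash, seed
and effective parameters of each stage.

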