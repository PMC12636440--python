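# latcondense

Models of LAT condensate formation on supported lipid bilayers.

In T-cell receptor signaling, the membrane adapter protein LAT (Linker for
Activation of T cells) is crosslinked by cytosolic Grb2:SOS1:Grb2 bridges
and phase-separates into micrometer-scale condensates.  Reconstitution
experiments on supported bilayers show three puzzles: a lag time of up to
tens of minutes before any visible condensation, a zoo of final morphologies
(circular or elongated inclusions, either LAT-rich or LAT-depleted, and
bicontinuous patterns), and patterns that freeze almost immediately once
they appear.  `latcondense` implements two complementary models that explain
these observations, for modelers who want to simulate, fit, or extend them:

* **`latcondense.aggregation`** — a Smoluchowski coagulation model
  dc_i/dt = ½Σ k_{i−j,j}c_{i−j}c_j − c_iΣ k_ij c_j with a composite kernel
  k_ij = k_Br·k_rxn: Evans–Sackmann membrane hydrodynamics for the encounter
  rate of fractal clusters (R_H = R0·i^γH) and a sticking probability
  P·N_ij/(P·N_ij + 1 − P) with N_ij = N11(ij)^σ.  It reproduces the lag time
  t_char2 = (μ^{1/(μ−1)} − 1)/(c̄₁k₁₁) ∝ 1/P of reaction-limited growth, the
  crossover size i_cross = (P·N11)^{−1/2σ} to diffusion-limited aggregation,
  and the DLCA growth law s ∝ t^{1/(1+2γH)}.
* **`latcondense.homogeneous_bonds`** — closed-form kinetics of the bond
  density per LAT before separation, dϕ/ds = (v/2−ϕ)² − K_Dϕ: the Riccati
  solution ϕ(s), the threshold condition K_D ≤ (v/2−ϕ_th)²/ϕ_th, and the
  threshold-crossing time τ_th.
* **`latcondense.field_dynamics`** — a pseudospectral solver for the coupled
  conserved density / bond reaction–diffusion system
  ∂δL/∂t = ∇·(D̃∇μ), ∂(ϕL)/∂t = −∇·(ϕj_L) + k̂₁(v/2−ϕ)²L² − k̂₋₁ϕL,
  with a free energy that switches from single- to double-well as ϕ crosses
  ϕ_th and a mobility that drops inside condensates (which freezes the
  patterns).
* **`latcondense.morphology`** — classification of density fields into
  {homogeneous, bicontinuous, rich/depleted × circular/noncircular} with
  fully periodic component analysis, plus (β̂₃, β̂₄) phase-diagram scans.

## Worked example

```python
import numpy as np
from latcondense.aggregation import KernelParams, simulate_aggregation, dimer_peak_time
from latcondense.homogeneous_bonds import BindingParams, dissociation_constant, threshold_time
from latcondense import presets
from latcondense.field_dynamics import run_simulation
from latcondense.morphology import classify

# 1. lag time of reaction-limited aggregation at binding probability P = 1%
p = KernelParams()                      # reference parameters, P = 1e-2
print(f"t_char2 = {dimer_peak_time(p):.1f}")
traj = simulate_aggregation(p, t_star_max=1e6)
print(f"stopped at t* = {traj.times[-1]:.0f}, mean size {traj.mean_sizes[-1]:.1f}, "
      f"mass retained {traj.mass_retained[-1]:.2f}")

# 2. when does the bond density reach the phase-separation threshold?
b = BindingParams()                     # reference rates, L0 = 3, v = 3
print(f"K_D = {dissociation_constant(b):.4f}, tau_th = {threshold_time(b):.0f}")

# 3. spatially resolved run (desk scale: compressed reaction clock)
pf = presets.desk_field_params()        # beta3 = -1.31, beta4 = -1.98
snaps, summary = run_simulation(pf, presets.desk_grid(128), presets.desk_solver(seed=11))
print(f"final var(L) = {summary.var_L.iloc[-1]:.3f}, label = {classify(snaps[-1].L, pf)}")
```

prints

```
t_char2 = 65.9
stopped at t* = 4608, mean size 143.8, mass retained 0.95
K_D = 0.0333, tau_th = 14087
final var(L) = 0.352, label = rich_noncircular
```

t_char2 ≈ 66 is the dimer-formation lag (in the model's non-dimensional
time): below it the mean cluster size stays ≈ 1; the run then grows to
clusters of ~10² before 5% of the mass passes the bookkeeping cutoff.
τ_th ≈ 1.4·10⁴ is when the average bond count per LAT reaches the
phase-separation threshold at the reference rates.  The field run separates
into elongated LAT-rich inclusions in a LAT-depleted background — the
classifier label `rich_noncircular`.

A command-line interface wraps the same functionality:

```sh
latcondense aggregate --config params.yml --out traj.csv
latcondense homogeneous --sweep KD
latcondense field --config run.yml --out run.h5 --seed 11
latcondense classify --h5 run.h5
latcondense phasediagram --config scan.yml --out diagram.csv
latcondense fixtures --out fixtures.h5
```

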