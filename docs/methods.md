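# Methods

`latcondense` implements two complementary models of LAT (Linker for
Activation of T cells) condensate formation on supported lipid bilayers: a
Smoluchowski coagulation model for the early, cluster-scale kinetics, and a
conserved phase-field model coupled to bond reaction–diffusion kinetics for
the spatially resolved condensate morphologies.  This note records the models,
their assumptions, the numerical choices, and what the desk-scale test
conditions do and do not probe.

## Aggregation model

The cluster-size distribution c_i(t) on the membrane obeys irreversible
two-body coagulation,

    dc_i/dt = 1/2 Σ_{j<i} k_{i−j,j} c_{i−j} c_j − c_i Σ_j k_ij c_j ,

starting from monomers only.  Fragmentation is deliberately absent: at early
times clusters other than monomers are rare, and at late times the bulk
bonding energy of a multivalent cluster dominates its interfacial energy, so
fragmentation is not expected to change the qualitative picture.

The kernel is a product of an encounter rate and a sticking probability,
k_ij = k_Br(i,j) · k_rxn(i,j):

* **Encounter (Brownian) part.**  k_Br ∝ D_i + D_j with Evans–Sackmann
  diffusivities for membrane inclusions over a substrate,
  D_i = kBT / (4π η_m f(ε_i)), f(ε) = ε²/4 + ε K1(ε)/K0(ε),
  ε_i = R_H(i) √(b_s/η_m), and a fractal mass–radius relation
  R_H(i) = R0 · i^γH.  Drag is logarithmic (membrane-viscosity dominated)
  for small ε and ∝ ε² (substrate-friction dominated) for large ε, so
  D_i ∝ i^(−2γH) for large clusters.  The Bessel ratio is evaluated with
  exponentially scaled K0/K1, which is accurate and overflow-free at every
  ε, removing the need for an asymptotic switch.
* **Sticking (reactive) part.**  k_rxn = P·N_ij / (P·N_ij + 1 − P) with
  N_ij = N11 (i·j)^σ collisions per encounter.  Small P·N_ij gives
  reaction-limited aggregation (RLCA, k_rxn ≈ P·N_ij); large clusters reach
  the diffusion-limited regime (DLCA, k_rxn → 1).  The crossover size is
  i_cross = (P·N11)^(−1/2σ), at which k_rxn = 1/(2−P) exactly.

All rates are expressed in the non-dimensional time t* that absorbs the
encounter-rate prefactor, kBT/(4π η_m), and the initial monomer density; in
these units k_Br(i,j) = 1/f(ε_i) + 1/f(ε_j) and c_1(0) = 1.

Reference parameters: P = 10⁻² (varied), N11 = 1, σ = 1,
η_m = 0.1 pN·µs/nm, b_s = 10⁻² pN·µs/nm³, γH = 2/3.  The monomer radius is
not fixed by those values; we use R0 = 2 nm (the scale of a small protein's
gyration radius), which puts ε_1 ≈ 0.63 so that the drag crossover happens
within reachable cluster sizes.

**Diagnostics.**  The mean cluster size is number-weighted,
s = Σ i c_i / Σ c_j.  The lag time is the dimer-peak time of the reduced
monomer–dimer system: with μ = k_12/k_11 (evaluated from the full composite
kernel),

    t_char2 = (μ^{1/(μ−1)} − 1) / (c̄₁ k_11),    (μ → 1: (e−1)/(c̄₁ k_11))

which scales as 1/P for P ≪ 1 since μ is then P-independent and k_11 ∝ P.
Rescaling time by t_char2 collapses s-curves across P at early times.  The
closed form is tested against a numerical argmax of the reduced system; note
that in the *full* hierarchy the dimer peak sits roughly a factor two earlier
(≈0.54·t_char2 at σ = 1), because dimers are also consumed by collisions
with i ≥ 2 clusters, which the reduction neglects.  t_char2 is therefore a
scaling variable, not a precise peak location — the 1/P law and the collapse
are what carry over.  For P = 1 the late-time growth follows
s ∝ t^{1/(1+2γH)} (= t^{3/7} at γH = 2/3); the measured local slope
approaches this from above once s ≫ i where drag is friction-dominated
(s ≳ 100 for the reference geometry).

**Numerics.**  Dense kernel matrix to Nmax (default 400; the slope and
crossover diagnostics use 1000 where the slow regime must be reached before
the truncation stop), gain term via an anti-diagonal bincount, adaptive
RK45 with rtol 10⁻⁸ / atol 10⁻¹², termination when 5% of the mass has
leaked past Nmax.  The RHS evaluates on max(c, 0) so round-off-level
negative excursions relax back to zero instead of feeding back through the
quadratic loss; concentrations more negative than the absolute tolerance
abort the run.

## Homogeneous bond kinetics

Before phase separation the LAT density is uniform (L = L0) and the bond
density per LAT, ϕ ∈ [0, v/2], obeys the Riccati equation

    dϕ/ds = (v/2 − ϕ)² − K_D ϕ ,   s = k̂₁ L0 t ,   K_D = k̂₋₁/(k̂₁ L0),

with valency v.  Closed forms implemented and oracle-tested (direct ODE
integration, root finding):

* ϕ(s) = λ₁λ₂ (e^{λ₁s} − e^{λ₂s}) / (λ₁ e^{λ₂s} − λ₂ e^{λ₁s}),
  λ₁,₂ = −(v+K_D)/2 ± √(2vK_D + K_D²)/2; ϕ(∞) = −λ₁.  Evaluated after
  normalizing by e^{λ₁s} so large times cannot overflow.  K_D = 0 uses the
  Bernoulli limit ϕ = (v/2)(vs/2)/(1 + vs/2).
* The threshold ϕ_th (default 1) is reachable iff K_D ≤ (v/2 − ϕ_th)²/ϕ_th.
* Crossing time τ_th = ln[(ϕ_th λ₁ + λ₁λ₂)/(ϕ_th λ₂ + λ₁λ₂)] /
  (k̂₁ L0 (λ₁ − λ₂)); it approaches a constant × 1/(k̂₁L0) as K_D → 0 and
  diverges logarithmically as K_D approaches its bound.  Lowering the
  valency from 4 toward 2ϕ_th at fixed K_D raises τ_th severalfold, the
  kinetic signature of incomplete LAT phosphorylation.

Reference rates k̂₁ = (1/3)·10⁻⁴, k̂₋₁ = (1/3)·10⁻⁵, L0 = 3 give
K_D = 1/30 and τ_th ≈ 1.4·10⁴ non-dimensional time units.

## Phase-field model

Non-dimensional fields on a periodic square: the LAT density deviation
δL = L − L̄ (L̄ = 3) and the bond field B = ϕL.

    μ    = −(ϕ−ϕ_th) δL + β̂₃(ϕ−ϕ_th) δL² + (1 + β̂₄(ϕ−ϕ_th)) δL³ − ∇²δL
    ∂δL/∂t = ∇·(D̃ ∇μ)
    ∂(ϕL)/∂t = −∇·(ϕ j_L) + k̂₁ (v/2 − ϕ)² L² − k̂₋₁ ϕ L,   j_L = −D̃∇μ

The bulk free energy has a single well for ϕ ≤ ϕ_th and a double well above
it; (β̂₃, β̂₄) are admissible iff

    −1/(v/2 − ϕ_th) < β̂₄ < 1/ϕ_th   and   β̂₃² < 4(1 − β̂₄ ϕ_th)/ϕ_th .

Both conditions are re-derived from the discriminant of ∂f/∂δL (the quartic
coefficient must stay positive over ϕ ∈ [0, v/2]; the cubic skew must not
open a second well below threshold) and are verified in the tests by
brute-force one-dimensional minimization of f.  Note the second condition
carries a single power of ϕ_th; at the reference ϕ_th = 1 this is
indistinguishable from a ϕ_th² variant, and every parameter set used here
has ϕ_th = 1.

The mobility D̃ = 1 − ((1−r)/4)(1 + tanh(ω(L−L̄)/L̄))(1 + tanh(ω(ϕ−ϕ_th)/ϕ_th))
interpolates from 1 (dilute, weakly bonded) to r = 0.05 (dense condensate,
ω = 20), which is what arrests the patterns soon after they form.

Initial conditions: L = L0(1 + ε(x)) with ε uniform, mean-subtracted,
amplitude 10⁻³ (seeded), and B = 0.

**Time stepping.**  Pseudospectral (FFT) space discretization with an
isotropic 2/3-rule dealiasing mask; the isotropic truncation also discards
the anisotropic corner modes, whose k⁴ stiffness otherwise dictates the
step.  Time integration is 2nd-order Crank–Nicolson/Adams–Bashforth: the
constant-coefficient operator −∇⁴δL + ϕ_th ∇²δL is treated with CN in
Fourier space, everything else (variable mobility, nonlinear potential,
bond advection, reactions) with AB2, bootstrapped by one Euler step.  The
ϕ_th ∇² shift is a standard stabilization: it bounds the explicitly treated
plain-diffusion part −(ϕ_th − ϕ)∇²δL of the pre-separation dynamics, which
AB2 alone cannot take at the default step.  ϕ is clamped to [0, v/2] after
each step (AB2 can overshoot the attracting bounds; discarded bond mass is
tallied).  δL's domain mean is conserved exactly (the k = 0 mode has no
dynamics), and dt-halving confirms 2nd-order convergence.

Defaults: grid 256² on a box of 100 (spacing 0.5 resolves the unit
interfacial width), dt = 5·10⁻³, T_sim = 6·10⁴.

**A note on how separation starts.**  During the homogeneous prelude
(ϕ < ϕ_th) density fluctuations decay diffusively, so by the time ϕ crosses
ϕ_th the seeded noise has been damped to the round-off floor; the spinodal
then re-amplifies fluctuations continuously re-seeded at the 10⁻¹⁶ level by
FFT round-off.  The growth rate is bounded by (ϕ∞ − ϕ_th)²/4 (≈ 0.0225 at
the reference K_D), so visible separation follows threshold crossing by
roughly 2·10³ time units — a reaction-independent delay that dictates the
desk-scale run lengths below.

## Desk-scale test conditions

The tests and the acceptance script compress the reaction clock: k̂₁ and
k̂₋₁ are both multiplied by 100, which leaves K_D, the Riccati trajectory in
s = k̂₁L0·t, every steady state, and the admissibility region unchanged,
while shortening the homogeneous prelude from τ_th ≈ 1.4·10⁴ to ≈ 1.4·10².
The compression keeps the reaction rate k̂₁L0 (= 10⁻²) below the maximum
spinodal growth rate, preserving the reactions-slower-than-transport
ordering of the model.  Runs then use T_sim = 3000 with dt = 0.05 for
single trajectories (grid 128² on a box of 64) and T_sim = 2800 with a
fine-phase dt = 0.03 for the (β̂₃, β̂₄) scans (64² on 32; the deepest-well
corners of the admissible region need the smaller step), with 40² on 20
and dt = 0.05 for the doubled-unbinding comparisons (which only ask
whether separation occurs, not for inclusion shapes).  All runs take a
coarser dt = 0.2 during the homogeneous prelude, where the dynamics are
linear-diffusive at near-unit mobility; the switch to the fine step
watches the variance carried by the spinodal band (0.15 < |k| < 0.8),
arms once it has decayed below 10⁻⁴ (amplitude ~1% of the mean density,
still linear) and fires when the regrowth carries it back above.

What the desk scale does *not* probe: quantitative pattern length scales
(grid and box are far below experimental scales), the very slow late-time
coarsening of the reference conditions, and morphology exactly at phase
boundaries.  In particular, small boxes bias late-time shapes: at a box of
24–48 the few surviving LAT-rich inclusions eventually round up under line
tension, whereas at a box of 64 and above the elongated morphology of the
example trajectory persists.  Morphology assertions therefore run at the
largest affordable box, and the phase-diagram scans are read for phase
identity (rich/depleted/interlaced) rather than inclusion shape.

## Morphology classification

Fields are classified on the final snapshot: Otsu binarization after a
bimodality gate (Otsu class means must differ by > 0.2·reference density);
connected components with full periodic (torus) adjacency, merged across
the seams by union–find; percolation detected by winding (a BFS lift into
the universal cover that returns to a pixel with a shifted coordinate);
perimeters by a four-direction Cauchy–Crofton count evaluated with periodic
rolls (no special-casing of wrapped or spanning components); circularity
4πA/P².  Labels: homogeneous (no bimodality), bicontinuous (both phases own
a spanning component), else the minority phase names the label with
circular/noncircular split at an area-weighted median circularity of 0.75
(components under 10 cells ignored).  All thresholds are package decisions,
fixed once against the six synthetic fixture classes (uniform, disks,
inverted disks, 4:1 bars rich and depleted, stripes) and the example
trajectory's outcome; they are keyword-configurable.

## Known limitations

* The aggregation model has no fragmentation and no spatial resolution, and
  t_char2 is a factor ≈ 2 above the true full-hierarchy dimer peak (see
  above); only its scaling is load-bearing.
* The phase-field stepper is stable but only first-order accurate in its
  splitting error at strong mobility contrast near r ≪ 1; r < 0.01 warns.
* Classification near phase boundaries is sensitive to the circularity cut
  and the domain size; reproduced phase diagrams should be read in topology
  and trend, not point by point.
* The desk-scale rate compression shifts where in time separation happens
  relative to the reaction clock; it does not change which morphologies are
  reachable, but boundary positions in (β̂₃, β̂₄) can move slightly.
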