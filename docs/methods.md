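# Methods

`capsim` simulates the self-assembly of a protective polymer shell around an
enzyme-mimicking nanosphere by free-radical polymerization, using dissipative
particle dynamics (DPD) coupled to a stochastic reaction model, and measures
the structural observables that characterize the resulting nanocapsule.

## Model

### DPD engine

All interactions act between soft beads of unit mass in reduced units
(length r_c ≅ 1 nm, energy k_BT = 1, time τ). Nonbonded pairs within the
cutoff r_c feel the standard three DPD forces:

* conservative soft repulsion `F^C = a_ij (1 − r/r_c) r̂`,
* dissipative drag `F^D = −γ w(r)² (r̂·v_ij) r̂`,
* random kicks `F^R = σ w(r) ζ Δt^(−1/2) r̂`, ζ a standard normal deviate,

with `w(r) = 1 − r/r_c` and the fluctuation–dissipation constraint
`σ² = 2 γ k_BT`. Defaults are the canonical parameterization at bead density
ρ = 3: `a_ii = 25`, `γ = 4.5`, `σ = 3.0`, giving k_BT = 1. Integration uses
the modified velocity-Verlet scheme with coupling λ = 0.65 and Δt = 0.04 τ;
under these settings the measured kinetic temperature stays within a few
tenths of a percent of 1.

Bonds are harmonic, `E = ½ k_b (r − r_0)²` with `k_b = 100`, `r_0 = 0.7 r_c`
(bonds stay well below the cutoff). Chain rigidity enters through a bending
term `E = k_angle (1 + cos θ)` on consecutive bond triples, which is minimal
for straight chains; `k_angle = 0` is a fully flexible chain and
`k_angle = 16` semi-rigid. Angle forces are the exact analytic gradient of
the cosine form, so collinear geometries are regular.

The random force uses a counter-based generator: the deviate for pair (i, j)
at step s is a hash of (seed, s, i, j), mapped through the AS241 inverse
normal approximation. Noise therefore does not depend on the order in which
pairs are visited — cell-list and all-pairs evaluation give identical
forces, and runs are bit-reproducible for a fixed seed.

### Composition

The reaction mixture contains (species in parentheses):

* a rigid nanosphere of frozen beads (O; alias N for additional spheres)
  built from filled concentric Fibonacci layers at 0.5 r_c spacing; frozen
  beads exert forces but do not move,
* monomers as A–B dimers: an adsorbable bead A whose affinity for the
  sphere is set by the repulsion parameter α_OA, and a polymerizable bead B
  whose hydrophobicity is set by α_WB,
* crosslinkers as C–C dimers; each C supports two network bonds,
* single-bead initiators I,
* hydrophilic CE₁₀ chains: ten E beads (PEG-like) capped by one
  polymerizable C bead,
* solvent W filling the box to ρ = 3.

The reference stoichiometry is n(M):n(C):n(I) = 75:14:1. The full-scale
system holds 1500 monomers (280 crosslinkers, 20 initiators) around a
sphere of radius 5 r_c; CE₁₀ content corresponds to 0.00519 mol L⁻¹ at
r_c = 1 nm. Unspecified interaction pairs default to a_ij = 25; only α_OA
(sphere–A, default 6.0: strong affinity, χ ≈ −5.8) and α_WB (solvent–B,
default 28.0: the low end of the hydrophobic window, where regular
capsules form) deviate. A hydrophobic B is essential: it drives the
polymerized chains to pack against the core instead of staying
solvent-swollen.

### Reaction model

Initiator beads become radical carriers at t = 0 (activation probability 1
by default). Every `attempt_interval` steps, each radical (visited in
random order) locates the nearest eligible polymerizable bead within the
reaction radius — an unreacted B, or a C with spare valence, excluding
beads within two bonds of the radical — and bonds to it with probability
P_r, transferring the radical to the acceptor. Valences: B ≤ 2, C ≤ 2,
I ≤ 1. Termination (radical–radical combination) is disabled by default,
so the radical count is conserved. When `k_angle > 0`, bending terms are
added along the growing backbone (triples whose middle bead joins two
backbone bonds) and along E-chains.

### Unit bridges

Two scalar bridges connect simulation parameters to laboratory chemistry:

* Flory–Huggins: `χ = 0.306 (a_ij − a_ii)` at ρ = 3; the adsorption window
  α_OA ∈ [3, 10) maps to χ_OA ∈ (−6.73, −4.59].
* Arrhenius: `P_r = A exp(−E_a/(k_B T))` with the literature prefactor
  A = 2.2 × 10⁵. Using the molar gas constant and T = 298 K (the
  temperature is a config knob; room temperature is assumed),
  P_r = 0.005 corresponds to E_a ≈ 43.6 kJ mol⁻¹, in the range typical of
  vinyl monomer polymerization.

## Observables

* **κ² (relative shape anisotropy)** — from the gyration tensor of the
  unwrapped shell network (E beads excluded by default, toggleable):
  κ² = 1 − 3(λ₁λ₂ + λ₂λ₃ + λ₃λ₁)/(λ₁+λ₂+λ₃)²; 0 for spherical symmetry, 1
  for a line. Coordinates are unwrapped by minimum image about the sphere
  center followed by a breadth-first walk over bonds.
* **SASA** — Shrake–Rupley quadrature on the probe-inflated core surface
  (probe 0.1 r_c = 0.1 nm, occluder radius 0.5 r_c, 2000 points by
  default); occluders are all non-solvent, non-core beads.
* **ρ_ads** — number density of non-solvent, non-core beads in the
  adsorption shell (R, R + 1 r_c] around the sphere.
* **N_shell / shell membership** — connected components of the molecular
  bond graph (builder + polymerization bonds) restricted to non-solvent,
  non-core beads; a component belongs to the shell when any bead lies
  within 1 r_c of the sphere surface. Detached micelles contribute
  nothing.
* **Shell thickness** — outermost radius at which the polymerized-bead
  density still reaches half its peak, minus the sphere radius.
* **Persistence length** — from the bond-orientation correlation
  ⟨cos θ(s)⟩ = exp(−s l_b/l_p), fitted log-linearly with zero intercept
  (the law is exactly 1 at s = 0) over the s-range with correlation >
  0.05 and ≥ 30 samples, weighted by n⟨cos⟩² (the delta-method inverse
  variance). Rigid rods return an infinite upper-bound sentinel;
  uncorrelated chains a lower-bound flag.
* **η_react** — fraction of reactive molecules (monomers, crosslinkers,
  CE₁₀ chains) with at least one bead in any sphere's shell network.
* **Encapsulation census** — spheres whose shell components intersect are
  merged (union–find); reported as capsule size classes and the
  mono-encapsulation fraction.
* **Morphology regimes** — I (fully encapsulated) when κ² ≤ 0.004 and core
  exposure (SASA/bare-core SASA) ≤ 0.2; III (partially exposed) when
  exposure > 0.2 regardless of shape; II (distorted) otherwise. The κ²
  threshold is the published critical value; the exposure threshold is a
  package calibration choice.

## Synthetic fixtures

The builder also generates the analytic structures the estimators are
validated against: uniform bead gases, spherical shells, rods, and
worm-like chains built by the cone construction (each bond at fixed angle
arccos(c) from its predecessor with uniform azimuth), which gives
⟨cos θ(1)⟩ = c exactly and ground truth l_p = −l_b/ln c. These fixtures
emulate the statistical geometry of the observables' inputs, not the
dynamics of real mixtures: passing estimator tests shows the measurement
machinery is correct, not that the simulated chemistry matches any
specific laboratory system.

## Scaled (desk) protocol

The published conditions (1500 monomers, ≥ 10⁵ τ trajectories) are beyond
a single-CPU test budget, so the test suite exercises a proportionally
reduced preset: 150 monomers (28 crosslinkers, 2 initiators, 10 CE₁₀
chains) in a 15³ box around a radius-3 sphere — same ratios, same
probabilities, ~10 000 beads. Scaled runs use a few hundred relaxation
steps (force-capped), ~1200 equilibration steps and a few thousand
reaction steps, with end-point metrics averaged over a handful of
snapshots 2 τ apart, standing in for the published practice of averaging
stabilized configurations over five independent replicates.

Because the desk system carries only two radicals, the reaction engine's
protocol knobs are calibrated once for this preset: a reaction sweep
follows every step (`attempt_interval = 1`) and the capture radius is
2.0 r_c, so that measurable conversion (~20 bonds) accumulates inside
the shortened window. P_r itself — the quantity with physical
meaning through the Arrhenius bridge — is never rescaled. Replicate
comparisons across parameter values share build/equilibration seeds
(common random numbers), which pairs the branches and sharpens trend
comparisons without biasing either side.

Shell growth rates at desk scale are measured as the least-squares slope
of N_shell over the whole reaction window: that window (~90 τ) lies
entirely inside the early-growth regime of the full-scale process, which
matures only after ~10⁵ τ. Three-point parameter sweeps are summarized by
the signed slope of the cell means plus the strict ordering of the
endpoint means; demanding strict ordering of the middle cell would test
sampling noise rather than the trend.

What the desk runs do and do not show: monomer adsorption, shell
nucleation, oligomer growth, micellar competition and the α_OA/P_r trend
directions are reproduced; full conversion, multilayer shell packing and
the absolute published values (e.g. κ² = 0.004 at α_OA = 10) are not
reachable at this scale and are retained only as full-scale targets.

## Numerical choices

* Cell-list neighbor search at cutoff-sized cells with a half stencil;
  boxes too small for three cells per axis fall back to an all-pairs
  loop. Both paths produce identical forces (same hashed noise).
* Coincident beads (r = 0) receive the full conservative force along a
  deterministic fallback axis and raise a warning.
* A step displacing any bead by more than r_c aborts with an instability
  error; freshly built systems are first relaxed with forces capped at 30
  (in reduced units) to remove insertion artifacts.
* Coordinates are wrapped to [0, L); all pair vectors use minimum image;
  a bond whose minimum-image length exceeds half the box raises a
  topology error.
* Stoichiometry resolution uses exact rational arithmetic and rejects
  non-integer implied counts rather than rounding.
* Reaction candidate selection breaks distance ties by lower bead index,
  making sweeps deterministic given geometry and RNG state.

## Limitations

* No electrostatics, many-body DPD, or pressure coupling; the sphere is a
  rigid homogeneous bead cluster, not an atomistic protein surface.
* The reaction model tracks neither kinetic chain-length distributions
  nor explicit termination chemistry (termination is available but off by
  default).
* Desk-scale conversions are low (tens of bonds), so observables that
  hinge on dense, mature shells — shell thickness, packing-limited
  rigidity effects, η_react saturation — carry large relative noise at
  this scale.
* The Arrhenius bridge reports energies for an assumed 298 K; the
  simulation itself is athermal in real units (k_BT = 1).
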