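# Methods

This note documents the model, the sampling machinery, the numerical
choices, and what the scaled-down tests do and do not demonstrate.

## Reduced units

Length is measured in ion diameters σ = 0.355 nm, energy in k_BT
(T = 298.15 K for every SI conversion; "room temperature" fixed once),
mass m = 1 (arbitrary: it does not enter any thermodynamic average), and
time in τ = σ√(m/k_BT). Concentrations are referred to c⦵ = 1 mol/L,
which equals 0.602 nm⁻³ = 0.0269 σ⁻³. All conversions round-trip to
≤10⁻¹² relative.

## Interactions

**λ-WCA pair potential.** The Lennard-Jones curve is split at its minimum
r_m = 2^{1/6}σ_ij:

- core (r < r_m): 4ε[(σ/r)¹² − (σ/r)⁶] + (1 − λ)ε
- tail (r_m ≤ r < r_c): λ·4ε[(σ/r)¹² − (σ/r)⁶]

then truncated and shifted so the potential is exactly zero at and beyond
the cutoff. λ = 0 is the purely repulsive athermal limit; λ = 1 the full
LJ well. λ maps to a second virial coefficient B₂ by adaptive quadrature
of −2π∫(e^{−βU} − 1)r²dr (the λ = 0 value lies within ~5% of the
hard-sphere 2πσ³/3). Pair parameters combine by Lorentz–Berthelot
(arithmetic σ, geometric λ). Pairs involving a monomer use
r_c = 2.5σ_ij (1.065 nm for monomer–monomer); athermal ion–ion pairs use
r_c = 2^{1/6}σ_ij, which is the identical potential at lower cost.

**Bonds.** Harmonic, U = ½K(r − R₀)², K = 827 k_BT/nm², R₀ = 0.426 nm.
Bonded neighbors *also* interact through the nonbonded WCA term (a flag
disables this). The choice is observable in the bond statistics: with the
WCA term the neutral 32-mer equilibrates to ⟨b⟩ = 0.457 nm with spread
0.024 nm; without it, 0.433 nm with spread 0.035 nm (both verified
against an isolated-dimer quadrature oracle). The included-WCA default
reproduces the reference spread and keeps its mean within one spread of
the reference mean; in the dense complex, electrostatic cohesion pulls
the mean further down.

**Electrostatics.** U = z₁z₂ l_B/r with the phase's Bjerrum length:
l_B = e²/(4πε₀ε_r k_BT) = 0.90 nm at ε_r = 62 (complex) and 0.71 nm at
ε_r = 78 (supernatant). Periodic sums use classic Ewald summation with
conducting (tinfoil) boundary. Parameters are auto-tuned: real-space
cutoff r_c = min(0.45L, 5σ), splitting parameter from
erfc(αr_c) = δ/10, reciprocal cutoff from e^{−k²/4α²} = δ/10, with target
relative accuracy δ = 10⁻³ by default; the tuning is validated against an
over-converged reference on a two-charge probe, and against explicit
image summation and the rocksalt Madelung constant in the tests. The two
phases use different l_B but share one reaction-constant set; the
solvation (Born) contribution of transferring an ion between media of
different permittivity is deliberately neglected, and
`born_transfer_factor` exposes the continuum estimate
exp[z²(l_B^pec − l_B^sup)/2r₀] ≈ 1.7 per unit charge for post-hoc error
assessment only.

## Dynamics

Langevin dynamics at k_BT = 1 via the BAOAB splitting with δt = 0.01τ and
γ = 1/τ by default. BAOAB was chosen for its high configurational
accuracy at this step size; at γ = 0 with the noise off it reduces
exactly to velocity Verlet, which the integrator-order test exploits
(energy-fluctuation scaling ∝ δt²). Inserted particles receive
Maxwell–Boltzmann velocities. Forces are evaluated by all-pairs
minimum-image loops in compiled (numba) kernels: at the problem sizes
this package targets (N up to a few hundred) all-pairs evaluation is
faster than any neighbor-list bookkeeping, and it is cross-checked
against an independent pure-numpy evaluation in the tests.

## Grand-reaction Monte Carlo

Composition fluctuations are sampled by reaction moves. The reaction set
for a reservoir of pH, c_salt (+ optional divalent salt and diprotic
solute) contains neutral grand-canonical insertions (NaCl, H₂O
autoionization products, NaOH, HCl, MCl₂), in-box acid dissociations
(pK_A,1 = 4.2, pK_A,2 = 5.6), and solute-exchange insertions of each acid
form with neutralizing Na⁺. Equilibrium constants are products of the
*ideal* target concentrations in units of c⦵; this parameterization makes
the electroneutrality constraint (only two of K_NaCl, K_NaOH, K_HCl are
independent given K_w: K_NaOH·K_HCl = K_NaCl·K_w) and every thermodynamic
cycle close identically, which the tests assert. Because the boxes
interact, measured compositions shift away from the ideal targets
(Debye–Hückel activity lowering pushes the measured salt concentration
*above* the target); `calibrate_reservoir` runs the auxiliary supernatant
simulation that measures the realized composition, so reported
concentrations are generally not round numbers. pH is reported on the
concentration scale, −log₁₀(c_H⁺/1 M), matching the reaction-ensemble
bookkeeping.

A trial move picks one reaction and a direction uniformly, pairs leading
consumed/produced species (sorted by size) as in-place identity changes,
deletes surplus consumed particles uniformly at random, inserts surplus
produced particles at uniform positions, and accepts with

min[1, K^ξ · Π_i N_i⁰!/(N_i⁰+ξν_i)! · (Vc⦵)^{ξν̄} · e^{−βΔU}]

evaluated in log space (log-Γ functions). Every stoichiometry is
electroneutral, so the box charge is conserved *exactly* at every step.
Detailed balance of the acceptance law is unit-tested on enumerated
microstates. ΔU is assembled incrementally — direct subset sums for the
short-range and screened-Coulomb terms, cached charge-structure-amplitude
updates for the reciprocal Ewald term, the analytic self term — and this
bookkeeping is cross-checked against full energy recomputation to ~10⁻¹³
relative in the tests. Polymer monomers are non-exchangeable; a reaction
referencing them is rejected at validation time.

Default cadence at production scale: 5×10² reaction attempts every 10⁴
dynamics steps; both are configurable and the scaled-down tests use
denser cadences on smaller boxes.

## Complex-phase construction

Chains initialize as fully extended rods on a cubic lattice (species
alternating in a checkerboard, counts rebalanced for odd grids), with a
short thermalization. The box then iteratively shrinks by ΔL = 0.7σ with
an affine coordinate rescale and a relaxation run between steps
(10⁵ steps at production scale; configurable) until the monomer volume
fraction φ = Σ(π/6)d³/V reaches its target; the final partial step lands
φ exactly. Note the φ ↔ L arithmetic: 2048 monomers of diameter 1.2σ at
φ = 0.15 give L = 23.1σ.

## Pressure and coexistence

The virial pressure is P = [N k_BT + ⅓(W_pair + W_bond) + ⅓U_elec]/V.
The electrostatic term uses homogeneity: the full periodic Coulomb energy
scales as 1/L under an affine dilation (with α ∝ 1/L, r_c ∝ L, k-vectors
∝ 1/L), so −V∂U/∂V = U/3 exactly. The estimator is validated against a
central-difference volume-perturbation oracle (≤10⁻³) and the
B₂-truncated virial series of the dilute athermal fluid.

`fit_dp_curve` fits ΔP(φ) = a₀ + a₁/tan(φ − a₂) by weighted nonlinear
least squares (inverse-variance weights when errors are supplied — the
weighting convention is a package choice; sensitivity to uniform weights
is small on the tested curves since the fitted branch has near-uniform
errors). Points enter the fit when ΔP > −2·stderr, excluding the
demixing-prone negative branch. Initial parameters come from a grid scan
of a₂ outside the data range with linear solves for (a₀, a₁). The root φ⁰
is located by bracketed bisection over the hull of *all* supplied φ
values (the root generically sits just below the lowest fitted point once
the negative branch is excluded; no extrapolation beyond the data), and
its uncertainty by parametric resampling from the fit covariance. Runs
with no sign change return a no-coexistence result (valid = False), as do
fits whose nearest data point to φ⁰ carries the demixing flag.

Demixing is flagged when the smallest-k shell of the spherically averaged
structure factor S(k) = ⟨|Σe^{ik·r}|²⟩/N is the strict global maximum of
the curve; shells have width 2π/L starting at the smallest box mode. The
gravimetric partition estimator for bench experiments,
K = (m_sup(1 − ĉ) + m_pec)/(ĉ·m_pec) with ĉ the control-normalized
supernatant concentration, assumes the hydrated complex has the density
of water (documented default of the mass-balance inversion).

## Titration analysis

Ideal diprotic speciation is closed-form mass action; the
potential-augmented ionization law α = 1/(1 + 10^{pK−pH}e^{zψ}) uses ψ in
k_BT/e so a potential of ±ln10 shifts the curve by exactly one pH unit.
Apparent-pK shifts are horizontal offsets minimizing the squared
deviation between measured and ideal *state-fraction* curves (state
populations, not α, because that is what the per-state observables
report). The Debye–Hückel prediction uses the extended form
ln γ_z = −z²l_Bκ/[2(1 + κσ)], giving a deprotonation-step shift
ΔpK = −2|z|·l_Bκ/[2(1+κσ)]/ln10 — negative (toward lower pH) and linear
in the valency of the state being formed; only the limiting behavior and
signs are asserted. Errors on simulated fractions use block averaging
(5 blocks) to respect MC/MD autocorrelation.

## Scaled-down study conditions

The production-scale conditions are 32+32 chains of 32 beads at
φ ≈ 10–15%, 10⁷ dynamics steps with 5×10⁵ reaction attempts per phase.
The test suite and worked examples run the same pipeline at 4+4 chains of
8 beads (φ = 0.12, box ≈ 7.8σ) with ~2×10⁴ dynamics steps and ~2×10⁴
reaction attempts per phase, sizes chosen so the whole suite completes on
one CPU in minutes. At this scale the *signs and trends* of the
partitioning physics are reproducible — monovalent K ≲ 1 and decreasing
with salt, divalent K > 1, total-acid K increasing with pH — but the
quantitative plateaus (divalent K ≈ 6–9, total-acid K ≈ 5, the 0.3-pH
divalent-population shift) and the full phase diagram require
production-length runs; the tests assert only the trends.

## What the synthetic data do and do not emulate

Generated fixtures (lattice chains, ideal reservoirs, ΔP tables drawn
from a known (a₀,a₁,a₂) with seeded Gaussian noise, constructed S(k)
curves) exercise every code path with known answers. They do not emulate
chemical specificity (ion-specific, Hofmeister-type effects), explicit
solvent or solvation free energies, polymer charge regulation (polymer
charges are fixed, appropriate near full ionization), asymmetric mixing
ratios (zero Donnan potential is assumed, which also makes the two
phases share one pH), or the critical region (the no-polymer-in-
supernatant assumption fails there). Passing tests therefore validate
the machinery and the generic electrostatics/sterics balance, not any
system-specific prediction.

## Known limitations

- Single-reservoir insertion moves become inefficient for bulky solutes
  in dense phases (no cavity biasing or continuous-fractional coupling).
- No barostat: coexistence is found by pressure matching across
  fixed-volume runs, which is the method's design, but interpolating in φ
  assumes the scan brackets φ⁰.
- The per-phase permittivities are inputs, not predictions; partition
  coefficients are sensitive to them.
- Desk-scale boxes under-resolve dilute species (e.g. H⁺/OH⁻ counts at
  near-neutral pH are ≪ 1 per box), so pH must be imposed through the
  reservoir constants rather than measured in-box at that scale.
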