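# pecsim

Coarse-grained simulation of polyelectrolyte complexes (PECs) in
coexistence with their supernatant, with pH- and salt-controlled chemistry.

When oppositely charged polyelectrolytes are mixed, the solution can
demix into a dense polymer-rich complex (a coacervate, when liquid) and a
dilute, essentially polymer-free supernatant. How small ions, multivalent
ions, and weak acids *partition* between these phases — and how that
partitioning responds to pH — matters for drug delivery, water
purification, and the physics of membraneless organelles. `pecsim` is a
research tool for computing these partition coefficients and the
underlying phase coexistence from a minimal bead-spring model.

## The model and method

* **Particles.** Polyanion/polycation beads (diameter 1.2σ, fixed charge
  ±1) on harmonic springs (K = 827 k<sub>B</sub>T/nm², R₀ = 0.426 nm), and
  spherical solutes of diameter σ = 0.355 nm: Na⁺, Cl⁻, H⁺, OH⁻, divalent
  M²⁺/X²⁻, and a diprotic weak acid H₂SuA/HSuA⁻/SuA²⁻ (pK<sub>A</sub> 4.2
  and 5.6). Excluded volume is a λ-tunable WCA potential (λ = 0 is the
  athermal, purely repulsive limit; λ maps to the second virial
  coefficient B₂ by quadrature). Electrostatics is the Coulomb potential
  z₁z₂l<sub>B</sub>/r of an implicit dielectric, summed by Ewald
  (tinfoil boundary, auto-tuned to ≤10⁻³ relative error): the complex
  phase uses l_B = 0.9 nm (ε_r ≈ 62), the supernatant 0.71 nm (ε_r ≈ 78).
* **Dynamics.** Langevin dynamics at k<sub>B</sub>T = 1 (BAOAB splitting,
  δt = 0.01τ) samples conformations.
* **Chemistry.** Grand-reaction Monte Carlo samples composition: neutral
  ion-pair insertions/deletions (∅ ⇌ Na⁺+Cl⁻, ∅ ⇌ H⁺+OH⁻, …), in-box
  acid dissociation, and solute-exchange reactions, each accepted with

  min[1, K<sup>ξ</sup> · Π<sub>i</sub> N<sub>i</sub>!/(N<sub>i</sub>+ξν<sub>i</sub>)! · (Vc<sup>⦵</sup>)<sup>ξν̄</sup> · e<sup>−βΔU</sup>]

  Driving two boxes with one equilibrium-constant set Γ equalizes the
  exchangeable species' chemical potentials with a virtual reservoir of
  prescribed pH and salt concentration.
* **Coexistence.** A series of fixed-volume complex runs over monomer
  volume fraction φ yields ΔP(φ) = P<sup>pec</sup> − P<sup>sup</sup>;
  the branch ΔP ≳ 0 is fitted with ΔP(φ) = a₀ + a₁/tan(φ − a₂) and the
  coexistence composition φ⁰ is its root. Self-consistency requires the
  monomer structure factor S(k) not to peak in its smallest-k shell
  (in-box demixing flag). Tie lines give partition coefficients
  K<sub>i</sub> = c<sub>i</sub><sup>pec</sup>/c<sub>i</sub><sup>sup</sup>.

## Worked example: ion partitioning at desk scale

```python
import numpy as np
from pecsim import (Model, ReservoirSpec, constants_from_reservoir,
                    run_phase, new_state, bjerrum_from_permittivity)
from pecsim.fixtures import small_pec_box
from pecsim.units import DEFAULT_UNITS as units

lb_pec = units.to_reduced_length(bjerrum_from_permittivity(62.0))
lb_sup = units.to_reduced_length(bjerrum_from_permittivity(78.0))
model = Model.default()

# one constant set drives both phases (pH 7, 0.1 M NaCl + 5 mM divalent salt)
reservoir = ReservoirSpec(pH=7.0, c_salt_M=0.10, c_divalent_M=0.005)
reactions = constants_from_reservoir(reservoir, model)

pec = small_pec_box(model, n_chains_per_species=4, chain_length=8,
                    target_phi=0.12, rng=np.random.default_rng(1),
                    relax_steps=300, lb=lb_pec)
sup = new_state(L=16.0, spec=np.zeros(0, dtype=np.int64),
                pos=np.zeros((0, 3)), lb=lb_sup, rng=np.random.default_rng(2))

out_pec = run_phase(pec, model, reactions, n_cycles=90, steps_per_cycle=200,
                    mc_attempts_per_cycle=150, equil_cycles=30)
out_sup = run_phase(sup, model, reactions, n_cycles=90, steps_per_cycle=150,
                    mc_attempts_per_cycle=150, equil_cycles=30)

for name in ("Na+", "M2+"):
    cp, ep = out_pec.mean_concentration(model, pec, name)
    cs, es = out_sup.mean_concentration(model, sup, name)
    print(f"{name}: c_pec = {cp:.4f} M, c_sup = {cs:.4f} M, K = {cp/cs:.2f}")
```

Output (about two minutes on one CPU):

```
Na+: c_pec = 0.0906 M, c_sup = 0.1311 M, K = 0.69
M2+: c_pec = 0.0598 M, c_sup = 0.0165 M, K = 3.62
```

The monovalent salt slightly prefers the dilute supernatant (K < 1,
steric repulsion and chain-connectivity correlations win), while the
divalent ion accumulates several-fold in the complex — the two hallmark
partitioning behaviors of these systems. At this deliberately small box
size (8 chains of 8 beads) the numbers carry sizeable statistical and
finite-size errors; production-scale runs (64 chains of 32 beads, 10⁷
steps) sharpen them considerably.

A command-line interface wraps the same machinery: `pecsim run`,
`pecsim titrate`, `pecsim scan`, `pecsim coexist`, `pecsim analyze`,
`pecsim fixtures` (see `pecsim --help`; configuration is a YAML file,
every run writes a manifest with config hash, seed and versions).

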