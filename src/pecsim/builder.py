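"""Construction of the dense polyelectrolyte-complex box.

Chains start as fully extended rods placed on a primitive cubic lattice
(alternating polyanion and polycation), then the box is compressed in
steps of dL = 0.7 sigma with an affine rescale of all coordinates and a
short Langevin relaxation after every step, until the monomer volume
fraction reaches its target.  The final (partial) compression lands the
box exactly on the requested volume fraction.
"""

from __future__ import annotations

import math

import numpy as np

from .coexistence import volume_fraction
from .langevin import LangevinIntegrator, LangevinParams
from .system import Model, SystemState, maxwell_velocities

COMPRESSION_DL = 0.7  # box-edge decrement per compression step, in sigma


def lattice_rods(n_chains_per_species: int, chain_length: int, model: Model,
                 L: float) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Extended rods along z, anchors on a cubic lattice, species alternating."""
    n_chains = 2 * n_chains_per_species
    b = model.bond.r0
    rod_len = (chain_length - 1) * b
    if rod_len >= L:
        raise ValueError("box too small for fully extended rods")
    n_side = math.ceil(math.sqrt(n_chains))
    spacing = L / n_side
    i_anion = model.species.index("A-")
    i_cation = model.species.index("C+")

    pos, spec, chains = [], [], []
    idx = 0
    for c in range(n_chains):
        gx, gy = c % n_side, c // n_side
        x = (gx + 0.5) * spacing
        y = (gy + 0.5) * spacing
        z0 = 0.5 * (L - rod_len)
        si = i_anion if (gx + gy) % 2 == 0 else i_cation
        chain = []
        for m in range(chain_length):
            pos.append((x, y, z0 + m * b))
            spec.append(si)
            chain.append(idx)
            idx += 1
        chains.append(np.array(chain, dtype=np.int64))
    # balance species: alternation on a checkerboard can go uneven for odd grids
    spec = np.array(spec, dtype=np.int64)
    n_anion = int(np.sum(spec == i_anion)) // chain_length
    surplus = n_anion - n_chains_per_species
    if surplus != 0:
        src, dst = (i_anion, i_cation) if surplus > 0 else (i_cation, i_anion)
        for chain in chains:
            if surplus == 0:
                break
            if spec[chain[0]] == src:
                spec[chain] = dst
                surplus += -1 if surplus > 0 else 1
    return np.array(pos, dtype=float), spec, chains


def monomer_volume(model: Model, n_monomers: int) -> float:
    d = model.species["A-"].diameter
    return n_monomers * math.pi / 6.0 * d**3


def build_initial_pec(model: Model,
                      n_chains_per_species: int = 32,
                      chain_length: int = 32,
                      target_phi: float = 0.15,
                      lb: float | None = None,
                      rng: np.random.Generator | None = None,
                      relax_steps: int = 1000,
                      thermalize_steps: int = 1000,
                      ld: LangevinParams | None = None,
                      initial_phi: float = 0.02) -> SystemState:
    """Lattice-initialize and compress a PEC box to the target volume fraction.

    ``relax_steps`` Langevin steps are run between successive compression
    steps (the production default in the protocol is 1e5; scaled-down runs
    use less).  The returned state has exactly the requested monomer volume
    fraction.
    """
    from .units import bjerrum_from_permittivity, DEFAULT_UNITS

    if not 0 < target_phi < 0.6:
        raise ValueError("target volume fraction out of feasible range")
    rng = rng or np.random.default_rng()
    lb = lb if lb is not None else DEFAULT_UNITS.to_reduced_length(
        bjerrum_from_permittivity(62.0))
    n_mon = 2 * n_chains_per_species * chain_length
    v_mon = monomer_volume(model, n_mon)
    L_final = (v_mon / target_phi) ** (1.0 / 3.0)
    rod_len = (chain_length - 1) * model.bond.r0
    L0 = max((v_mon / min(initial_phi, target_phi)) ** (1.0 / 3.0),
             rod_len + 2.0 * model.bond.r0, L_final)
    if L_final > L0:
        raise ValueError("target volume fraction below the initial lattice density")

    pos, spec, chains = lattice_rods(n_chains_per_species, chain_length, model, L0)
    state = SystemState(L=L0, pos=pos, vel=maxwell_velocities(len(spec), rng),
                        spec=spec, chains=chains, lb=lb, rng=rng)
    ld = ld or LangevinParams()
    integ = LangevinIntegrator(state, model, ld)
    if thermalize_steps:
        integ.step(thermalize_steps)

    while state.L > L_final + 1e-12:
        new_L = max(state.L - COMPRESSION_DL, L_final)
        state.rescale(new_L)
        integ.invalidate(box_changed=True)
        if relax_steps and state.L > L_final:
            integ.step(relax_steps)
    phi = volume_fraction(state, model, "monomers")
    assert abs(phi - target_phi) < 1e-9
    return state


def mean_bond_length(frames: list[np.ndarray], bonds: np.ndarray, L: float):
    """(mean, std, stderr) of instantaneous bond lengths over frames (reduced)."""
    if len(bonds) == 0:
        raise ValueError("no bonds in topology")
    all_means = []
    lengths_accum = []
    for pos in frames:
        d = pos[bonds[:, 0]] - pos[bonds[:, 1]]
        d -= L * np.round(d / L)
        lengths = np.linalg.norm(d, axis=1)
        lengths_accum.append(lengths)
        all_means.append(lengths.mean())
    flat = np.concatenate(lengths_accum)
    means = np.array(all_means)
    stderr = means.std(ddof=1) / math.sqrt(len(means)) if len(means) > 1 else float("nan")
    return float(flat.mean()), float(flat.std()), float(stderr)
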