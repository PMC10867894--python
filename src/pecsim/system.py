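"""System state: particles, topology, box, and the model bundle.

Positions are stored unwrapped (minimum-image separations make the pair
terms periodic; reciprocal-space phase factors are periodic by
construction), which keeps center-of-mass displacement diagnostics trivial.
`wrapped_positions` folds coordinates into [0, L) for output and insertion
bookkeeping.

Array-layout invariant: polymer monomers occupy the leading slots of the
particle arrays and are never deleted, so bonded topology indices stay
valid under grand-canonical insertion (append) and deletion (of trailing,
exchangeable particles only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .potentials import BondParams, PairTable, default_bond_params
from .species import SpeciesTable, default_species_table
from .units import DEFAULT_UNITS, UnitSystem


@dataclass
class Model:
    """Interaction model shared by all phases: species, pair table, bonds."""

    species: SpeciesTable
    pairs: PairTable
    bond: BondParams
    units: UnitSystem = field(default_factory=lambda: DEFAULT_UNITS)
    include_bonded_wca: bool = True
    interactions: bool = True  # False = ideal gas (all potentials off)
    electrostatics: bool = True
    ewald_accuracy: float = 1e-3

    @classmethod
    def default(cls, **overrides) -> "Model":
        table = default_species_table()
        return cls(species=table, pairs=PairTable(table),
                   bond=default_bond_params(), **overrides)

    @classmethod
    def ideal(cls) -> "Model":
        return cls.default(interactions=False, electrostatics=False)

    def charges(self) -> np.ndarray:
        return np.array([s.z for s in self.species], dtype=float)


@dataclass
class SystemState:
    """One periodic cubic simulation box.

    ``chains`` lists each polymer as an ordered array of particle indices;
    consecutive entries are bonded.  ``lb`` is the phase's Bjerrum length in
    reduced units (it differs between the complex and the supernatant).
    """

    L: float
    pos: np.ndarray  # (N, 3) unwrapped reduced coordinates
    vel: np.ndarray  # (N, 3)
    spec: np.ndarray  # (N,) int species indices
    chains: list[np.ndarray]
    lb: float
    rng: np.random.Generator

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float).reshape(-1, 3)
        self.vel = np.asarray(self.vel, dtype=float).reshape(-1, 3)
        self.spec = np.asarray(self.spec, dtype=np.int64)
        self._bonds: np.ndarray | None = None

    # --- basic queries ------------------------------------------------
    @property
    def n(self) -> int:
        return self.pos.shape[0]

    @property
    def volume(self) -> float:
        return self.L**3

    def bonds(self) -> np.ndarray:
        """(nb, 2) bonded index pairs derived from the chain topology."""
        if self._bonds is None:
            pairs = []
            for chain in self.chains:
                for a, b in zip(chain[:-1], chain[1:]):
                    pairs.append((a, b))
            self._bonds = (np.array(pairs, dtype=np.int64)
                           if pairs else np.zeros((0, 2), dtype=np.int64))
        return self._bonds

    def charges(self, model: Model) -> np.ndarray:
        return model.charges()[self.spec]

    def total_charge(self, model: Model) -> float:
        return float(self.charges(model).sum())

    def counts(self, model: Model) -> np.ndarray:
        return np.bincount(self.spec, minlength=len(model.species))

    def concentrations_molar(self, model: Model) -> dict[str, float]:
        """Mean number density of every species converted to mol/L."""
        c = self.counts(model) / self.volume
        u = model.units
        return {s.name: u.reduced_density_to_molar(c[i])
                for i, s in enumerate(model.species)}

    def wrapped_positions(self) -> np.ndarray:
        return np.mod(self.pos, self.L)

    # --- mutation (grand-canonical moves) ------------------------------
    def n_monomers(self) -> int:
        return sum(len(c) for c in self.chains)

    def insert(self, spec_idx: int, position: np.ndarray, velocity: np.ndarray) -> int:
        self.pos = np.vstack([self.pos, position.reshape(1, 3)])
        self.vel = np.vstack([self.vel, velocity.reshape(1, 3)])
        self.spec = np.append(self.spec, spec_idx)
        return self.n - 1

    def delete(self, index: int) -> None:
        if index < self.n_monomers():
            raise ValueError("polymer monomers cannot be deleted")
        self.pos = np.delete(self.pos, index, axis=0)
        self.vel = np.delete(self.vel, index, axis=0)
        self.spec = np.delete(self.spec, index)

    def copy(self) -> "SystemState":
        new = SystemState(L=self.L, pos=self.pos.copy(), vel=self.vel.copy(),
                          spec=self.spec.copy(),
                          chains=[c.copy() for c in self.chains],
                          lb=self.lb, rng=self.rng)
        return new

    def rescale(self, new_L: float) -> None:
        """Affine rescale of the box and all coordinates (compression step)."""
        factor = new_L / self.L
        self.pos = self.pos * factor
        self.L = new_L


def maxwell_velocities(n: int, rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities at kT = 1, m = 1."""
    return rng.normal(0.0, 1.0, size=(n, 3))


def new_state(L: float, spec: np.ndarray, pos: np.ndarray, lb: float,
              rng: np.random.Generator, chains: list[np.ndarray] | None = None
              ) -> SystemState:
    spec = np.asarray(spec, dtype=np.int64)
    return SystemState(L=L, pos=pos, vel=maxwell_velocities(len(spec), rng),
                       spec=spec, chains=chains or [], lb=lb, rng=rng)
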