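"""Species registry for the coarse-grained bead model.

Every particle kind (salt ions, water ions, divalent ions, the three
ionization states of the diprotic acid, and the two polymer monomers) is a
:class:`Species` with a charge number, an effective diameter, a
hydrophobicity parameter ``lam`` and an ``exchangeable`` flag.  Polymer
monomers carry fixed charges and are never created or destroyed by the
reaction moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Reduced diameters (unit of length = sigma_ion = 0.355 nm)
ION_DIAMETER = 1.0
MONOMER_DIAMETER = 1.2


@dataclass(frozen=True)
class Species:
    """One particle kind.

    ``lam`` in [0, 1] tunes the attractive tail of the pair potential
    (0 = athermal, purely repulsive).  ``is_monomer`` marks polymer beads,
    which participate in bonded topology and use the longer pair cutoff.
    """

    name: str
    z: int
    diameter: float = ION_DIAMETER
    lam: float = 0.0
    exchangeable: bool = True
    is_monomer: bool = False

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"species {self.name}: diameter must be positive")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"species {self.name}: lam must lie in [0, 1]")
        if self.is_monomer and self.exchangeable:
            raise ValueError(f"species {self.name}: monomers are not exchangeable")


@dataclass
class SpeciesTable:
    """Ordered registry mapping species names to integer indices."""

    species: list[Species] = field(default_factory=list)

    def add(self, sp: Species) -> int:
        if sp.name in self.names():
            raise ValueError(f"duplicate species {sp.name}")
        self.species.append(sp)
        return len(self.species) - 1

    def names(self) -> list[str]:
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        try:
            return self.names().index(name)
        except ValueError:
            raise KeyError(f"unknown species {name}") from None

    def __getitem__(self, key: str | int) -> Species:
        if isinstance(key, str):
            return self.species[self.index(key)]
        return self.species[key]

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self):
        return iter(self.species)

    def charges(self) -> list[int]:
        return [s.z for s in self.species]


def default_species_table(
    monomer_diameter: float = MONOMER_DIAMETER,
    monomer_lam: float = 0.0,
    monomer_charge: int = 1,
) -> SpeciesTable:
    """The default cast: salt/water ions, divalents, diprotic acid, monomers.

    The polyanion bead ``A-`` carries charge ``-monomer_charge`` and the
    polycation bead ``C+`` carries ``+monomer_charge``; both are
    non-exchangeable and flagged as monomers.
    """
    t = SpeciesTable()
    t.add(Species("Na+", +1))
    t.add(Species("Cl-", -1))
    t.add(Species("H+", +1))
    t.add(Species("OH-", -1))
    t.add(Species("M2+", +2))
    t.add(Species("X2-", -2))
    t.add(Species("H2SuA", 0))
    t.add(Species("HSuA-", -1))
    t.add(Species("SuA2-", -2))
    t.add(
        Species(
            "A-",
            -monomer_charge,
            diameter=monomer_diameter,
            lam=monomer_lam,
            exchangeable=False,
            is_monomer=True,
        )
    )
    t.add(
        Species(
            "C+",
            +monomer_charge,
            diameter=monomer_diameter,
            lam=monomer_lam,
            exchangeable=False,
            is_monomer=True,
        )
    )
    return t
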