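"""Run configuration: a YAML file with flat key-value sections.

Every default mirrors the standard parameterization of the model (ion
diameter 0.355 nm, monomer diameter 0.426 nm, spring 827 kT/nm^2, complex
permittivity 62, supernatant permittivity 78, pK_A 4.2/5.6, time step
0.01 tau, reaction cadence 500 attempts per 1e4 steps).  Loading and
serializing round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .units import DEFAULT_UNITS, bjerrum_from_permittivity


@dataclass
class SpeciesConfig:
    monomer_diameter_nm: float = 0.426
    ion_diameter_nm: float = 0.355
    monomer_lam: float = 0.0
    monomer_charge: int = 1


@dataclass
class InteractionConfig:
    eps_r_pec: float = 62.0
    eps_r_sup: float = 78.0
    k_bond_kt_per_nm2: float = 827.0
    bond_r0_nm: float = 0.426
    include_bonded_wca: bool = True
    ewald_accuracy: float = 1.0e-3
    electrostatics: bool = True
    interactions: bool = True


@dataclass
class ReservoirConfig:
    pH: float = 7.0
    c_salt_M: float = 0.15
    c_divalent_M: float = 0.0
    c_solute_M: float = 0.0
    pk_a1: float = 4.2
    pk_a2: float = 5.6
    pk_w: float = 14.0


@dataclass
class ProtocolConfig:
    n_chains_per_species: int = 32
    chain_length: int = 32
    target_phi: float = 0.15
    dt: float = 0.01
    gamma: float = 1.0
    relax_steps: int = 100_000        # dynamics steps between compressions
    equil_cycles: int = 20
    n_cycles: int = 100
    steps_per_cycle: int = 10_000
    mc_attempts_per_cycle: int = 500
    phi_grid: list[float] = field(default_factory=list)  # empty = auto
    sup_box_L: float = 20.0


@dataclass
class RunConfig:
    phase: str = "pec"  # pec | supernatant
    seed: int = 1
    outdir: str = "out"
    species: SpeciesConfig = field(default_factory=SpeciesConfig)
    interactions: InteractionConfig = field(default_factory=InteractionConfig)
    reservoir: ReservoirConfig = field(default_factory=ReservoirConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)

    def __post_init__(self) -> None:
        if self.phase not in ("pec", "supernatant"):
            raise ValueError("phase must be 'pec' or 'supernatant'")

    # -- serialization -------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        return cls.from_dict(raw)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sections = {"species": SpeciesConfig, "interactions": InteractionConfig,
                    "reservoir": ReservoirConfig, "protocol": ProtocolConfig}
        kwargs = {}
        for key, value in raw.items():
            if key in sections:
                known = sections[key].__dataclass_fields__
                bad = set(value) - set(known)
                if bad:
                    raise ValueError(f"unknown keys in section '{key}': "
                                     f"{', '.join(sorted(f'{key}.{b}' for b in bad))}")
                kwargs[key] = sections[key](**value)
            elif key in ("phase", "seed", "outdir"):
                kwargs[key] = value
            else:
                raise ValueError(f"unknown configuration key: {key}")
        return cls(**kwargs)

    # -- model construction --------------------------------------------
    def build_model(self):
        from .potentials import BondParams, PairTable
        from .species import default_species_table
        from .system import Model

        u = DEFAULT_UNITS
        table = default_species_table(
            monomer_diameter=self.species.monomer_diameter_nm / self.species.ion_diameter_nm,
            monomer_lam=self.species.monomer_lam,
            monomer_charge=self.species.monomer_charge,
        )
        bond = BondParams(
            k_bond=u.energy_per_nm2_to_reduced(self.interactions.k_bond_kt_per_nm2),
            r0=u.to_reduced_length(self.interactions.bond_r0_nm),
        )
        return Model(species=table, pairs=PairTable(table), bond=bond, units=u,
                     include_bonded_wca=self.interactions.include_bonded_wca,
                     interactions=self.interactions.interactions,
                     electrostatics=self.interactions.electrostatics,
                     ewald_accuracy=self.interactions.ewald_accuracy)

    def bjerrum_reduced(self) -> float:
        eps = (self.interactions.eps_r_pec if self.phase == "pec"
               else self.interactions.eps_r_sup)
        return DEFAULT_UNITS.to_reduced_length(bjerrum_from_permittivity(eps))

    def reservoir_spec(self):
        from .grxmc import ReservoirSpec

        r = self.reservoir
        return ReservoirSpec(pH=r.pH, c_salt_M=r.c_salt_M,
                             c_divalent_M=r.c_divalent_M,
                             c_solute_M=r.c_solute_M, pk_a1=r.pk_a1,
                             pk_a2=r.pk_a2, pk_w=r.pk_w)
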