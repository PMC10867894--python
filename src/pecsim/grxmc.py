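"""Grand-reaction Monte Carlo: reservoir-coupled ion and speciation sampling.

Composition fluctuations are sampled by stochastic chemical reactions:
grand-canonical pair insertions/deletions of neutral ion combinations
(NaCl, H2O autoionization products, NaOH, HCl, divalent salts), acid-base
dissociation of a diprotic solute inside the box, and exchange reactions
that insert/delete the solute's ionization states together with
neutralizing counterions.  Every reaction is electroneutral, so the box
charge is conserved exactly.

Each reaction carries a dimensionless equilibrium constant referred to the
standard concentration c_std = 1 mol/L.  A trial move in direction
xi = +/-1 is accepted with probability

    min[1, K^xi * prod_i N_i!/(N_i + xi nu_i)! * (V c_std)^(xi nu_bar)
           * exp(-beta dU)]

evaluated in log space.  Two boxes (complex and supernatant) driven by the
same constant set exchange species with a common virtual reservoir, which
equalizes the relevant linear combinations of chemical potentials across
the phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .ewald import EwaldParams, tune_ewald
from .system import Model, SystemState, maxwell_velocities

_SQRT_PI = math.sqrt(math.pi)


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction: signed stoichiometry (negative = consumed) and ln K."""

    label: str
    stoichiometry: dict[str, int]
    ln_k: float

    @property
    def k_gamma(self) -> float:
        return math.exp(self.ln_k)

    def validate(self, model: Model) -> None:
        if not self.stoichiometry or all(v == 0 for v in self.stoichiometry.values()):
            raise ValueError(f"reaction {self.label}: no species changes")
        net_charge = 0
        for name, nu in self.stoichiometry.items():
            sp = model.species[name]
            if not sp.exchangeable:
                raise ValueError(
                    f"reaction {self.label}: species {name} is not exchangeable "
                    "(polymer monomers cannot take part in reaction moves)")
            net_charge += nu * sp.z
        if net_charge != 0:
            raise ValueError(f"reaction {self.label}: stoichiometry is not neutral")

    @property
    def nu_bar(self) -> int:
        return sum(self.stoichiometry.values())


def acceptance_probability(counts: dict[str, int], reaction: ReactionSpec,
                           xi: int, d_energy: float, v_cstd: float) -> float:
    """Acceptance probability of one trial reaction move.

    ``counts`` maps species name -> current particle number; ``v_cstd`` is
    the box volume times the reference concentration (the particle number a
    box of this volume would hold at c_std).  Out-of-range proposals
    (negative resulting counts) return 0.
    """
    if xi not in (-1, 1):
        raise ValueError("xi must be +1 or -1")
    ln_acc = xi * reaction.ln_k - d_energy
    for name, nu in reaction.stoichiometry.items():
        n0 = counts[name]
        n1 = n0 + xi * nu
        if n1 < 0:
            return 0.0
        ln_acc += math.lgamma(n0 + 1) - math.lgamma(n1 + 1)
        ln_acc += xi * nu * math.log(v_cstd)
    return min(1.0, math.exp(min(ln_acc, 0.0)) if ln_acc < 0 else 1.0)


# ----------------------------------------------------------------------
# Reservoir definition and the map (pH, c_salt, ...) -> equilibrium constants
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ReservoirSpec:
    """Target composition of the virtual reservoir (ideal-gas level).

    The pH is on the concentration scale, -log10(c_H+/mol/L).  Only two of
    the three ion-pair constants (NaCl, NaOH, HCl) are independent: the
    third follows from electroneutrality of the reservoir through the cycle
    identity K_NaOH * K_HCl = K_NaCl * K_w.
    """

    pH: float = 7.0
    c_salt_M: float = 0.1
    c_divalent_M: float = 0.0
    c_solute_M: float = 0.0
    pk_a1: float = 4.2
    pk_a2: float = 5.6
    pk_w: float = 14.0

    def ideal_concentrations(self) -> dict[str, float]:
        """Electroneutral ideal composition (mol/L) realizing the targets."""
        c_h = 10.0 ** (-self.pH)
        c_oh = 10.0 ** (-(self.pk_w - self.pH))
        c = {"H+": c_h, "OH-": c_oh, "Na+": self.c_salt_M, "Cl-": self.c_salt_M,
             "M2+": 0.0, "X2-": 0.0, "H2SuA": 0.0, "HSuA-": 0.0, "SuA2-": 0.0}
        if self.c_divalent_M > 0:
            c["M2+"] = self.c_divalent_M
            c["Cl-"] += 2.0 * self.c_divalent_M
        if self.c_solute_M > 0:
            from .observables import ideal_speciation

            f0, f1, f2 = ideal_speciation(self.pH, self.pk_a1, self.pk_a2)
            c["H2SuA"] = f0 * self.c_solute_M
            c["HSuA-"] = f1 * self.c_solute_M
            c["SuA2-"] = f2 * self.c_solute_M
            c["Na+"] += c["HSuA-"] + 2.0 * c["SuA2-"]
        # set pH with NaOH or HCl
        if c_oh >= c_h:
            c["Na+"] += c_oh - c_h
        else:
            c["Cl-"] += c_h - c_oh
        return c

    def ionic_strength_M(self) -> float:
        from .species import default_species_table

        table = default_species_table()
        c = self.ideal_concentrations()
        return 0.5 * sum(c[name] * table[name].z ** 2 for name in c)


def constants_from_reservoir(spec: ReservoirSpec, model: Model | None = None
                             ) -> list[ReactionSpec]:
    """Ideal-gas (mass action) equilibrium constants realizing the reservoir.

    The insertion constants are products of the target ideal concentrations
    (in units of c_std), which makes the electroneutrality constraint and
    every thermodynamic cycle close by construction.  The acid-dissociation
    constants inside the box are the bare acidity constants.
    """
    c = spec.ideal_concentrations()
    for name, v in c.items():
        if v < 0:
            raise ValueError(f"infeasible reservoir: negative implied {name}")
    reactions = [
        ReactionSpec("NaCl_in", {"Na+": 1, "Cl-": 1},
                     math.log(c["Na+"] * c["Cl-"])),
        ReactionSpec("water_auto", {"H+": 1, "OH-": 1},
                     -spec.pk_w * math.log(10.0)),
        ReactionSpec("NaOH_in", {"Na+": 1, "OH-": 1},
                     math.log(c["Na+"] * c["OH-"])),
        ReactionSpec("HCl_in", {"H+": 1, "Cl-": 1},
                     math.log(c["H+"] * c["Cl-"])),
    ]
    if spec.c_divalent_M > 0:
        reactions.append(ReactionSpec(
            "MCl2_in", {"M2+": 1, "Cl-": 2},
            math.log(c["M2+"] * c["Cl-"] ** 2)))
    if spec.c_solute_M > 0:
        reactions += [
            ReactionSpec("acid_diss_1", {"H2SuA": -1, "H+": 1, "HSuA-": 1},
                         -spec.pk_a1 * math.log(10.0)),
            ReactionSpec("acid_diss_2", {"HSuA-": -1, "H+": 1, "SuA2-": 1},
                         -spec.pk_a2 * math.log(10.0)),
            ReactionSpec("H2SuA_in", {"H2SuA": 1}, math.log(c["H2SuA"])),
            ReactionSpec("NaHSuA_in", {"Na+": 1, "HSuA-": 1},
                         math.log(c["Na+"] * c["HSuA-"])),
            ReactionSpec("Na2SuA_in", {"Na+": 2, "SuA2-": 1},
                         math.log(c["Na+"] ** 2 * c["SuA2-"])),
        ]
    if model is not None:
        for r in reactions:
            r.validate(model)
    return reactions


# ----------------------------------------------------------------------
# The sampler
# ----------------------------------------------------------------------

@dataclass
class _Trial:
    removed: list[int] = field(default_factory=list)
    added_spec: list[int] = field(default_factory=list)
    added_pos: list[np.ndarray] = field(default_factory=list)


class ReactionSampler:
    """Performs reaction trial moves on one box with incremental energetics.

    The energy change of a trial is assembled from the interactions of the
    removed and added particles only (short-range and screened-Coulomb
    terms by direct subset sums; the reciprocal-space term by updating the
    cached charge structure amplitudes; the Ewald self term analytically).
    A full-recompute cross-check of this bookkeeping lives in the tests.
    """

    def __init__(self, model: Model, reactions: list[ReactionSpec],
                 ewald: EwaldParams | None = None):
        for r in reactions:
            r.validate(model)
        self.model = model
        self.reactions = reactions
        self._ewald = ewald
        self.n_attempted = 0
        self.n_accepted = 0

    # -- energetics ----------------------------------------------------
    def _ewald_params(self, state: SystemState) -> EwaldParams:
        if self._ewald is None:
            self._ewald = tune_ewald(state.L, accuracy=self.model.ewald_accuracy)
        return self._ewald

    def _subset_energy(self, pos, spec, q, subset, L, lb, alpha, rcoul, do_coul):
        p = self.model.pairs
        return _kernels.subset_energy(pos, spec, q,
                                      np.asarray(subset, dtype=np.int64), L,
                                      p.sigma, p.lam, p.cutoff, p.shift,
                                      lb, alpha, rcoul, do_coul)

    def _trial_delta_energy(self, state: SystemState, trial: _Trial,
                            sk: np.ndarray | None):
        """Return (dE, new_sk)."""
        model = self.model
        if not model.interactions:
            return 0.0, sk
        zch = model.charges()
        q = zch[state.spec]
        do_coul = model.electrostatics
        if do_coul:
            ew = self._ewald_params(state)
            alpha, rcoul = ew.alpha, ew.r_cut
        else:
            ew, alpha, rcoul = None, 1.0, 0.0

        d_e = 0.0
        # energy of removed particles with the rest (old configuration)
        if trial.removed:
            d_e -= self._subset_energy(state.pos, state.spec, q, trial.removed,
                                       state.L, state.lb, alpha, rcoul, do_coul)
        # energy of added particles in the new configuration
        if trial.added_spec:
            keep = np.ones(state.n, dtype=bool)
            keep[trial.removed] = False
            pos_new = np.vstack([state.pos[keep]] + [p.reshape(1, 3)
                                                     for p in trial.added_pos])
            spec_new = np.concatenate([state.spec[keep],
                                       np.array(trial.added_spec, dtype=np.int64)])
            q_new = zch[spec_new]
            n_added = len(trial.added_spec)
            subset = list(range(len(spec_new) - n_added, len(spec_new)))
            d_e += self._subset_energy(pos_new, spec_new, q_new, subset,
                                       state.L, state.lb, alpha, rcoul, do_coul)

        new_sk = sk
        if do_coul:
            # reciprocal-space and self corrections
            d_sk = np.zeros(ew.kvecs.shape[0], np.complex128)
            q_rem2 = 0.0
            q_add2 = 0.0
            if trial.removed:
                idx = np.asarray(trial.removed, dtype=np.int64)
                d_sk -= _kernels.struct_factor_charge(
                    state.pos[idx], q[idx], state.L, ew.kvecs, ew.n_max)
                q_rem2 = float(np.sum(q[idx] ** 2))
            if trial.added_spec:
                apos = np.vstack([p.reshape(1, 3) for p in trial.added_pos])
                aq = zch[np.array(trial.added_spec, dtype=np.int64)]
                d_sk += _kernels.struct_factor_charge(
                    apos, aq, state.L, ew.kvecs, ew.n_max)
                q_add2 = float(np.sum(aq**2))
            new_sk = sk + d_sk
            d_e += (_kernels.recip_energy_from_sk(new_sk, state.L, alpha,
                                                  ew.kvecs, state.lb)
                    - _kernels.recip_energy_from_sk(sk, state.L, alpha,
                                                    ew.kvecs, state.lb))
            d_e += -state.lb * alpha / _SQRT_PI * (q_add2 - q_rem2)
        return d_e, new_sk

    # -- move construction ---------------------------------------------
    def _build_trial(self, state: SystemState, reaction: ReactionSpec,
                     xi: int) -> _Trial | None:
        model = self.model
        counts = state.counts(model)
        consumed: list[int] = []  # species indices, expanded by count
        produced: list[int] = []
        for name, nu in reaction.stoichiometry.items():
            s = xi * nu
            si = model.species.index(name)
            if s < 0:
                if counts[si] < -s:
                    return None  # infeasible; acceptance is 0 anyway
                consumed += [si] * (-s)
            elif s > 0:
                produced += [si] * s
        key = lambda si: (-model.species[si].diameter, si)
        consumed.sort(key=key)
        produced.sort(key=key)

        trial = _Trial()
        chosen: set[int] = set()
        for si in consumed:
            pool = np.flatnonzero(state.spec == si)
            pool = pool[~np.isin(pool, list(chosen))] if chosen else pool
            pick = int(state.rng.choice(pool))
            chosen.add(pick)
            trial.removed.append(pick)
        # pair leading consumed/produced entries: identity change in place
        n_pair = min(len(consumed), len(produced))
        for a in range(len(produced)):
            trial.added_spec.append(produced[a])
            if a < n_pair:
                trial.added_pos.append(state.pos[trial.removed[a]].copy())
            else:
                trial.added_pos.append(state.rng.uniform(0.0, state.L, size=3))
        return trial

    def _apply(self, state: SystemState, trial: _Trial) -> None:
        for idx in sorted(trial.removed, reverse=True):
            state.delete(idx)
        for si, p in zip(trial.added_spec, trial.added_pos):
            state.insert(si, p, maxwell_velocities(1, state.rng)[0])

    # -- public API ----------------------------------------------------
    def attempt(self, state: SystemState, sk: np.ndarray | None = None):
        """One trial reaction move; mutates ``state`` on acceptance.

        Returns (accepted, new_sk).  ``sk`` is the cached charge structure
        amplitude array for the current positions (None when electrostatics
        is off).
        """
        rng = state.rng
        reaction = self.reactions[int(rng.integers(len(self.reactions)))]
        xi = 1 if rng.random() < 0.5 else -1
        self.n_attempted += 1

        trial = self._build_trial(state, reaction, xi)
        counts = {s.name: int(c) for s, c in
                  zip(self.model.species, state.counts(self.model))}
        v_cstd = state.volume * self.model.units.reference_density_reduced
        if trial is None:
            return False, sk
        d_e, new_sk = self._trial_delta_energy(state, trial, sk)
        p_acc = acceptance_probability(counts, reaction, xi, d_e, v_cstd)
        if rng.random() < p_acc:
            self._apply(state, trial)
            self.n_accepted += 1
            return True, new_sk
        return False, sk

    def run_block(self, state: SystemState, n_attempts: int) -> int:
        """A block of trial moves with a freshly computed amplitude cache."""
        sk = None
        if (self.model.interactions and self.model.electrostatics):
            ew = self._ewald_params(state)
            q = state.charges(self.model)
            sk = _kernels.struct_factor_charge(state.pos, q, state.L,
                                               ew.kvecs, ew.n_max)
        acc = 0
        for _ in range(n_attempts):
            ok, sk = self.attempt(state, sk)
            acc += int(ok)
        return acc

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / max(1, self.n_attempted)


def calibrate_reservoir(model: Model, reactions: list[ReactionSpec],
                        lb: float, L: float = 16.0,
                        n_cycles: int = 400, steps_per_cycle: int = 50,
                        mc_attempts_per_cycle: int = 50,
                        equil_cycles: int = 100,
                        rng: np.random.Generator | None = None) -> dict:
    """Measure the actual composition a constant set produces.

    Runs an auxiliary supernatant-only simulation (ions in implicit solvent
    at the supernatant Bjerrum length) and reports time-averaged
    concentrations of every species, the pH on the concentration scale,
    the salt concentration, and the ionic strength.  With interactions on,
    the measured concentrations shift away from the ideal targets (activity
    effects), which is why reported compositions are not round numbers.

    The result carries an ``equilibrated`` flag from a first-half vs
    second-half drift test on the total particle number.
    """
    from .simulate import block_stats, run_phase
    from .system import new_state

    rng = rng or np.random.default_rng(0)
    state = new_state(L, np.zeros(0, dtype=np.int64), np.zeros((0, 3)),
                      lb=lb, rng=rng)
    result = run_phase(state, model, reactions, n_cycles=n_cycles,
                       steps_per_cycle=steps_per_cycle if model.interactions else 0,
                       mc_attempts_per_cycle=mc_attempts_per_cycle,
                       equil_cycles=equil_cycles, measure_pressure=model.interactions)

    out: dict = {"concentrations_M": {}, "L": L}
    to_molar = model.units.reduced_density_to_molar(1.0 / state.volume)
    totals = None
    for sp in model.species:
        series = result.table[f"N_{sp.name}"].to_numpy(dtype=float)
        totals = series if totals is None else totals + series
        m, se = block_stats(series)
        out["concentrations_M"][sp.name] = {"mean": m * to_molar,
                                            "stderr": se * to_molar}
    c = out["concentrations_M"]
    out["pH"] = -math.log10(c["H+"]["mean"]) if c["H+"]["mean"] > 0 else float("nan")
    out["c_salt_M"] = c["Na+"]["mean"]
    out["ionic_strength_M"] = 0.5 * sum(
        c[sp.name]["mean"] * sp.z**2 for sp in model.species)
    half = len(totals) // 2
    m1, s1 = block_stats(totals[:half])
    m2, s2 = block_stats(totals[half:])
    drift_sigma = math.hypot(s1, s2) or 1.0
    out["equilibrated"] = bool(abs(m2 - m1) < 4.0 * drift_sigma)
    return out
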