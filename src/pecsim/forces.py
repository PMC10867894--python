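"""Assembly of the total energy, forces, and virial pressure of one phase.

The electrostatic pressure contribution exploits homogeneity: the full
periodic Coulomb energy of a configuration scales as 1/L under an affine
dilation of the box (with Ewald parameters scaled consistently), hence
P_elec = U_elec / (3V) exactly.  Short-range and bonded contributions enter
through the standard pair virial sum(r . F)/3V.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .ewald import EwaldParams, recip_energy_forces, self_energy, tune_ewald
from .system import Model, SystemState


@dataclass
class EnergyBreakdown:
    bonded: float
    short_range: float
    electrostatic: float
    wca_virial: float
    bond_virial: float
    forces: np.ndarray

    @property
    def total(self) -> float:
        return self.bonded + self.short_range + self.electrostatic


def get_ewald(state: SystemState, model: Model,
              params: EwaldParams | None = None) -> EwaldParams:
    if params is not None:
        return params
    return tune_ewald(state.L, accuracy=model.ewald_accuracy)


def _ewald_total(pos, q, L, params: EwaldParams, lb) -> float:
    """Full Ewald energy of bare point charges (real + recip + self)."""
    spec = np.zeros(len(q), dtype=np.int64)
    zero = np.zeros((1, 1))
    e_real = _kernels.short_range_ef(pos, spec, q, L, zero, zero, zero, zero,
                                     lb, params.alpha, params.r_cut, True)[1]
    e_recip = recip_energy_forces(pos, q, L, params, lb)[0]
    return e_real + e_recip + self_energy(q, params.alpha, lb)


def compute_energy_forces(state: SystemState, model: Model,
                          ewald: EwaldParams | None = None) -> EnergyBreakdown:
    n = state.n
    if not model.interactions:
        return EnergyBreakdown(0.0, 0.0, 0.0, 0.0, 0.0, np.zeros((n, 3)))

    q = state.charges(model)
    do_coul = model.electrostatics and np.any(q != 0.0)
    if do_coul:
        if abs(q.sum()) > 1e-9:
            raise ValueError(
                f"electrostatics requires a neutral system (net charge {q.sum():g})"
            )
        ew = get_ewald(state, model, ewald)
        alpha, rcoul = ew.alpha, ew.r_cut
    else:
        ew, alpha, rcoul = None, 1.0, 0.0

    p = model.pairs
    e_wca, e_real, f, w_wca = _kernels.short_range_ef(
        state.pos, state.spec, q, state.L, p.sigma, p.lam, p.cutoff, p.shift,
        state.lb, alpha, rcoul, do_coul)

    bonds = state.bonds()
    e_bond, w_bond = 0.0, 0.0
    if len(bonds):
        e_bond, f_bond, w_bond = _kernels.bonds_ef(
            state.pos, bonds, state.L, model.bond.k_bond, model.bond.r0)
        f = f + f_bond
        if not model.include_bonded_wca:
            e_x, f_x, w_x = _bonded_wca_terms(state, model)
            e_wca -= e_x
            f = f - f_x
            w_wca -= w_x

    e_elec = 0.0
    if do_coul:
        e_recip, f_recip = recip_energy_forces(state.pos, q, state.L, ew, state.lb)
        e_elec = e_real + e_recip + self_energy(q, alpha, state.lb)
        f = f + f_recip

    return EnergyBreakdown(bonded=e_bond, short_range=e_wca, electrostatic=e_elec,
                           wca_virial=w_wca, bond_virial=w_bond, forces=f)


def _bonded_wca_terms(state: SystemState, model: Model):
    """WCA energy/forces/virial restricted to bonded pairs (for exclusion)."""
    bonds = state.bonds()
    p = model.pairs
    n = state.n
    e, w = 0.0, 0.0
    f = np.zeros((n, 3))
    for i, j in bonds:
        d = state.pos[i] - state.pos[j]
        d -= state.L * np.round(d / state.L)
        r2 = float(d @ d)
        si, sj = state.spec[i], state.spec[j]
        rc = p.cutoff[si, sj]
        if r2 < rc * rc:
            ev, fp = _kernels._pair_wca(r2, p.sigma[si, sj], p.lam[si, sj],
                                        p.shift[si, sj])
            e += ev
            f[i] += fp * d
            f[j] -= fp * d
            w += fp * r2
    return e, f, w


def total_energy(state: SystemState, model: Model,
                 ewald: EwaldParams | None = None) -> dict[str, float]:
    """Energy breakdown {bonded, short_range, electrostatic, total} in kT."""
    eb = compute_energy_forces(state, model, ewald)
    return {"bonded": eb.bonded, "short_range": eb.short_range,
            "electrostatic": eb.electrostatic, "total": eb.total}


def pressure_from_breakdown(eb: EnergyBreakdown, state: SystemState) -> float:
    return (state.n + (eb.wca_virial + eb.bond_virial) / 3.0
            + eb.electrostatic / 3.0) / state.volume


def virial_pressure(state: SystemState, model: Model,
                    ewald: EwaldParams | None = None) -> float:
    """Instantaneous pressure (reduced): ideal + pair virial + electrostatic."""
    if not model.interactions:
        return state.n / state.volume
    eb = compute_energy_forces(state, model, ewald)
    return pressure_from_breakdown(eb, state)
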