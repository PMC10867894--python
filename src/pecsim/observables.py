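"""Structural and chemical observables.

Static structure factors on the discrete wavevector lattice of the periodic
box (spherically shell-averaged), chain conformation and relaxation
diagnostics, and the acid-base analysis layer: ideal diprotic speciation,
the potential-augmented ionization law, apparent-pK shifts of measured
titration curves, and the Debye-Hueckel prediction for those shifts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

LN10 = math.log(10.0)


# ----------------------------------------------------------------------
# structure factor
# ----------------------------------------------------------------------

@dataclass
class StructureFactorCurve:
    k: np.ndarray  # shell-averaged |k| (ascending)
    s_k: np.ndarray
    counts: np.ndarray  # wavevectors per shell


def structure_factor(frames: list[np.ndarray], L: float,
                     subset: np.ndarray | None = None,
                     n_max: int = 8) -> StructureFactorCurve:
    """Spherically averaged S(k) = <|sum_j exp(i k.r_j)|^2>/N over frames.

    Wavevectors are the box modes 2 pi n / L with |n| <= n_max, binned into
    shells of width 2 pi / L starting at the smallest nonzero mode.
    """
    if not frames:
        raise ValueError("need at least one frame")
    grid = np.arange(-n_max, n_max + 1)
    nx, ny, nz = np.meshgrid(grid, grid, grid, indexing="ij")
    n_vec = np.column_stack([nx.ravel(), ny.ravel(), nz.ravel()])
    n2 = np.sum(n_vec**2, axis=1)
    keep = (n2 > 0) & (n2 <= n_max * n_max)
    n_vec = n_vec[keep]
    kvecs = 2.0 * math.pi / L * n_vec
    kmag = np.linalg.norm(kvecs, axis=1)

    acc = np.zeros(len(kvecs))
    n_part = None
    for pos in frames:
        r = pos if subset is None else pos[subset]
        if len(r) == 0:
            raise ValueError("empty species selection")
        n_part = len(r)
        phase = np.exp(1j * (r @ kvecs.T))
        s = phase.sum(axis=0)
        acc += (s.real**2 + s.imag**2) / n_part
    acc /= len(frames)

    dk = 2.0 * math.pi / L
    shell = np.floor(kmag / dk - 0.5 + 1e-9).astype(int)
    shell = np.clip(shell, 0, None)
    n_shells = shell.max() + 1
    k_out = np.zeros(n_shells)
    s_out = np.zeros(n_shells)
    c_out = np.zeros(n_shells, dtype=int)
    for i in range(len(kvecs)):
        k_out[shell[i]] += kmag[i]
        s_out[shell[i]] += acc[i]
        c_out[shell[i]] += 1
    mask = c_out > 0
    return StructureFactorCurve(k=(k_out[mask] / c_out[mask]),
                                s_k=(s_out[mask] / c_out[mask]),
                                counts=c_out[mask])


# ----------------------------------------------------------------------
# chain conformation and relaxation
# ----------------------------------------------------------------------

@dataclass
class ChainMetrics:
    rg: float
    rg_std: float
    end_to_end: float
    msd_time: np.ndarray
    msd_com: np.ndarray
    relaxation_time: float  # MSD crossing of Rg^2; nan if not reached


def chain_metrics(frames: list[np.ndarray], times: np.ndarray,
                  chains: list[np.ndarray]) -> ChainMetrics:
    """Radius of gyration, end-to-end distance, and center-of-mass MSD.

    Positions must be unwrapped.  The relaxation-time estimate is the lag
    at which the chain center-of-mass MSD first exceeds the mean Rg^2; a
    warning is issued when the trajectory is shorter than 10x that time.
    """
    if not chains:
        raise ValueError("topology required")
    times = np.asarray(times, dtype=float)
    rgs, e2es = [], []
    coms = np.empty((len(frames), len(chains), 3))
    for fi, pos in enumerate(frames):
        for ci, chain in enumerate(chains):
            r = pos[chain]
            com = r.mean(axis=0)
            coms[fi, ci] = com
            rgs.append(math.sqrt(float(np.mean(np.sum((r - com) ** 2, axis=1)))))
            if len(chain) > 1:
                e2es.append(float(np.linalg.norm(r[-1] - r[0])))
    rg = float(np.mean(rgs))
    rg_std = float(np.std(rgs))

    n_f = len(frames)
    lags = np.arange(1, n_f)
    msd = np.empty(len(lags))
    for li, lag in enumerate(lags):
        d = coms[lag:] - coms[:-lag]
        msd[li] = float(np.mean(np.sum(d**2, axis=2)))
    msd_time = times[lags] - times[0]

    tau = float("nan")
    cross = np.nonzero(msd >= rg**2)[0]
    if len(cross):
        tau = float(msd_time[cross[0]])
        if msd_time[-1] < 10.0 * tau:
            warnings.warn("trajectory shorter than 10x the estimated "
                          "relaxation time; averages may not be converged",
                          stacklevel=2)
    return ChainMetrics(rg=rg, rg_std=rg_std,
                        end_to_end=float(np.mean(e2es)) if e2es else 0.0,
                        msd_time=msd_time, msd_com=msd,
                        relaxation_time=tau)


def rigid_rod_rg(n_beads: int, spacing: float) -> float:
    """Closed-form radius of gyration of a discrete rod of n equidistant beads."""
    return spacing * math.sqrt((n_beads**2 - 1) / 12.0)


# ----------------------------------------------------------------------
# acid-base analysis
# ----------------------------------------------------------------------

def ideal_speciation(ph, pk_a1: float, pk_a2: float):
    """Ideal fractions (neutral, mono-, di-anion) of a diprotic acid.

    Closed-form mass action: the neutral and monoanion populations cross at
    pH = pK_A1, the monoanion peaks at pH = (pK_A1 + pK_A2)/2, and the
    mono-/di-anion populations cross at pH = pK_A2.
    """
    ph = np.asarray(ph, dtype=float)
    r1 = 10.0 ** (ph - pk_a1)  # c_HA / c_H2A
    r2 = 10.0 ** (ph - pk_a2)  # c_A / c_HA
    denom = 1.0 + r1 + r1 * r2
    f0 = 1.0 / denom
    f1 = r1 / denom
    f2 = r1 * r2 / denom
    if ph.ndim == 0:
        return float(f0), float(f1), float(f2)
    return f0, f1, f2


def augmented_hh(ph, pk_a: float, z: int = -1, psi: float = 0.0):
    """Degree of ionization with a mean electrostatic-potential correction.

    alpha = 1 / (1 + 10^(pK_A - pH) * exp(z * psi)), with ``z`` the charge
    number of the ionized form and ``psi`` the mean electrostatic potential
    in units of kT/e.  psi = 0 recovers the ideal law; a potential shift
    z*psi = +/- ln(10) translates the curve by exactly one pH unit, and the
    direction of the shift flips with the sign of z.
    """
    ph = np.asarray(ph, dtype=float)
    alpha = 1.0 / (1.0 + 10.0 ** (pk_a - ph) * math.exp(z * psi))
    return float(alpha) if ph.ndim == 0 else alpha


@dataclass
class TitrationCurve:
    """Measured per-pH populations of the three acid states + ideal reference."""

    ph: np.ndarray
    fractions: np.ndarray  # (3, n_ph): H2A, HA-, A2-
    errors: np.ndarray
    pk_a1: float = 4.2
    pk_a2: float = 5.6
    ideal: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        self.ideal = np.vstack(ideal_speciation(self.ph, self.pk_a1, self.pk_a2))

    def apparent_pk_shifts(self) -> np.ndarray:
        return apparent_pk_shift(self.ph, self.fractions, self.pk_a1, self.pk_a2)


def apparent_pk_shift(ph: np.ndarray, measured_fractions: np.ndarray,
                      pk_a1: float, pk_a2: float,
                      max_shift: float = 3.0) -> np.ndarray:
    """Per-state horizontal offset between measured and ideal populations.

    For each ionization state, finds the shift s minimizing
    sum_pH (measured(pH) - ideal(pH - s))^2; negative s means the measured
    curve is displaced toward lower pH (enhanced ionization).
    """
    ph = np.asarray(ph, dtype=float)
    measured = np.asarray(measured_fractions, dtype=float)
    shifts = np.empty(3)
    for state in range(3):
        def loss(s, state=state):
            ideal = np.vstack(ideal_speciation(ph - s, pk_a1, pk_a2))[state]
            return float(np.sum((measured[state] - ideal) ** 2))

        res = minimize_scalar(loss, bounds=(-max_shift, max_shift),
                              method="bounded", options={"xatol": 1e-6})
        shifts[state] = res.x
    return shifts


def dh_activity_shift(z: int, ionic_strength: float, lb: float,
                      sigma: float = 1.0) -> float:
    """Debye-Hueckel prediction of the pK shift forming the |z|-valent state.

    With kappa = sqrt(8 pi lb I) (all reduced units, I the ionic strength
    as a number density) and ln gamma_z = -z^2 lb kappa / (2 (1 + kappa
    sigma)), the deprotonation step (|z|-1) -> |z| (which also releases one
    H+) shifts by  dpK = (ln g_H + ln g_z - ln g_(z-1)) / ln 10
    = -2|z| * lb kappa / (2 (1 + kappa sigma)) / ln 10.  The shift is
    negative (ionization enhanced, curves move to lower pH) and grows
    linearly with the valency of the state being formed.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    if z == 0 or ionic_strength == 0:
        return 0.0
    kappa = math.sqrt(8.0 * math.pi * lb * ionic_strength)
    f = lb * kappa / (2.0 * (1.0 + kappa * sigma))
    return -2.0 * abs(z) * f / LN10
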