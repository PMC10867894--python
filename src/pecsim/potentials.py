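"""Pair and bond potentials of the bead-spring model.

Three interactions act between particles:

* a lambda-tunable WCA / Lennard-Jones pair potential (truncated and
  shifted so that it is exactly zero at and beyond its cutoff),
* harmonic bonds between consecutive beads of a chain,
* the Coulomb potential z1*z2*l_B/r of the dielectric-continuum solvent.

The lambda form splits the Lennard-Jones curve at its minimum
r_m = 2^(1/6)*sigma: the repulsive core is kept at full strength and
raised by (1-lambda)*eps, while the attractive tail is scaled by lambda.
lambda = 0 is the purely repulsive (athermal) WCA limit; lambda = 1 is the
full Lennard-Jones well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .species import SpeciesTable

R_MIN_FACTOR = 2.0 ** (1.0 / 6.0)
#: cutoff multiple for pairs involving a polymer monomer
MONOMER_CUTOFF_FACTOR = 2.5


@dataclass(frozen=True)
class BondParams:
    """Harmonic bond, U = (K/2)(r - R0)^2, in reduced units."""

    k_bond: float
    r0: float

    def __post_init__(self) -> None:
        if self.k_bond <= 0 or self.r0 <= 0:
            raise ValueError("bond stiffness and rest length must be positive")


def default_bond_params(units=None) -> BondParams:
    """Default spring: 827 kT/nm^2 with rest length 0.426 nm, in reduced units."""
    from .units import DEFAULT_UNITS

    u = units or DEFAULT_UNITS
    return BondParams(
        k_bond=u.energy_per_nm2_to_reduced(827.0),
        r0=u.to_reduced_length(0.426),
    )


@dataclass(frozen=True)
class PairParams:
    """Effective parameters of one species pair (Lorentz-Berthelot combined)."""

    sigma: float
    lam: float
    cutoff: float
    shift: float  # constant subtracted so U(cutoff) == 0


def _lj_core(r: float, sigma: float) -> float:
    sr6 = (sigma / r) ** 6
    return 4.0 * (sr6 * sr6 - sr6)


def _wca_unshifted(r: float, sigma: float, lam: float) -> float:
    if r < R_MIN_FACTOR * sigma:
        return _lj_core(r, sigma) + (1.0 - lam)
    return lam * _lj_core(r, sigma)


def make_pair_params(sigma: float, lam: float, cutoff: float | None = None) -> PairParams:
    """Build one pair entry; the shift makes the potential continuous at the cutoff."""
    if cutoff is None:
        cutoff = R_MIN_FACTOR * sigma if lam == 0.0 else MONOMER_CUTOFF_FACTOR * sigma
    shift = _wca_unshifted(cutoff, sigma, lam)
    return PairParams(sigma=sigma, lam=lam, cutoff=cutoff, shift=shift)


def wca_energy(r: float, pair: PairParams) -> float:
    """Truncated-shifted lambda-WCA pair energy at separation ``r`` (kT)."""
    if r <= 0:
        raise ValueError("separation must be positive")
    if r >= pair.cutoff:
        return 0.0
    return _wca_unshifted(r, pair.sigma, pair.lam) - pair.shift


def bond_energy(r: float, params: BondParams) -> float:
    """Harmonic bond energy (kT); minimum exactly at the rest length."""
    if r < 0:
        raise ValueError("separation must be non-negative")
    return 0.5 * params.k_bond * (r - params.r0) ** 2


def coulomb_energy(r: float, z1: int, z2: int, lb: float) -> float:
    """Bare Coulomb pair energy z1*z2*l_B/r in kT (r and l_B reduced)."""
    if r <= 0:
        raise ValueError("Coulomb energy diverges at zero separation")
    return z1 * z2 * lb / r


class PairTable:
    """Symmetric table of :class:`PairParams` for every species pair.

    Sigma by the Lorentz-Berthelot arithmetic mean, lambda by the geometric
    mean (so any pair with an athermal partner stays purely repulsive).
    Pairs involving a monomer use the long cutoff 2.5*sigma_ij; athermal
    ion-ion pairs use the minimal repulsive cutoff 2^(1/6)*sigma_ij, which
    is the identical potential at lower cost.
    """

    def __init__(self, table: SpeciesTable):
        n = len(table)
        self.n = n
        self.sigma = np.zeros((n, n))
        self.lam = np.zeros((n, n))
        self.cutoff = np.zeros((n, n))
        self.shift = np.zeros((n, n))
        self._params: dict[tuple[int, int], PairParams] = {}
        for i in range(n):
            for j in range(i, n):
                si, sj = table[i], table[j]
                sigma = 0.5 * (si.diameter + sj.diameter)
                lam = math.sqrt(si.lam * sj.lam)
                if lam == 0.0 and not (si.is_monomer or sj.is_monomer):
                    cutoff = R_MIN_FACTOR * sigma
                else:
                    cutoff = MONOMER_CUTOFF_FACTOR * sigma
                p = make_pair_params(sigma, lam, cutoff)
                self._params[(i, j)] = p
                for a, b in ((i, j), (j, i)):
                    self.sigma[a, b] = p.sigma
                    self.lam[a, b] = p.lam
                    self.cutoff[a, b] = p.cutoff
                    self.shift[a, b] = p.shift

    def pair(self, i: int, j: int) -> PairParams:
        return self._params[(min(i, j), max(i, j))]

    @property
    def max_cutoff(self) -> float:
        return float(self.cutoff.max())


def b2_from_lambda(lam: float, sigma: float = 1.0) -> float:
    """Second virial coefficient of the truncated-shifted pair potential.

    B2 = -2 pi Int (exp(-U(r)) - 1) r^2 dr by adaptive quadrature.  For
    lambda = 0 the result is positive (athermal, close to the hard-sphere
    value 2 pi sigma^3 / 3) and it decreases monotonically as the
    attractive tail is switched on.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    pair = make_pair_params(sigma, lam, MONOMER_CUTOFF_FACTOR * sigma)

    def integrand(r: float) -> float:
        if r == 0.0:
            return 0.0
        return (math.exp(-wca_energy(r, pair)) - 1.0) * r * r

    val, err = integrate.quad(
        integrand,
        0.0,
        pair.cutoff,
        points=[R_MIN_FACTOR * sigma],
        limit=200,
    )
    if not math.isfinite(val) or err > 1e-8 * max(1.0, abs(val)):
        raise RuntimeError("B2 quadrature did not converge")
    return -2.0 * math.pi * val


def hard_sphere_b2(sigma: float = 1.0) -> float:
    """Closed-form hard-sphere second virial coefficient, 2 pi sigma^3 / 3."""
    return 2.0 * math.pi * sigma**3 / 3.0
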