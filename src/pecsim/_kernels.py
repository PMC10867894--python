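"""Numba-compiled inner loops: short-range pairs, bonds, Ewald sums.

All kernels take plain numpy arrays in reduced units.  Pair interactions use
all-pairs minimum-image loops, which at the problem sizes of this package
(N up to a few hundred) beat any neighbor-list bookkeeping.

Energy bookkeeping convention: the lambda-WCA potential is evaluated in its
truncated-shifted form (zero at and beyond the per-pair cutoff); the Coulomb
part is split Ewald-style into a screened real-space term, a reciprocal-space
term over the box's wavevectors, and the self term handled by the caller.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT_PI = math.sqrt(math.pi)
_RMIN2 = 2.0 ** (1.0 / 3.0)  # (2^(1/6))^2, squared LJ minimum in units of sigma^2


@njit(cache=True, fastmath=True)
def _pair_wca(r2, sig, lam, shift):
    """Return (energy, force_prefactor) of one truncated-shifted pair."""
    s2 = sig * sig / r2
    sr6 = s2 * s2 * s2
    sr12 = sr6 * sr6
    e_lj = 4.0 * (sr12 - sr6)
    fpref = 24.0 * (2.0 * sr12 - sr6) / r2
    if r2 < _RMIN2 * sig * sig:
        return e_lj + (1.0 - lam) - shift, fpref
    return lam * e_lj - shift, lam * fpref


@njit(cache=True, fastmath=True)
def short_range_ef(pos, spec, q, L, sigma_t, lam_t, cut_t, shift_t,
                   lb, alpha, rcoul, do_coulomb):
    """All-pairs WCA + Ewald-real energy, forces and WCA virial.

    Returns (e_wca, e_real, forces, w_wca) where w_wca = sum r.F over
    WCA pairs (the Coulomb virial is obtained from the total electrostatic
    energy by homogeneity, see the pressure module).
    """
    n = pos.shape[0]
    f = np.zeros((n, 3))
    e_wca = 0.0
    e_real = 0.0
    w_wca = 0.0
    rcoul2 = rcoul * rcoul
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        si = spec[i]
        qi = q[i]
        for j in range(i + 1, n):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            dz -= L * round(dz / L)
            r2 = dx * dx + dy * dy + dz * dz
            sj = spec[j]
            fpref = 0.0
            rc = cut_t[si, sj]
            if r2 < rc * rc:
                e, fp = _pair_wca(r2, sigma_t[si, sj], lam_t[si, sj], shift_t[si, sj])
                e_wca += e
                fpref += fp
                w_wca += fp * r2
            if do_coulomb:
                qq = qi * q[j]
                if qq != 0.0 and r2 < rcoul2:
                    r = math.sqrt(r2)
                    er = math.erfc(alpha * r)
                    u = lb * qq * er / r
                    e_real += u
                    fpref += lb * qq * (er / r + 2.0 * alpha / _SQRT_PI
                                        * math.exp(-alpha * alpha * r2)) / r2
            if fpref != 0.0:
                f[i, 0] += fpref * dx
                f[i, 1] += fpref * dy
                f[i, 2] += fpref * dz
                f[j, 0] -= fpref * dx
                f[j, 1] -= fpref * dy
                f[j, 2] -= fpref * dz
    return e_wca, e_real, f, w_wca


@njit(cache=True, fastmath=True)
def subset_energy(pos, spec, q, subset, L, sigma_t, lam_t, cut_t, shift_t,
                  lb, alpha, rcoul, do_coulomb):
    """Short-range + Ewald-real energy of `subset` particles with the rest
    of the system plus among themselves (used for Monte Carlo energy deltas)."""
    n = pos.shape[0]
    m = subset.shape[0]
    in_subset = np.zeros(n, np.uint8)
    for a in range(m):
        in_subset[subset[a]] = 1
    e = 0.0
    rcoul2 = rcoul * rcoul
    for a in range(m):
        i = subset[a]
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        si = spec[i]
        qi = q[i]
        for j in range(n):
            if j == i:
                continue
            # count subset-subset pairs once
            if in_subset[j] == 1 and j < i:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            dz -= L * round(dz / L)
            r2 = dx * dx + dy * dy + dz * dz
            sj = spec[j]
            rc = cut_t[si, sj]
            if r2 < rc * rc:
                ev, _ = _pair_wca(r2, sigma_t[si, sj], lam_t[si, sj], shift_t[si, sj])
                e += ev
            if do_coulomb:
                qq = qi * q[j]
                if qq != 0.0 and r2 < rcoul2:
                    r = math.sqrt(r2)
                    e += lb * qq * math.erfc(alpha * r) / r
    return e


@njit(cache=True, fastmath=True)
def bonds_ef(pos, bonds, L, k_bond, r0):
    """Harmonic bond energy, forces and virial over the bond list (nb x 2)."""
    nb = bonds.shape[0]
    n = pos.shape[0]
    f = np.zeros((n, 3))
    e = 0.0
    w = 0.0
    for b in range(nb):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= L * round(dx / L)
        dy -= L * round(dy / L)
        dz -= L * round(dz / L)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0
        e += 0.5 * k_bond * dr * dr
        if r > 0.0:
            fpref = -k_bond * dr / r
            f[i, 0] += fpref * dx
            f[i, 1] += fpref * dy
            f[i, 2] += fpref * dz
            f[j, 0] -= fpref * dx
            f[j, 1] -= fpref * dy
            f[j, 2] -= fpref * dz
            w += fpref * r * r
    return e, f, w


@njit(cache=True, fastmath=True)
def _phase_tables(pos, L, nmax):
    """Per-dimension complex phase factors exp(i 2 pi n x / L), n = 0..nmax."""
    n = pos.shape[0]
    tp = 2.0 * math.pi / L
    eik = np.empty((3, n, nmax + 1), np.complex128)
    for d in range(3):
        for j in range(n):
            eik[d, j, 0] = 1.0 + 0.0j
            base = complex(math.cos(tp * pos[j, d]), math.sin(tp * pos[j, d]))
            for m in range(1, nmax + 1):
                eik[d, j, m] = eik[d, j, m - 1] * base
    return eik


@njit(cache=True, fastmath=True)
def _phase(eik, j, nx, ny, nz):
    px = eik[0, j, nx] if nx >= 0 else np.conj(eik[0, j, -nx])
    py = eik[1, j, ny] if ny >= 0 else np.conj(eik[1, j, -ny])
    pz = eik[2, j, nz] if nz >= 0 else np.conj(eik[2, j, -nz])
    return px * py * pz


@njit(cache=True, fastmath=True)
def ewald_recip_ef(pos, q, L, alpha, kint, nmax, lb):
    """Reciprocal-space Ewald energy and forces (half-space k list, tinfoil)."""
    n = pos.shape[0]
    nk = kint.shape[0]
    tp = 2.0 * math.pi / L
    V = L * L * L
    eik = _phase_tables(pos, L, nmax)
    f = np.zeros((n, 3))
    energy = 0.0
    ph = np.empty(n, np.complex128)
    inv4a2 = 1.0 / (4.0 * alpha * alpha)
    for kidx in range(nk):
        nx = kint[kidx, 0]
        ny = kint[kidx, 1]
        nz = kint[kidx, 2]
        kx = tp * nx
        ky = tp * ny
        kz = tp * nz
        k2 = kx * kx + ky * ky + kz * kz
        ak = math.exp(-k2 * inv4a2) / k2
        s = 0.0 + 0.0j
        for j in range(n):
            p = _phase(eik, j, nx, ny, nz)
            ph[j] = p
            s += q[j] * p
        energy += ak * (s.real * s.real + s.imag * s.imag)
        sc = np.conj(s)
        for j in range(n):
            if q[j] == 0.0:
                continue
            im = (ph[j] * sc).imag
            c = q[j] * ak * im
            f[j, 0] += c * kx
            f[j, 1] += c * ky
            f[j, 2] += c * kz
    # half-space factor 2; energy prefactor 2 pi lb / V, force 4 pi lb / V
    e_out = energy * 4.0 * math.pi * lb / V
    pref = 8.0 * math.pi * lb / V
    for j in range(n):
        f[j, 0] *= pref
        f[j, 1] *= pref
        f[j, 2] *= pref
    return e_out, f


@njit(cache=True, fastmath=True)
def struct_factor_charge(pos, q, L, kint, nmax):
    """Charge-weighted structure amplitudes S(k) = sum_j q_j exp(i k r_j)."""
    n = pos.shape[0]
    nk = kint.shape[0]
    eik = _phase_tables(pos, L, nmax)
    s = np.zeros(nk, np.complex128)
    for kidx in range(nk):
        nx = kint[kidx, 0]
        ny = kint[kidx, 1]
        nz = kint[kidx, 2]
        acc = 0.0 + 0.0j
        for j in range(n):
            acc += q[j] * _phase(eik, j, nx, ny, nz)
        s[kidx] = acc
    return s


@njit(cache=True, fastmath=True)
def recip_energy_from_sk(sk, L, alpha, kint, lb):
    """Reciprocal energy evaluated from precomputed amplitudes."""
    nk = kint.shape[0]
    tp = 2.0 * math.pi / L
    inv4a2 = 1.0 / (4.0 * alpha * alpha)
    e = 0.0
    for kidx in range(nk):
        kx = tp * kint[kidx, 0]
        ky = tp * kint[kidx, 1]
        kz = tp * kint[kidx, 2]
        k2 = kx * kx + ky * ky + kz * kz
        ak = math.exp(-k2 * inv4a2) / k2
        e += ak * (sk[kidx].real ** 2 + sk[kidx].imag ** 2)
    return e * 4.0 * math.pi * lb / (L * L * L)
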