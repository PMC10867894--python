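"""Classic Ewald summation with conducting (tinfoil) boundary conditions.

Parameters are auto-tuned to a target relative accuracy: the splitting
parameter alpha is chosen so that the real-space tail erfc(alpha*rc)/rc is
negligible at the cutoff, and the reciprocal sum is truncated where the
Gaussian damping exp(-k^2/4 alpha^2) falls below the same margin.  The
achieved accuracy is validated against a high-resolution reference on a
two-charge probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfcinv

from ._kernels import ewald_recip_ef

_SQRT_PI = math.sqrt(math.pi)


@dataclass(frozen=True)
class EwaldParams:
    """Tuned Ewald parameters for a cubic box of edge L (reduced units)."""

    accuracy: float
    r_cut: float
    alpha: float
    n_max: int
    kvecs: np.ndarray = field(repr=False)  # (nk, 3) int half-space list

    @property
    def n_kvecs(self) -> int:
        return self.kvecs.shape[0]


def _half_space_kvecs(n_max: int, n_cut: float) -> np.ndarray:
    """Integer wavevector triples in the half-space |n| <= n_cut, k != 0."""
    out = []
    nc2 = n_cut * n_cut
    for nx in range(0, n_max + 1):
        for ny in range(-n_max, n_max + 1):
            for nz in range(-n_max, n_max + 1):
                if nx == 0 and (ny < 0 or (ny == 0 and nz <= 0)):
                    continue
                if nx * nx + ny * ny + nz * nz <= nc2:
                    out.append((nx, ny, nz))
    return np.array(out, dtype=np.int64)


def tune_ewald(L: float, accuracy: float = 1e-3, r_cut: float | None = None) -> EwaldParams:
    """Choose alpha, real-space cutoff and k-space cutoff for a target accuracy."""
    if L <= 0:
        raise ValueError("box edge must be positive")
    if not 0 < accuracy < 1:
        raise ValueError("accuracy must lie in (0, 1)")
    if r_cut is None:
        r_cut = min(0.45 * L, 5.0)
    if r_cut >= 0.5 * L:
        raise ValueError("real-space cutoff must be below L/2")
    margin = accuracy / 10.0
    alpha = float(erfcinv(margin)) / r_cut
    k_cut = 2.0 * alpha * math.sqrt(math.log(1.0 / margin))
    n_max = max(1, int(math.ceil(k_cut * L / (2.0 * math.pi))))
    kvecs = _half_space_kvecs(n_max, k_cut * L / (2.0 * math.pi))
    return EwaldParams(accuracy=accuracy, r_cut=r_cut, alpha=alpha,
                       n_max=n_max, kvecs=kvecs)


def self_energy(q: np.ndarray, alpha: float, lb: float) -> float:
    """Ewald self-interaction correction, -lb * alpha/sqrt(pi) * sum q^2."""
    return -lb * alpha / _SQRT_PI * float(np.sum(q * q))


def recip_energy_forces(pos: np.ndarray, q: np.ndarray, L: float,
                        params: EwaldParams, lb: float):
    return ewald_recip_ef(pos, q, L, params.alpha, params.kvecs, params.n_max, lb)


def two_charge_probe_error(L: float, params: EwaldParams, lb: float = 1.0) -> float:
    """Relative energy error of the tuned parameters on a +1/-1 probe pair,
    measured against a heavily over-converged Ewald reference."""
    from .forces import _ewald_total  # local import to avoid a cycle

    pos = np.array([[0.0, 0.0, 0.0], [0.3 * L, 0.1 * L, 0.05 * L]])
    q = np.array([1.0, -1.0])
    ref_params = tune_ewald(L, accuracy=1e-9, r_cut=0.49 * L)
    e = _ewald_total(pos, q, L, params, lb)
    e_ref = _ewald_total(pos, q, L, ref_params, lb)
    return abs(e - e_ref) / abs(e_ref)


def validate_accuracy(L: float, params: EwaldParams, lb: float = 1.0) -> None:
    """Raise if the standard two-charge probe misses the accuracy target."""
    err = two_charge_probe_error(L, params, lb)
    if err > params.accuracy:
        raise RuntimeError(
            f"Ewald tuning failed the two-charge probe: {err:.2e} > {params.accuracy:.2e}"
        )
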