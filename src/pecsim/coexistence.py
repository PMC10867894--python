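"""Pressure-composition protocol: locating phase coexistence.

A series of fixed-volume complex-phase runs at different monomer volume
fractions phi yields the osmotic pressure difference to the supernatant,
dP(phi).  The branch with dP >~ 0 is fitted with the phenomenological
monotone form

    dP(phi) = a0 + a1 / tan(phi - a2)

and the coexistence composition phi0 is the root dP(phi0) = 0 of the fit.
Self-consistency requires the complex at phi0 to be a homogeneous single
phase: compositions whose monomer structure factor peaks in its smallest-k
shell are flagged as demixing inside the box and invalidate the result.
Tie-line concentrations of each exchangeable species in the two phases give
partition coefficients K_i = c_i(complex)/c_i(supernatant); K > 1 means
accumulation in the complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

from .system import Model, SystemState

#: points enter the fit when dP > -FIT_INCLUSION_NSIGMA * stderr
FIT_INCLUSION_NSIGMA = 2.0


@dataclass(frozen=True)
class PressurePoint:
    """One phi-scan sample: composition, pressure mismatch, demixing flag."""

    phi_mon: float
    dp: float
    stderr: float = 0.0
    demixed: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.phi_mon < 1.0:
            raise ValueError("volume fraction must lie in (0, 1)")
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")


@dataclass
class CoexistenceResult:
    phi0: float
    phi0_err: float
    params: np.ndarray  # (a0, a1, a2)
    covariance: np.ndarray
    valid: bool
    message: str = ""
    tie_line: dict[str, dict[str, float]] = field(default_factory=dict)

    def curve(self, phi: np.ndarray) -> np.ndarray:
        return dp_model(np.asarray(phi), *self.params)


def volume_fraction(state: SystemState, model: Model, which: str) -> float:
    """Occupied-volume fraction of a particle class (Eq.-of-state input).

    ``which`` is one of ``monomers``, ``ions`` (all non-monomer particles),
    or ``water`` (the complement of the other two).
    """
    diam = np.array([s.diameter for s in model.species])
    is_mon = np.array([s.is_monomer for s in model.species])
    v = math.pi / 6.0 * diam[state.spec] ** 3
    mon = is_mon[state.spec]
    phi_mon = float(v[mon].sum()) / state.volume
    phi_ion = float(v[~mon].sum()) / state.volume
    if which == "monomers":
        return phi_mon
    if which == "ions":
        return phi_ion
    if which == "water":
        return 1.0 - phi_mon - phi_ion
    raise ValueError(f"unknown particle class {which!r}")


def dp_model(phi, a0, a1, a2):
    return a0 + a1 / np.tan(phi - a2)


def _initial_guess(phi: np.ndarray, dp: np.ndarray) -> tuple[float, float, float]:
    """Grid-scan a2 outside the data range; linear-solve a0, a1 for each."""
    best = None
    span = phi.max() - phi.min() + 1e-3
    candidates = np.concatenate([
        phi.max() + np.linspace(0.02, 5.0, 60) * span,
        phi.min() - np.linspace(0.02, 5.0, 60) * span,
    ])
    for a2 in candidates:
        x = 1.0 / np.tan(phi - a2)
        A = np.column_stack([np.ones_like(x), x])
        coef, res, *_ = np.linalg.lstsq(A, dp, rcond=None)
        ssr = float(np.sum((A @ coef - dp) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, coef[0], coef[1], a2)
    return best[1], best[2], best[3]


def fit_dp_curve(points: list[PressurePoint], rng=None,
                 n_resample: int = 400) -> CoexistenceResult:
    """Weighted fit of the dP(phi) branch and root-finding for phi0.

    Inverse-variance weights when errors are available; phi0 uncertainty by
    parametric resampling from the fit covariance.  Data without a sign
    change over the sampled range produce ``valid=False`` (single-phase
    outcome: no coexistence detected).
    """
    usable = [p for p in points
              if p.dp > -FIT_INCLUSION_NSIGMA * p.stderr]
    if len(usable) < 4:
        raise ValueError("need at least 4 points with dP >~ 0 to fit")
    order = np.argsort([p.phi_mon for p in usable])
    usable = [usable[i] for i in order]
    phi = np.array([p.phi_mon for p in usable])
    dp = np.array([p.dp for p in usable])
    err = np.array([p.stderr for p in usable])
    sigma = err if np.all(err > 0) else None

    p0 = _initial_guess(phi, dp)
    popt, pcov = curve_fit(dp_model, phi, dp, p0=p0, sigma=sigma,
                           absolute_sigma=sigma is not None, maxfev=20000)

    # Root bracketing spans the full sampled composition range (the root sits
    # generically just below the lowest point of the fitted dP >~ 0 branch),
    # but never extrapolates beyond the data.
    all_phi = [p.phi_mon for p in points]
    lo, hi = min(all_phi), max(all_phi)
    f = lambda x: dp_model(x, *popt)
    root, valid, msg = float("nan"), False, ""
    grid = np.linspace(lo, hi, 256)
    vals = f(grid)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        msg = "no coexistence detected: fitted dP does not change sign"
    else:
        i = sign_change[0]
        root = brentq(f, grid[i], grid[i + 1])
        valid = True
        nearest = min(usable, key=lambda p: abs(p.phi_mon - root))
        if nearest.demixed:
            valid = False
            msg = ("composition nearest phi0 shows in-box demixing; "
                   "coexistence estimate is not self-consistent")

    phi0_err = float("nan")
    if not math.isnan(root) and np.all(np.isfinite(pcov)):
        rng = rng or np.random.default_rng(0)
        roots = []
        try:
            draws = rng.multivariate_normal(popt, pcov, size=n_resample)
        except np.linalg.LinAlgError:
            draws = []
        for d in draws:
            g = dp_model(grid, *d)
            sc = np.nonzero(np.diff(np.sign(g)) != 0)[0]
            if len(sc):
                i = sc[0]
                try:
                    roots.append(brentq(lambda x: dp_model(x, *d),
                                        grid[i], grid[i + 1]))
                except ValueError:
                    pass
        if len(roots) > 10:
            phi0_err = float(np.std(roots))

    return CoexistenceResult(phi0=root, phi0_err=phi0_err, params=popt,
                             covariance=pcov, valid=valid, message=msg)


def demixing_flag(k: np.ndarray, s_k: np.ndarray) -> bool:
    """True iff the smallest-wavevector shell is the global maximum of S(k)."""
    k = np.asarray(k, dtype=float)
    s_k = np.asarray(s_k, dtype=float)
    if len(k) < 3 or len(k) != len(s_k):
        raise ValueError("need at least 3 structure-factor bins")
    i0 = int(np.argmin(k))
    rest = np.delete(s_k, i0)
    return bool(s_k[i0] > rest.max())


def tie_line(pec_conc: dict[str, tuple[float, float]],
             sup_conc: dict[str, tuple[float, float]]) -> dict[str, dict[str, float]]:
    """Partition coefficients K_i = c_i(pec)/c_i(sup) with propagated errors.

    Inputs map species name -> (mean concentration, stderr); any unit works
    as long as it is shared.  K > 1 means accumulation in the complex.
    """
    out: dict[str, dict[str, float]] = {}
    for name, (cp, ep) in pec_conc.items():
        if name not in sup_conc:
            continue
        cs, es = sup_conc[name]
        if cs == 0:
            raise ZeroDivisionError(
                f"supernatant concentration of {name} is zero; K undefined")
        k = cp / cs
        err = abs(k) * math.sqrt((ep / cp) ** 2 + (es / cs) ** 2) if cp != 0 else \
            abs(ep / cs)
        out[name] = {"c_sup": cs, "c_pec": cp, "K": k, "K_err": err}
    return out


def experimental_partition(m_pec: float, m_sup: float,
                           c_sup_normalized: float) -> float:
    """Gravimetric partition-coefficient estimator.

    ``c_sup_normalized`` is the supernatant concentration of the tracked
    solute divided by a polyelectrolyte-free control prepared at the same
    total composition (so 1.0 means no uptake by the complex).  Mass
    balance with the documented equal-density assumption (hydrated complex
    about as dense as water) gives

        K = (m_sup (1 - c) + m_pec) / (c * m_pec).
    """
    if not 0 < c_sup_normalized <= 1:
        raise ValueError("normalized supernatant concentration must be in (0, 1]")
    if m_pec <= 0 or m_sup <= 0:
        raise ValueError("masses must be positive")
    c = c_sup_normalized
    return (m_sup * (1.0 - c) + m_pec) / (c * m_pec)
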