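"""Programmatic generation of small test inputs.

Everything here is synthetic and generated at run time: small neutral
chains and complex boxes for engine tests, ideal-gas reservoir
configurations, pressure-mismatch tables drawn from a known
phenomenological curve, and constructed structure-factor curves for the
demixing classifier.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .coexistence import dp_model
from .grxmc import ReservoirSpec, constants_from_reservoir
from .system import Model, SystemState, maxwell_velocities


def single_chain(model: Model, n_beads: int = 32, rng=None,
                 L: float | None = None, charged: bool = False) -> SystemState:
    """One chain along z in a periodic box (neutral A-/C+ alternating if
    ``charged``; otherwise all beads are polyanion species with
    electrostatics expected off)."""
    rng = rng or np.random.default_rng(0)
    b = model.bond.r0
    if L is None:
        L = max(4.0 * n_beads * b, 20.0)
    i_a = model.species.index("A-")
    i_c = model.species.index("C+")
    pos = np.zeros((n_beads, 3))
    pos[:, 2] = np.arange(n_beads) * b
    pos += L / 2.0
    spec = np.full(n_beads, i_a, dtype=np.int64)
    if charged:
        spec[1::2] = i_c
    chains = [np.arange(n_beads, dtype=np.int64)]
    return SystemState(L=L, pos=pos, vel=maxwell_velocities(n_beads, rng),
                       spec=spec, chains=chains, lb=2.5, rng=rng)


def small_pec_box(model: Model, n_chains_per_species: int = 4,
                  chain_length: int = 8, target_phi: float = 0.12,
                  rng=None, relax_steps: int = 200, lb: float = 2.5,
                  **kwargs) -> SystemState:
    """Scaled-down complex box (<= 8 chains x 8 beads by default)."""
    from .builder import build_initial_pec

    rng = rng or np.random.default_rng(0)
    return build_initial_pec(model, n_chains_per_species=n_chains_per_species,
                             chain_length=chain_length, target_phi=target_phi,
                             lb=lb, rng=rng, relax_steps=relax_steps,
                             thermalize_steps=relax_steps, **kwargs)


def ideal_reservoir(pH: float = 7.0, c_salt_M: float = 0.15, **kwargs):
    """(ReservoirSpec, reactions) for an ideal-gas reservoir at given targets."""
    spec = ReservoirSpec(pH=pH, c_salt_M=c_salt_M, **kwargs)
    return spec, constants_from_reservoir(spec)


def synthetic_dp_table(a0: float = -0.05, a1: float = -8.0e-3,
                       a2: float = 0.32, phi_lo: float = 0.08,
                       phi_hi: float = 0.25, n_points: int = 8,
                       noise: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Pressure-mismatch samples from a known curve, optional Gaussian noise.

    The default parameters produce an increasing dP(phi) whose root
    phi0 ~ 0.161 lies inside the sampled range, mimicking a
    compressed-complex scan.
    """
    rng = np.random.default_rng(seed)
    phi = np.linspace(phi_lo, phi_hi, n_points)
    dp = dp_model(phi, a0, a1, a2)
    err = np.full_like(phi, max(noise, 2e-3))
    if noise > 0:
        dp = dp + rng.normal(0.0, noise, size=len(phi))
    return pd.DataFrame({"phi": phi, "dP": dp, "stderr": err,
                         "demixed": np.zeros(len(phi), dtype=bool)})


def synthetic_sk_curves(n_bins: int = 12, L: float = 10.0):
    """Three constructed S(k) curves: flat, demixing rise, mid-k peak."""
    k = 2.0 * math.pi / L * np.arange(1, n_bins + 1)
    flat = np.ones(n_bins)
    demix = 1.0 + 4.0 * np.exp(-k / k[1])  # monotone rise toward k -> 0
    midpeak = 1.0 + 2.0 * np.exp(-((k - k[n_bins // 2]) ** 2) / (2 * k[0] ** 2))
    return k, {"flat": flat, "demixing": demix, "correlation_peak": midpeak}


def write_fixture_files(outdir: str | Path, seed: int = 0) -> list[Path]:
    """Materialize the file-based fixtures (TSV) used by the CLI tests."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    dp = synthetic_dp_table(seed=seed)
    p = out / "synthetic_dp.tsv"
    dp.to_csv(p, sep="\t", index=False)
    written.append(p)

    dp_noisy = synthetic_dp_table(noise=2e-3, seed=seed)
    p = out / "synthetic_dp_noisy.tsv"
    dp_noisy.to_csv(p, sep="\t", index=False)
    written.append(p)

    k, curves = synthetic_sk_curves()
    for name, s in curves.items():
        p = out / f"sk_{name}.tsv"
        pd.DataFrame({"k": k, "S": s}).to_csv(p, sep="\t", index=False)
        written.append(p)
    return written
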