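"""Langevin dynamics at kT = 1 via the BAOAB splitting.

The stochastic equation of motion m dv = F dt - gamma m v dt + random-force
is integrated with the BAOAB scheme, which samples the canonical
configurational distribution with high accuracy at dt = 0.01 tau.  In the
limit gamma -> 0 with the noise switched off, the scheme reduces exactly to
velocity Verlet, which the integrator-order tests rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ewald import EwaldParams
from .forces import compute_energy_forces, get_ewald
from .system import Model, SystemState


@dataclass
class LangevinParams:
    gamma: float = 1.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.dt <= 0:
            raise ValueError("gamma must be >= 0 and dt > 0")


class LangevinIntegrator:
    """Stateful integrator bound to one system and model (m = 1, kT = 1)."""

    def __init__(self, state: SystemState, model: Model,
                 params: LangevinParams | None = None,
                 ewald: EwaldParams | None = None):
        self.state = state
        self.model = model
        self.params = params or LangevinParams()
        self._ewald = ewald
        self._refresh_forces()

    @property
    def ewald(self) -> EwaldParams | None:
        if self._ewald is None and self.model.electrostatics and self.model.interactions:
            self._ewald = get_ewald(self.state, self.model)
        return self._ewald

    def invalidate(self, box_changed: bool = False) -> None:
        """Call after external changes to particle count or box size."""
        if box_changed:
            self._ewald = None
        self._refresh_forces()

    def _refresh_forces(self) -> None:
        try:
            eb = compute_energy_forces(self.state, self.model, self.ewald)
        except ZeroDivisionError:
            raise FloatingPointError(
                f"force overflow: coincident particle pair {self._closest_pair()}"
            ) from None
        if not np.all(np.isfinite(eb.forces)):
            bad = int(np.argmax(~np.isfinite(eb.forces).all(axis=1)))
            raise FloatingPointError(
                f"non-finite force on particle {bad}; "
                f"closest pair {self._closest_pair()}")
        self.forces = eb.forces
        self.energy = eb

    def _closest_pair(self) -> tuple[int, int]:
        pos, L = self.state.pos, self.state.L
        d = pos[:, None, :] - pos[None, :, :]
        d -= L * np.round(d / L)
        r2 = np.sum(d * d, axis=-1)
        np.fill_diagonal(r2, np.inf)
        i, j = np.unravel_index(int(np.argmin(r2)), r2.shape)
        return int(i), int(j)

    def step(self, n_steps: int = 1) -> None:
        s, p = self.state, self.params
        dt = p.dt
        c1 = math.exp(-p.gamma * dt)
        c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
        for _ in range(n_steps):
            s.vel += 0.5 * dt * self.forces
            s.pos += 0.5 * dt * s.vel
            if c2 > 0.0:
                s.vel *= c1
                s.vel += c2 * s.rng.standard_normal(s.vel.shape)
            elif c1 != 1.0:
                s.vel *= c1
            s.pos += 0.5 * dt * s.vel
            self._refresh_forces()
            s.vel += 0.5 * dt * self.forces

    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.state.vel**2))

    def kinetic_temperature(self) -> float:
        return 2.0 * self.kinetic_energy() / (3.0 * self.state.n)
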