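"""Run driver: Langevin dynamics interleaved with reaction Monte Carlo.

A production run is a sequence of cycles; each cycle propagates the
dynamics for a fixed number of steps, optionally performs a block of
reaction trial moves, and records observables (species counts, energies,
pressure, frames).  Block averages over the recorded series provide means
with autocorrelation-respecting error bars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forces import pressure_from_breakdown
from .grxmc import ReactionSampler, ReactionSpec
from .langevin import LangevinIntegrator, LangevinParams
from .system import Model, SystemState


@dataclass
class RunResult:
    """Time series and frames collected over a run."""

    table: pd.DataFrame  # one row per cycle: counts, energy terms, pressure
    frames: list[np.ndarray] = field(default_factory=list)
    frame_times: list[float] = field(default_factory=list)
    acceptance_rate: float = float("nan")

    def mean_concentration(self, model: Model, state: SystemState,
                           name: str, discard: float = 0.0):
        """(mean, stderr) concentration of a species in mol/L (block averaged)."""
        series = self.table[f"N_{name}"].to_numpy(dtype=float)
        series = series[int(discard * len(series)):]
        to_molar = model.units.reduced_density_to_molar(1.0 / state.volume)
        m, se = block_stats(series)
        return m * to_molar, se * to_molar

    def mean_pressure(self, discard: float = 0.0):
        series = self.table["pressure"].to_numpy(dtype=float)
        series = series[int(discard * len(series)):]
        return block_stats(series)


def block_stats(series: np.ndarray, n_blocks: int = 5) -> tuple[float, float]:
    """Mean and standard error from block averages (5 blocks by default)."""
    series = np.asarray(series, dtype=float)
    if len(series) == 0:
        return float("nan"), float("nan")
    if len(series) < n_blocks:
        return float(series.mean()), float(series.std(ddof=1) / np.sqrt(len(series))
                                           if len(series) > 1 else np.nan)
    usable = (len(series) // n_blocks) * n_blocks
    blocks = series[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(blocks.mean()), float(blocks.std(ddof=1) / np.sqrt(n_blocks))


def run_phase(state: SystemState, model: Model,
              reactions: list[ReactionSpec] | None = None,
              ld: LangevinParams | None = None,
              n_cycles: int = 100,
              steps_per_cycle: int = 100,
              mc_attempts_per_cycle: int = 50,
              equil_cycles: int = 0,
              collect_frames: bool = False,
              frame_every: int = 1,
              measure_pressure: bool = True) -> RunResult:
    """Propagate one phase; mutates ``state`` and returns recorded series.

    Cycles with index < ``equil_cycles`` are run but not recorded.
    """
    ld = ld or LangevinParams()
    integ = LangevinIntegrator(state, model, ld)
    sampler = ReactionSampler(model, reactions, ewald=integ.ewald) if reactions else None

    rows = []
    frames: list[np.ndarray] = []
    frame_times: list[float] = []
    n_species = len(model.species)
    names = model.species.names()
    for cycle in range(equil_cycles + n_cycles):
        if steps_per_cycle:
            integ.step(steps_per_cycle)
        if sampler is not None and mc_attempts_per_cycle:
            sampler.run_block(state, mc_attempts_per_cycle)
            integ.invalidate()
        if cycle < equil_cycles:
            continue
        counts = np.bincount(state.spec, minlength=n_species)
        row = {f"N_{names[i]}": counts[i] for i in range(n_species)}
        row["time"] = (cycle + 1) * steps_per_cycle * ld.dt
        row["E_total"] = integ.energy.total
        row["E_bonded"] = integ.energy.bonded
        row["E_short_range"] = integ.energy.short_range
        row["E_electrostatic"] = integ.energy.electrostatic
        if measure_pressure:
            if model.interactions:
                row["pressure"] = pressure_from_breakdown(integ.energy, state)
            else:
                row["pressure"] = state.n / state.volume
        rows.append(row)
        if collect_frames and (cycle - equil_cycles) % frame_every == 0:
            frames.append(state.pos.copy())
            frame_times.append(row["time"])

    acc = sampler.acceptance_rate if sampler is not None else float("nan")
    return RunResult(table=pd.DataFrame(rows), frames=frames,
                     frame_times=frame_times, acceptance_rate=acc)
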