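"""Plain-text artifacts: XYZ trajectories, TSV series, JSON summaries,
checkpoints, and run manifests."""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .system import Model, SystemState


def write_xyz_frame(fh, state: SystemState, model: Model, comment: str = "") -> None:
    names = model.species.names()
    pos = state.wrapped_positions()
    fh.write(f"{state.n}\n{comment}\n")
    for i in range(state.n):
        x, y, z = pos[i]
        fh.write(f"{names[state.spec[i]]} {x:.6f} {y:.6f} {z:.6f}\n")


def write_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_checkpoint(path: str | Path, state: SystemState) -> None:
    """Full text checkpoint including the RNG state."""
    payload = {
        "L": state.L,
        "lb": state.lb,
        "pos": state.pos.tolist(),
        "vel": state.vel.tolist(),
        "spec": state.spec.tolist(),
        "chains": [c.tolist() for c in state.chains],
        "rng_state": _encode_rng(state.rng),
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> SystemState:
    payload = json.loads(Path(path).read_text())
    rng = np.random.default_rng()
    rng.bit_generator.state = json.loads(payload["rng_state"])
    return SystemState(
        L=payload["L"],
        pos=np.array(payload["pos"], dtype=float),
        vel=np.array(payload["vel"], dtype=float),
        spec=np.array(payload["spec"], dtype=np.int64),
        chains=[np.array(c, dtype=np.int64) for c in payload["chains"]],
        lb=payload["lb"],
        rng=rng,
    )


def _encode_rng(rng: np.random.Generator) -> str:
    return json.dumps(rng.bit_generator.state)


def write_manifest(path: str | Path, config_text: str, seed: int,
                   extra: dict | None = None) -> None:
    """Reproducibility manifest: config hash, seed, interpreter/library versions."""
    import numba
    import scipy

    manifest = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": seed,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "numba": numba.__version__,
        "pecsim": _version(),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def _version() -> str:
    from . import __version__

    return __version__
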