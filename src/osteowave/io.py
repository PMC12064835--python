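"""File dialects for simulation states and JSON reports."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .model import FieldState

__all__ = [
    "write_states_csv",
    "read_states_csv",
    "write_json_report",
    "file_digest",
]

STATE_COLUMNS = ["x_um", "rho_m", "rho_o", "k_per_h", "col", "pg_kpa", "v_um_per_h", "phi"]


def write_states_csv(states: Sequence[FieldState], out_dir: str | Path,
                     prefix: str = "state") -> list[Path]:
    """One CSV per saved state: x_um, rho_m, rho_o, ..., v_um_per_h, phi."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, s in enumerate(states):
        df = pd.DataFrame(
            {
                "x_um": s.x,
                "rho_m": s.rho_m,
                "rho_o": s.rho_o,
                "k_per_h": s.k,
                "col": s.col,
                "pg_kpa": s.pg,
                "v_um_per_h": s.v,
                "phi": s.phi,
            }
        )
        path = out_dir / f"{prefix}_{i:04d}_t{s.t:08.3f}h.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        paths.append(path)
    return paths


def read_states_csv(paths: Sequence[str | Path]) -> list[FieldState]:
    """Rebuild FieldStates from the CSV dialect (time parsed from filenames)."""
    states = []
    for path in sorted(Path(p) for p in paths):
        df = pd.read_csv(path)
        stem = path.stem
        t = float(stem.split("_t")[-1].rstrip("h"))
        states.append(
            FieldState(
                x=df["x_um"].to_numpy(),
                rho_m=df["rho_m"].to_numpy(),
                rho_o=df["rho_o"].to_numpy(),
                k=df["k_per_h"].to_numpy(),
                col=df["col"].to_numpy(),
                pg=df["pg_kpa"].to_numpy(),
                v=df["v_um_per_h"].to_numpy(),
                t=t,
            )
        )
    return states


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, slice):
        return [obj.start, obj.stop, obj.step]
    return obj


def write_json_report(report: Any, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file's bytes."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
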