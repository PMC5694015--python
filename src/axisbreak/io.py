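"""File I/O: trajectory CSV export, report JSON, and run manifests.

Formats are deliberately plain: long-format CSV for bulk numbers (one row
per cell per snapshot), JSON for configuration and reports.  Reruns with
identical inputs and seeds reproduce identical bytes; the manifest records
content hashes so that can be checked.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParameters
from .simulate import TrajectoryRecord
from .state import EmbryoState

__all__ = [
    "trajectory_frame", "write_trajectory", "read_trajectory",
    "write_report", "write_outputs", "file_sha256",
]

CSV_COLUMNS = ["time", "cell_index", "B", "V", "FB", "FV"]


def trajectory_frame(record: TrajectoryRecord) -> pd.DataFrame:
    """Long-format DataFrame: columns time, cell_index, B, V, FB, FV."""
    chunks = []
    for t, s in zip(record.times, record.snapshots):
        chunks.append(pd.DataFrame({
            "time": t, "cell_index": np.arange(s.n_cells),
            "B": s.B, "V": s.V, "FB": s.FB, "FV": s.FV,
        }))
    return pd.concat(chunks, ignore_index=True)


def write_trajectory(record: TrajectoryRecord, path: str | Path) -> Path:
    """Write the trajectory CSV plus a JSON sidecar with run metadata."""
    path = Path(path)
    frame = trajectory_frame(record)
    frame.to_csv(path, index=False, float_format="%.12g")
    sidecar = path.with_suffix(".meta.json")
    meta = {
        "params": record.params.to_dict(),
        "seed": record.seed,
        "events": [p.to_dict() for p in record.events],
        "converged": bool(record.converged),
        "final_residual": (float(record.final_residual)
                           if np.isfinite(record.final_residual) else None),
        "cuts": list(record.final.cuts),
        "n_snapshots": len(record.times),
    }
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_trajectory(path: str | Path) -> tuple[pd.DataFrame, dict | None]:
    """Read a trajectory CSV (and its sidecar if present)."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing trajectory columns {sorted(missing)}")
    sidecar = path.with_suffix(".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return frame, meta


def final_state_from_frame(frame: pd.DataFrame, cuts: tuple[int, ...] = ()) -> EmbryoState:
    """Rebuild the last snapshot of a trajectory CSV as an EmbryoState."""
    t_last = frame["time"].max()
    last = frame[frame["time"] == t_last].sort_values("cell_index")
    return EmbryoState(last["B"].to_numpy(), last["V"].to_numpy(),
                       last["FB"].to_numpy(), last["FV"].to_numpy(),
                       cuts=cuts, time=float(t_last))


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_outputs(out_dir: str | Path,
                  record: TrajectoryRecord | None = None,
                  report: dict | None = None) -> dict:
    """Write whatever artifacts were produced and a manifest of their hashes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    if record is not None:
        p = write_trajectory(record, out_dir / "trajectory.csv")
        files += [p, p.with_suffix(".meta.json")]
    if report is not None:
        files.append(write_report(report, out_dir / "report.json"))
    manifest = {"files": {f.name: file_sha256(f) for f in files}}
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
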