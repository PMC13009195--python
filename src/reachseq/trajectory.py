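"""Fingertip trajectories sampled at a fixed rate, plus tabular I/O.

A trajectory is one trial's 2D fingertip path at 100 Hz.  On disk a batch of
trials is a TSV with columns ``trial, t_s, x_mm, y_mm`` plus a JSON sidecar
carrying identity and provenance (sequence id, model tag, parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "write_trials", "read_trials"]


@dataclass
class Trajectory:
    times: np.ndarray
    positions: np.ndarray
    trial: int = 0
    sequence_id: str = ""
    tag: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if self.times.shape[0] != self.positions.shape[0]:
            raise ValueError("times and positions length mismatch")
        if self.times.shape[0] < 3:
            raise ValueError("a trajectory needs at least 3 samples")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.positions))):
            raise ValueError("non-finite values in trajectory")
        dts = np.diff(self.times)
        if dts.size and not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trajectory sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_samples(self) -> int:
        return int(self.times.shape[0])

    def speed(self) -> np.ndarray:
        """Per-sample speed magnitude (mm/s) from central differences."""
        vx = np.gradient(self.positions[:, 0], self.times)
        vy = np.gradient(self.positions[:, 1], self.times)
        return np.hypot(vx, vy)

    def path_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.positions, axis=0), axis=1)))

    def mean_speed(self) -> float:
        """Path length divided by duration (mm/s)."""
        return self.path_length() / (self.times[-1] - self.times[0])

    def peak_speed(self) -> float:
        return float(np.max(self.speed()))


def write_trials(path: str | Path, trials: list[Trajectory], meta: dict | None = None) -> None:
    """Write trials to ``path`` (TSV) with a ``.json`` sidecar."""
    path = Path(path)
    frames = []
    for tr in trials:
        frames.append(
            pd.DataFrame(
                {
                    "trial": tr.trial,
                    "t_s": tr.times,
                    "x_mm": tr.positions[:, 0],
                    "y_mm": tr.positions[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    sidecar = dict(meta or {})
    if trials:
        sidecar.setdefault("sequence_id", trials[0].sequence_id)
        sidecar.setdefault("tag", trials[0].tag)
    sidecar["n_trials"] = len(trials)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_trials(path: str | Path) -> tuple[list[Trajectory], dict]:
    """Read a TSV trial table and its JSON sidecar back into trajectories."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata file: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas gives the detail
        raise ValueError(f"malformed trial table {path}: {exc}") from exc
    required = {"trial", "t_s", "x_mm", "y_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    trials = []
    for trial_id, g in df.groupby("trial", sort=True):
        trials.append(
            Trajectory(
                times=g["t_s"].to_numpy(),
                positions=g[["x_mm", "y_mm"]].to_numpy(),
                trial=int(trial_id),
                sequence_id=str(meta.get("sequence_id", "")),
                tag=str(meta.get("tag", "")),
            )
        )
    return trials, meta
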