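"""Canonical task layout and synthetic-participant generation.

The packaged layout fixes start and target coordinates once (the study's
published sizes and distances constrain but do not pin them); every sequence
is start -> primary -> secondary -> start.  Synthetic participants are
generated by either planning model with known ground-truth labels, making the
whole kinematics -> stats -> classify pipeline testable without recorded
data.

Accepted trials must fall inside the task's speed window.  The per-trial
speed statistic used for the 600-900 mm/s window is the trial's *peak* speed
(see docs/methods.md for why): trials outside the window are rejected and
resampled, as are hierarchical trials whose sequencing layer never reached
the final attractor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import SequenceGeometry, Target
from .hiseq import build_hiseq_plan, make_shc_connectivity, simulate_hiseq
from .plant import PlantParams
from .trajectory import Trajectory, read_trials, write_trials
from .vpsoc import plan_sequence, simulate_vpsoc

__all__ = [
    "TaskLayout",
    "SyntheticParticipant",
    "Dataset",
    "SPEED_WINDOW",
    "MAX_REJECTIONS",
    "default_layout",
    "recovery_cohort",
    "generate_participant",
    "generate_cohort",
    "write_dataset",
    "read_dataset",
]

#: accepted range for the per-trial peak speed (mm/s)
SPEED_WINDOW = (600.0, 900.0)
#: consecutive rejected trials in one cell before giving up
MAX_REJECTIONS = 100


@dataclass(frozen=True)
class TaskLayout:
    """Start circle, named target circles, and the six sequence orders."""

    start: tuple[float, float]
    start_radius: float
    targets: dict[str, Target]
    sequences: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        for seq in self.sequences:
            unknown = [lab for lab in seq if lab not in self.targets]
            if unknown:
                raise ValueError(f"sequence uses unknown target labels: {unknown}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def home_target(self) -> Target:
        return Target(self.start, self.start_radius, "home")

    def sequence_geometry(self, sequence_id: int) -> SequenceGeometry:
        """Three-target geometry for a sequence id: primary, secondary, home."""
        if not (0 <= sequence_id < self.n_sequences):
            raise ValueError(f"sequence_id must be in [0, {self.n_sequences})")
        labels = self.sequences[sequence_id]
        targets = tuple(self.targets[lab] for lab in labels) + (self.home_target(),)
        return SequenceGeometry(
            start=self.start, targets=targets, sequence_id=str(sequence_id)
        )

    def to_dict(self) -> dict:
        return {
            "version": 1,
            "units": "mm",
            "start": list(self.start),
            "start_radius": self.start_radius,
            "targets": {
                lab: {"center": list(t.center), "radius": t.radius}
                for lab, t in self.targets.items()
            },
            "sequences": [list(s) for s in self.sequences],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskLayout":
        try:
            targets = {
                lab: Target(tuple(spec["center"]), float(spec["radius"]), lab)
                for lab, spec in d["targets"].items()
            }
            return cls(
                start=tuple(d["start"]),
                start_radius=float(d["start_radius"]),
                targets=targets,
                sequences=tuple(tuple(s) for s in d["sequences"]),
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed layout: missing or bad field {exc}") from exc


def default_layout() -> TaskLayout:
    """The packaged canonical layout (fixed coordinates, six sequences)."""
    text = resources.files("reachseq").joinpath("data/layout.json").read_text()
    return TaskLayout.from_dict(json.loads(text))


@dataclass(frozen=True)
class SyntheticParticipant:
    """Recipe for one synthetic participant.

    ``models`` maps sequence id -> (model name, parameter dict); model names
    are ``"vpsoc3"`` (flat three-target plan) and ``"hiseq"`` (hierarchical).
    Parameter dicts may carry ``h`` (per-target position-cost weights),
    ``r`` (control-cost weight), and for hiseq any of ``tau``, ``rho_next``,
    ``rho_other``, ``monitor_sd``, ``monitor_distance``.
    """

    participant_id: str
    models: dict[int, tuple[str, dict]]
    seed: int
    n_trials: int = 20

    def __post_init__(self) -> None:
        for sid, (model, params) in self.models.items():
            if model not in ("vpsoc3", "hiseq"):
                raise ValueError(f"unknown model '{model}' for sequence {sid}")
            if not isinstance(params, dict):
                raise ValueError("model parameters must be a dict")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class Dataset:
    """Trajectories plus ground-truth labels for a synthetic cohort.

    ``trials`` maps (participant_id, sequence_id) -> list of trajectories;
    ``truth`` has one row per cell (participant, sequence, model, params,
    seed, resampled count).
    """

    layout: TaskLayout
    trials: dict[tuple[str, int], list[Trajectory]]
    truth: pd.DataFrame


_SHC_KEYS = ("tau", "rho_next", "rho_other")
_MONITOR_KEYS = ("monitor_sd", "monitor_distance", "eta_base", "pulse_cutoff")


def _simulate_cell(
    model: str,
    mparams: dict,
    geometry: SequenceGeometry,
    plant: PlantParams,
    n: int,
    seed: int,
) -> list[Trajectory]:
    h = tuple(mparams.get("h", (1.0, 1.0, 1.0)))
    r = float(mparams.get("r", 1e-6))
    if model == "vpsoc3":
        matrices, _, solution = plan_sequence(geometry, plant, h=h, r=r)
        return simulate_vpsoc(
            solution, matrices, geometry, plant, n_trials=n, seed=seed, tag="vpsoc3"
        )
    plan = build_hiseq_plan(geometry, plant, h=h, r=r)
    shc_kwargs = {k: mparams[k] for k in _SHC_KEYS if k in mparams}
    extra = {k: mparams[k] for k in _MONITOR_KEYS if k in mparams}
    shc = make_shc_connectivity(len(plan.attractor_map), **shc_kwargs, **extra)
    return simulate_hiseq(plan, shc, plant, n_trials=n, seed=seed, tag="hiseq")


def _trial_ok(traj: Trajectory) -> bool:
    if traj.meta.get("stuck"):
        return False
    return SPEED_WINDOW[0] <= traj.peak_speed() <= SPEED_WINDOW[1]


#: interior nodes of the packaged vpSOC(3) grid used for the recovery
#: cohort's flat-planner participants (r, h1, h2)
_RECOVERY_VPSOC_NODES = (
    (2.5119e-7, 2.2210, 2.0),
    (1.2589e-6, 3.0866, 2.0),
    (6.3096e-6, 4.2895, 2.0),
    (2.5119e-7, 5.9612, 2.0),
    (1.2589e-6, 8.2845, 2.0),
    (6.3096e-6, 2.6183, 2.0),
    (2.5119e-7, 3.0866, 4.0),
    (1.2589e-6, 4.2895, 1.0),
    (6.3096e-6, 5.9612, 4.0),
    (1.2589e-6, 2.6183, 2.0),
)

#: decoupled-regime nodes of the packaged HiSeq grid (r, h1, h2): lax control
#: cost with a dominant first-target weight, where hc1 is strongly negative
#: while second-target curvature stays high
_RECOVERY_HISEQ_NODES = (
    (1.7e-4, 25.7114, 4.2602),
    (1.7e-4, 48.0, 4.2602),
)


def recovery_cohort(
    seed: int,
    n_participants: int = 20,
    n_trials: int = 20,
    sequences: tuple[int, ...] = (0,),
) -> list[SyntheticParticipant]:
    """Specs for the classifier-recovery cohort.

    Half the participants reach with vpSOC(3) at interior nodes of its
    packaged grid, half with HiSeq at its decoupled-regime nodes, so that
    classification against the packaged coverage regions has a known answer.
    Per-participant seeds are derived from ``seed``.
    """
    if n_participants < 2 or n_participants % 2:
        raise ValueError("n_participants must be a positive even number")
    specs = []
    for p in range(n_participants):
        if p % 2 == 0:
            model = "vpsoc3"
            r, h1, h2 = _RECOVERY_VPSOC_NODES[(p // 2) % len(_RECOVERY_VPSOC_NODES)]
        else:
            model = "hiseq"
            r, h1, h2 = _RECOVERY_HISEQ_NODES[(p // 2) % len(_RECOVERY_HISEQ_NODES)]
        params = {"h": (h1, h2, h2), "r": r}
        specs.append(
            SyntheticParticipant(
                participant_id=f"p{p:02d}",
                models={sid: (model, params) for sid in sequences},
                seed=seed + p,
                n_trials=n_trials,
            )
        )
    return specs


def generate_participant(
    layout: TaskLayout,
    spec: SyntheticParticipant,
    plant: PlantParams | None = None,
) -> Dataset:
    """Simulate all of one participant's sequences with rejection resampling.

    Each (participant, sequence) cell draws batches of trials until
    ``spec.n_trials`` pass the acceptance check (peak speed in
    ``SPEED_WINDOW``, sequencing completed); more than ``MAX_REJECTIONS``
    consecutive rejections aborts with a parameterization error.  The same
    spec and seed always produce the identical dataset.
    """
    if plant is None:
        plant = PlantParams(add_noise=8000.0)
    master = np.random.default_rng(spec.seed)
    trials: dict[tuple[str, int], list[Trajectory]] = {}
    truth_rows = []
    for sid in sorted(spec.models):
        model, mparams = spec.models[sid]
        geometry = layout.sequence_geometry(sid)
        accepted: list[Trajectory] = []
        consecutive_rejects = 0
        total_rejects = 0
        while len(accepted) < spec.n_trials:
            need = spec.n_trials - len(accepted)
            batch_seed = int(master.integers(2**63))
            batch = _simulate_cell(model, mparams, geometry, plant, need, batch_seed)
            for tr in batch:
                if _trial_ok(tr):
                    accepted.append(tr)
                    consecutive_rejects = 0
                else:
                    consecutive_rejects += 1
                    total_rejects += 1
                    if consecutive_rejects > MAX_REJECTIONS:
                        raise RuntimeError(
                            f"cell ({spec.participant_id}, seq {sid}): more than "
                            f"{MAX_REJECTIONS} consecutive rejected trials; the "
                            f"{model} parameters {mparams} are incompatible with "
                            f"the {SPEED_WINDOW} mm/s speed window"
                        )
        for i, tr in enumerate(accepted):
            tr.trial = i
            tr.sequence_id = str(sid)
        trials[(spec.participant_id, sid)] = accepted
        truth_rows.append(
            {
                "participant": spec.participant_id,
                "sequence": sid,
                "model": model,
                "params": json.dumps(mparams, sort_keys=True),
                "seed": spec.seed,
                "n_resampled": total_rejects,
            }
        )
    return Dataset(layout=layout, trials=trials, truth=pd.DataFrame(truth_rows))


def generate_cohort(
    specs: list[SyntheticParticipant],
    layout: TaskLayout | None = None,
    plant: PlantParams | None = None,
) -> Dataset:
    """Generate and merge several participants into one dataset."""
    if layout is None:
        layout = default_layout()
    trials: dict[tuple[str, int], list[Trajectory]] = {}
    frames = []
    seen = set()
    for spec in specs:
        if spec.participant_id in seen:
            raise ValueError(f"duplicate participant id '{spec.participant_id}'")
        seen.add(spec.participant_id)
        ds = generate_participant(layout, spec, plant=plant)
        trials.update(ds.trials)
        frames.append(ds.truth)
    return Dataset(layout=layout, trials=trials, truth=pd.concat(frames, ignore_index=True))


def write_dataset(path: str | Path, dataset: Dataset) -> None:
    """Write a dataset directory: per-cell TSVs, truth table, layout, manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = []
    truth = dataset.truth.set_index(["participant", "sequence"])
    for (pid, sid), cell_trials in sorted(dataset.trials.items()):
        stem = f"{pid}_seq{sid}"
        row = truth.loc[(pid, sid)]
        write_trials(
            path / f"{stem}.tsv",
            cell_trials,
            meta={
                "participant": pid,
                "sequence_id": str(sid),
                "model": row["model"],
                "params": json.loads(row["params"]),
                "seed": int(row["seed"]),
                "n_resampled": int(row["n_resampled"]),
            },
        )
        files.append(f"{stem}.tsv")
    dataset.truth.to_csv(path / "truth.tsv", sep="\t", index=False)
    (path / "layout.json").write_text(json.dumps(dataset.layout.to_dict(), indent=2))
    manifest = {
        "format": "reachseq-dataset",
        "version": 1,
        "files": files,
        "truth": "truth.tsv",
        "layout": "layout.json",
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"not a dataset directory (no manifest): {path}")
    manifest = json.loads(manifest_path.read_text())
    layout = TaskLayout.from_dict(json.loads((path / manifest["layout"]).read_text()))
    truth = pd.read_csv(path / manifest["truth"], sep="\t")
    trials: dict[tuple[str, int], list[Trajectory]] = {}
    for fname in manifest["files"]:
        cell_trials, meta = read_trials(path / fname)
        pid = str(meta["participant"])
        sid = int(meta["sequence_id"])
        for tr in cell_trials:
            tr.meta.update(model=meta.get("model"), participant=pid)
        trials[(pid, sid)] = cell_trials
    return Dataset(layout=layout, trials=trials, truth=truth)
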