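"""Reading, writing and validating two-instrument trajectory logs.

A trajectory is the engine's substitute for the live optical-tracker stream:
one sample per row with a timestamp, the 3D tip position of each instrument
in mm, the jaw state, and the diathermy-pedal state.  Two dialects are
supported — a flat CSV with a fixed header and JSON-Lines — both
deterministic byte-for-byte for identical input, and both validated on read
(strictly increasing timestamps, finite coordinates, complete columns, with
offending row numbers in error messages).

Files may omit one hand entirely (single-hand tasks); the reader fills the
missing hand as parked at its trocar pivot with the jaw open and diathermy
off.  The engine never assumes uniform sampling: all time integrals use the
actual timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .geometry import Point3, Segment3, as_point
from .tasks import HANDS, TaskDefinition, _PIVOTS as _DEFAULT_PIVOTS

__all__ = [
    "Trajectory",
    "InstrumentPose",
    "TrajectoryError",
    "CSV_COLUMNS",
    "read_trajectory",
    "write_trajectory",
    "pose_at",
]

CSV_COLUMNS = (
    "time_s",
    "left_tip_x_mm", "left_tip_y_mm", "left_tip_z_mm",
    "left_jaw_closed", "left_diathermy_on",
    "right_tip_x_mm", "right_tip_y_mm", "right_tip_z_mm",
    "right_jaw_closed", "right_diathermy_on",
)

DEFAULT_SAMPLE_RATE_HZ = 60.0


class TrajectoryError(ValueError):
    """Malformed trajectory data (schema, monotonicity, NaN...)."""


@dataclass
class Trajectory:
    """Time-ordered two-instrument tip-motion log.

    Arrays are column-oriented for fast vectorised event detection:
    ``t`` is (n,), each hand's ``tips[hand]`` is (n, 3) mm, and the jaw /
    diathermy states are (n,) booleans.
    """

    t: np.ndarray
    tips: Dict[str, np.ndarray]
    jaw_closed: Dict[str, np.ndarray]
    diathermy_on: Dict[str, np.ndarray]
    task_id: int = 0
    dominant_hand: str = "right"
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2:
            raise TrajectoryError("trajectory needs at least 2 samples")
        if not np.all(np.isfinite(self.t)):
            row = int(np.flatnonzero(~np.isfinite(self.t))[0])
            raise TrajectoryError(f"non-finite timestamp at row {row}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            row = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise TrajectoryError(f"timestamps must be strictly increasing (row {row})")
        for hand in HANDS:
            if hand not in self.tips:
                raise TrajectoryError(f"missing hand {hand!r}")
            self.tips[hand] = np.asarray(self.tips[hand], dtype=float)
            if self.tips[hand].shape != (self.t.size, 3):
                raise TrajectoryError(f"{hand} tips must have shape (n, 3)")
            if not np.all(np.isfinite(self.tips[hand])):
                row = int(np.flatnonzero(~np.isfinite(self.tips[hand]).all(axis=1))[0])
                raise TrajectoryError(f"non-finite {hand} tip coordinate at row {row}")
            self.jaw_closed[hand] = np.asarray(self.jaw_closed[hand], dtype=bool)
            self.diathermy_on[hand] = np.asarray(self.diathermy_on[hand], dtype=bool)
            for name, arr in (("jaw", self.jaw_closed[hand]),
                              ("diathermy", self.diathermy_on[hand])):
                if arr.shape != (self.t.size,):
                    raise TrajectoryError(f"{hand} {name} state must have shape (n,)")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class InstrumentPose:
    """Tip position plus the intracorporeal shaft through the trocar pivot."""

    tip: Point3
    shaft: Segment3


def pose_at(traj: Trajectory, hand: str, index: int, task: TaskDefinition) -> InstrumentPose:
    """Reconstruct the instrument pose at a sample from the fulcrum model.

    The shaft is the segment from the tip to the hand's trocar pivot — the
    fulcrum constraint means the (straight, rigid) shaft always passes
    through the body-wall entry point.
    """
    if hand not in task.pivots:
        raise KeyError(f"task {task.task_id} scene has no pivot for hand {hand!r}")
    tip = as_point(traj.tips[hand][index])
    pivot = task.pivots[hand]
    if np.array_equal(tip, pivot):
        raise ValueError(f"degenerate shaft: tip coincides with pivot at sample {index}")
    return InstrumentPose(tip=tip, shaft=Segment3(tip, pivot))


def _park_positions(task: Optional[TaskDefinition]) -> Dict[str, np.ndarray]:
    pivots = task.pivots if task is not None else _DEFAULT_PIVOTS
    return {h: np.asarray(pivots[h], dtype=float) for h in HANDS}


def _infer_format(path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("csv", "jsonl"):
            raise ValueError(f"unknown trajectory format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    return "jsonl" if suffix in (".jsonl", ".ndjson") else "csv"


def read_trajectory(path, fmt: Optional[str] = None,
                    task: Optional[TaskDefinition] = None) -> Trajectory:
    """Load and validate a trajectory log (CSV or JSON-Lines).

    A metadata sidecar ``<path>.meta.json`` is merged in when present.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "csv":
        traj = _read_csv(path, task)
    else:
        traj = _read_jsonl(path, task)
    sidecar = path.with_name(path.name + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        traj.task_id = int(meta.get("task_id", traj.task_id))
        traj.dominant_hand = meta.get("dominant_hand", traj.dominant_hand)
        traj.sample_rate_hz = float(meta.get("sample_rate_hz", traj.sample_rate_hz))
        traj.metadata.update(meta.get("metadata", {}))
    return traj


def _assemble(df: pd.DataFrame, task: Optional[TaskDefinition]) -> Trajectory:
    if df.shape[0] < 2:
        raise TrajectoryError("trajectory file holds fewer than 2 samples")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise TrajectoryError(f"missing/NaN values at rows {list(bad[:5])}")
    park = _park_positions(task)
    tips, jaw, dia = {}, {}, {}
    n = df.shape[0]
    for hand in HANDS:
        cols = [f"{hand}_tip_{ax}_mm" for ax in "xyz"]
        if cols[0] in df.columns:
            tips[hand] = df[cols].to_numpy(dtype=float)
            jaw[hand] = df[f"{hand}_jaw_closed"].to_numpy().astype(bool)
            dia[hand] = df[f"{hand}_diathermy_on"].to_numpy().astype(bool)
        else:
            tips[hand] = np.tile(park[hand], (n, 1))
            jaw[hand] = np.zeros(n, dtype=bool)
            dia[hand] = np.zeros(n, dtype=bool)
    return Trajectory(
        t=df["time_s"].to_numpy(dtype=float),
        tips=tips, jaw_closed=jaw, diathermy_on=dia,
        task_id=task.task_id if task is not None else 0,
    )


def _read_csv(path: Path, task: Optional[TaskDefinition]) -> Trajectory:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise TrajectoryError(f"empty trajectory file: {path}") from None
    if "time_s" not in df.columns:
        raise TrajectoryError("missing required column time_s")
    present_hands = [h for h in HANDS if f"{h}_tip_x_mm" in df.columns]
    if not present_hands:
        raise TrajectoryError("no hand columns present")
    for hand in present_hands:
        for col in (f"{hand}_tip_x_mm", f"{hand}_tip_y_mm", f"{hand}_tip_z_mm",
                    f"{hand}_jaw_closed", f"{hand}_diathermy_on"):
            if col not in df.columns:
                raise TrajectoryError(f"missing column {col}")
    return _assemble(df, task)


def _read_jsonl(path: Path, task: Optional[TaskDefinition]) -> Trajectory:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                doc = json.loads(line)
            except json.JSONDecodeError as e:
                raise TrajectoryError(f"invalid JSON at line {lineno}: {e}") from None
            row = {"time_s": doc["t"]}
            for hand in HANDS:
                if hand in doc:
                    x, y, z, j, d = doc[hand]
                    row.update({f"{hand}_tip_x_mm": x, f"{hand}_tip_y_mm": y,
                                f"{hand}_tip_z_mm": z, f"{hand}_jaw_closed": j,
                                f"{hand}_diathermy_on": d})
            rows.append(row)
    if not rows:
        raise TrajectoryError(f"empty trajectory file: {path}")
    return _assemble(pd.DataFrame(rows), task)


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_trajectory(traj: Trajectory, path, fmt: Optional[str] = None,
                     sidecar: bool = True) -> None:
    """Write a trajectory log; byte output is deterministic for equal input."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        lines = [",".join(CSV_COLUMNS)]
        for i in range(traj.n_samples):
            fields = [_fmt(traj.t[i])]
            for hand in HANDS:
                x, y, z = traj.tips[hand][i]
                fields += [_fmt(x), _fmt(y), _fmt(z),
                           str(int(traj.jaw_closed[hand][i])),
                           str(int(traj.diathermy_on[hand][i]))]
            lines.append(",".join(fields))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    else:
        lines = []
        for i in range(traj.n_samples):
            doc = {"t": float(traj.t[i])}
            for hand in HANDS:
                x, y, z = traj.tips[hand][i]
                doc[hand] = [float(x), float(y), float(z),
                             int(traj.jaw_closed[hand][i]),
                             int(traj.diathermy_on[hand][i])]
            lines.append(json.dumps(doc, separators=(",", ":")))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    if sidecar:
        meta = {
            "task_id": traj.task_id,
            "dominant_hand": traj.dominant_hand,
            "sample_rate_hz": traj.sample_rate_hz,
            "metadata": traj.metadata,
        }
        path.with_name(path.name + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
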