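"""The five assessment parameters and the final score.

Performance on a task is summarised by five parameters: task time,
efficiency of movement per hand (excess of the actual tip-path length over
the ideal path length, together with the time spent outside the ideal-path
corridor), economy of diathermy (on-target burn time beyond a strict 2-s
threshold), the per-class error tally, and the final score

    S = 100 - sum_i n_i * v_i

where ``n_i`` is the count of errors of class *i* and ``v_i`` its weight in
[1, 5].  The continuous quantities (off-path seconds, excess-burn seconds)
enter the score through their own error classes, discretised as
ceil-of-seconds, which keeps the printed formula exact.  The score is not
clamped at zero by default — a lower score always means worse performance —
but a clamp option exists for display parity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .events import (
    DetectionParams,
    EventKind,
    EventLog,
    burn_episodes,
    detect_events,
    off_path_intervals,
)
from .geometry import polyline_length
from .tasks import (
    APPLICABLE_TASKS,
    ErrorClass,
    HANDS,
    TaskDefinition,
    default_weights,
    validate_weights,
)
from .trajio import Trajectory

__all__ = [
    "EXCESS_BURN_THRESHOLD_S",
    "METRIC_PARAMETERS",
    "ErrorTally",
    "MetricsResult",
    "movement_efficiency",
    "diathermy_economy",
    "tally_errors",
    "final_score",
    "score_session",
    "SessionRecord",
    "SessionStore",
    "report",
]

# Only on-target burn time beyond this counts as excess (strictly "more than").
EXCESS_BURN_THRESHOLD_S = 2.0

# The five top-level assessment parameters.
METRIC_PARAMETERS = (
    "time",
    "efficiency_of_movement",
    "economy_of_diathermy",
    "errors",
    "final_score",
)


@dataclass
class ErrorTally:
    """Per-class error counts plus the raw continuous quantities."""

    counts: Dict[ErrorClass, int] = field(
        default_factory=lambda: {c: 0 for c in ErrorClass})
    off_path_seconds: Dict[str, float] = field(
        default_factory=lambda: {h: 0.0 for h in HANDS})
    excess_burn_seconds: float = 0.0

    def __post_init__(self):
        for c in ErrorClass:
            self.counts.setdefault(c, 0)
        for c, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {c}")

    @property
    def total_errors(self) -> int:
        return sum(self.counts.values())

    @property
    def empty(self) -> bool:
        return self.total_errors == 0

    def to_json(self) -> dict:
        return {
            "counts": {c.value: int(n) for c, n in self.counts.items()},
            "off_path_seconds": dict(self.off_path_seconds),
            "excess_burn_seconds": self.excess_burn_seconds,
        }

    @staticmethod
    def from_json(doc: dict) -> "ErrorTally":
        return ErrorTally(
            counts={ErrorClass(k): int(v) for k, v in doc["counts"].items()},
            off_path_seconds=dict(doc.get("off_path_seconds", {})),
            excess_burn_seconds=float(doc.get("excess_burn_seconds", 0.0)),
        )


def movement_efficiency(traj: Trajectory, hand: str, task: TaskDefinition,
                        params: Optional[DetectionParams] = None
                        ) -> Tuple[float, float]:
    """Efficiency of movement for one hand.

    Returns ``(path_excess_mm, off_path_seconds)``: the excess of the actual
    tip-path length over the ideal path length (floored at 0), and the total
    time the tip spent outside the ideal-path corridor.
    """
    params = params or DetectionParams()
    if hand not in task.ideal_path:
        raise ValueError(f"task {task.task_id} defines no ideal path for hand {hand!r}")
    path = task.ideal_path[hand]
    actual = float(np.linalg.norm(np.diff(traj.tips[hand], axis=0), axis=1).sum())
    excess = max(0.0, actual - polyline_length(path))
    off = sum(te - ts for ts, te in
              off_path_intervals(traj, hand, path, params.corridor_mm))
    return excess, off


def diathermy_economy(episodes: Sequence[tuple]) -> float:
    """Total excess burn time: Σ over on-target episodes of max(0, dur − 2 s)."""
    total = 0.0
    for _target, _hand, ts, te, on_target in episodes:
        if on_target:
            total += max(0.0, (te - ts) - EXCESS_BURN_THRESHOLD_S)
    return total


def tally_errors(log: EventLog, task: TaskDefinition,
                 params: Optional[DetectionParams] = None) -> ErrorTally:
    """Count errors per class from an event log.

    Discrete classes count one per episode; the continuous classes discretise
    as ceil-of-seconds.  Classes not applicable to the task are forced to 0.
    """
    counts = {c: 0 for c in ErrorClass}
    off_path = {h: 0.0 for h in HANDS}
    for e in log.events:
        if e.kind is EventKind.OFFTIP_TARGET_CONTACT:
            counts[ErrorClass.OFF_TIP_CONTACT] += 1
        elif e.kind is EventKind.BOUNDARY_CONTACT:
            counts[ErrorClass.WORKSPACE_BOUNDARY] += 1
        elif e.kind is EventKind.TIP_TARGET_CONTACT and not e.payload.get("exempt"):
            counts[ErrorClass.TARGET_CONTACT_EXCESS] += 1
        elif e.kind is EventKind.CONTAINER_CONTACT:
            counts[ErrorClass.CONTAINER_CONTACT] += 1
        elif e.kind is EventKind.INSTRUMENT_CLASH:
            counts[ErrorClass.INSTRUMENT_CLASH] += 1
        elif e.kind is EventKind.OVAL_CONTACT:
            counts[ErrorClass.OVAL_CONTACT_EXCESS] += 1
        elif e.kind is EventKind.BURN_OFF_TARGET:
            counts[ErrorClass.DIATHERMY_OFF_TARGET] += 1
        elif e.kind is EventKind.OFF_PATH_INTERVAL:
            off_path[e.hand] = off_path.get(e.hand, 0.0) + e.duration
    counts[ErrorClass.OVAL_CONTACT_EXCESS] = max(
        0, counts[ErrorClass.OVAL_CONTACT_EXCESS] - task.permitted_oval_contacts)
    total_off = sum(off_path.values())
    counts[ErrorClass.OFF_PATH_TIME] = int(math.ceil(total_off)) if total_off > 0 else 0
    excess = 0.0
    for e in log.events:
        if e.kind is EventKind.BURN_ON_TARGET:
            excess += max(0.0, e.duration - EXCESS_BURN_THRESHOLD_S)
    counts[ErrorClass.EXCESS_BURN_TIME] = int(math.ceil(excess)) if excess > 0 else 0
    for c in ErrorClass:
        if task.task_id not in APPLICABLE_TASKS[c]:
            counts[c] = 0
    return ErrorTally(counts=counts, off_path_seconds=off_path,
                      excess_burn_seconds=excess)


def final_score(tally: ErrorTally,
                weights: Optional[Dict[ErrorClass, int]] = None,
                clamp: bool = False) -> float:
    """``100 - sum(count * weight)``; 100 iff the tally is empty."""
    weights = default_weights() if weights is None else weights
    violations = validate_weights(weights)
    if violations:
        raise ValueError("invalid weight table: " + "; ".join(violations))
    s = 100.0 - float(sum(tally.counts[c] * weights[c] for c in ErrorClass))
    return max(0.0, s) if clamp else s


@dataclass
class MetricsResult:
    """The five assessment parameters for one attempt."""

    task_id: int
    time_s: float
    efficiency_mm: Dict[str, Optional[float]]       # path excess per hand
    off_path_seconds: Dict[str, float]
    economy_excess_burn_s: float
    tally: ErrorTally
    final_score: float
    completed: bool
    completion_time_s: Optional[float] = None
    dominant_hand: str = "right"

    def to_json(self) -> dict:
        return {
            "task_id": self.task_id,
            "time_s": self.time_s,
            "efficiency_mm": self.efficiency_mm,
            "off_path_seconds": self.off_path_seconds,
            "economy_excess_burn_s": self.economy_excess_burn_s,
            "tally": self.tally.to_json(),
            "final_score": self.final_score,
            "completed": self.completed,
            "completion_time_s": self.completion_time_s,
            "dominant_hand": self.dominant_hand,
        }

    @staticmethod
    def from_json(doc: dict) -> "MetricsResult":
        return MetricsResult(
            task_id=doc["task_id"], time_s=doc["time_s"],
            efficiency_mm=dict(doc["efficiency_mm"]),
            off_path_seconds=dict(doc["off_path_seconds"]),
            economy_excess_burn_s=doc["economy_excess_burn_s"],
            tally=ErrorTally.from_json(doc["tally"]),
            final_score=doc["final_score"], completed=doc["completed"],
            completion_time_s=doc.get("completion_time_s"),
            dominant_hand=doc.get("dominant_hand", "right"),
        )


def score_session(traj: Trajectory, task: TaskDefinition,
                  weights: Optional[Dict[ErrorClass, int]] = None,
                  params: Optional[DetectionParams] = None,
                  clamp: bool = False) -> MetricsResult:
    """Full pipeline: detect events, compute the five parameters, score."""
    params = params or DetectionParams()
    log = detect_events(traj, task, params)
    tally = tally_errors(log, task, params)
    efficiency: Dict[str, Optional[float]] = {h: None for h in HANDS}
    for hand in task.ideal_path:
        excess, _off = movement_efficiency(traj, hand, task, params)
        efficiency[hand] = excess
    score = final_score(tally, weights, clamp=clamp)
    return MetricsResult(
        task_id=task.task_id,
        time_s=traj.duration,
        efficiency_mm=efficiency,
        off_path_seconds=dict(tally.off_path_seconds),
        economy_excess_burn_s=tally.excess_burn_seconds,
        tally=tally,
        final_score=score,
        completed=log.completed,
        completion_time_s=log.completion_time,
        dominant_hand=traj.dominant_hand,
    )


# --------------------------------------------------------------------------
# session store and feedback reports


@dataclass
class SessionRecord:
    subject: str
    task_id: int
    timestamp: str                       # ISO-8601, UTC
    result: MetricsResult

    def to_json(self) -> dict:
        return {"subject": self.subject, "task_id": self.task_id,
                "timestamp": self.timestamp, "result": self.result.to_json()}

    @staticmethod
    def from_json(doc: dict) -> "SessionRecord":
        return SessionRecord(doc["subject"], doc["task_id"], doc["timestamp"],
                             MetricsResult.from_json(doc["result"]))


class SessionStore:
    """Append-only per-subject attempt store: one JSON file per subject."""

    def __init__(self, root):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _path(self, subject: str) -> Path:
        safe = "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in subject)
        return self.root / f"{safe}.json"

    def append(self, subject: str, result: MetricsResult,
               timestamp: Optional[str] = None) -> SessionRecord:
        ts = timestamp or datetime.now(timezone.utc).isoformat()
        rec = SessionRecord(subject, result.task_id, ts, result)
        records = self._load(subject)
        records.append(rec)
        self._path(subject).write_text(json.dumps(
            [r.to_json() for r in records], indent=2) + "\n")
        return rec

    def _load(self, subject: str) -> List[SessionRecord]:
        p = self._path(subject)
        if not p.exists():
            return []
        return [SessionRecord.from_json(d) for d in json.loads(p.read_text())]

    def history(self, subject: str, task_id: Optional[int] = None
                ) -> List[SessionRecord]:
        recs = self._load(subject)
        if task_id is not None:
            recs = [r for r in recs if r.task_id == task_id]
        return sorted(recs, key=lambda r: r.timestamp)


def report(history: Sequence[SessionRecord], kind: str = "immediate") -> dict:
    """Immediate feedback (latest attempt) or terminal feedback (series + trend)."""
    if kind not in ("immediate", "terminal"):
        raise ValueError(f"report kind must be 'immediate' or 'terminal', got {kind!r}")
    if not history:
        raise ValueError("empty performance history")
    if kind == "immediate":
        latest = history[-1]
        return {"kind": "immediate", "subject": latest.subject,
                "timestamp": latest.timestamp, "result": latest.result.to_json()}
    series = [
        {"attempt_index": i, "timestamp": r.timestamp, "task_id": r.task_id,
         "score": r.result.final_score, "time_s": r.result.time_s,
         "total_errors": r.result.tally.total_errors,
         "completed": r.result.completed}
        for i, r in enumerate(history)
    ]
    trend = (history[-1].result.final_score - history[0].result.final_score
             if len(history) > 1 else None)
    return {"kind": "terminal", "subject": history[0].subject,
            "n_attempts": len(history), "series": series,
            "score_trend": trend,
            "trend_defined": len(history) > 1}


def report_series_csv(doc: dict) -> str:
    """Terminal-feedback series as a CSV (attempt_index,score,time_s,total_errors)."""
    if doc.get("kind") != "terminal":
        raise ValueError("series CSV requires a terminal report")
    lines = ["attempt_index,score,time_s,total_errors"]
    for row in doc["series"]:
        lines.append(f"{row['attempt_index']},{row['score']:.6g},"
                     f"{row['time_s']:.6g},{row['total_errors']}")
    return "\n".join(lines) + "\n"
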