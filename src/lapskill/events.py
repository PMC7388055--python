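"""Event detection: trajectory + task definition -> timestamped event log.

Every metric and error count sits on top of this layer.  Contact-type events
are maximal intervals of a thresholded, linearly-interpolated distance
signal (so episode boundaries have sub-sample precision); gaps shorter than
the debounce window merge neighbouring contact episodes.  Grasp/release/
placement come from a per-sample object state machine; removal/reinsertion
from a hysteresis test on the depth of the tip along the insertion axis;
burn episodes from maximal diathermy-pedal runs (sample-aligned — the pedal
is a sampled binary state, so its bounds are not interpolated and not
debounced).  Off-path intervals are likewise not debounced: they feed a
continuous time integral, and merging across a gap would count on-path time
as off-path.

Conventions that the scoring layer relies on:

* the tip "contacts" a shape when it comes within ``contact_eps_mm`` of the
  shape's contact surface (closed shapes: being inside counts);
* an off-tip contact requires the shaft (minus the distal ``tip_zone_mm``)
  to touch the target while the tip itself is *not* touching it;
* a tip-target contact episode is exempt from the error count when the hand
  grasps the object during it, or when it is the unavoidable disengagement
  right after that hand released or handed over the object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import (
    Cuboid,
    Polyline3,
    Sphere,
    contains_many,
    distance_points_to_polyline,
    segment_pairs_distance,
    surface_distance,
)
from .tasks import CompletionKind, HANDS, TaskDefinition
from .trajio import Trajectory

__all__ = [
    "EventKind",
    "Event",
    "EventLog",
    "DetectionParams",
    "detect_events",
    "off_path_intervals",
    "burn_episodes",
    "intervals_from_signal",
]


class EventKind(str, Enum):
    TIP_TARGET_CONTACT = "TIP_TARGET_CONTACT"
    OFFTIP_TARGET_CONTACT = "OFFTIP_TARGET_CONTACT"
    GRASP = "GRASP"
    RELEASE = "RELEASE"
    PLACEMENT = "PLACEMENT"
    BOUNDARY_CONTACT = "BOUNDARY_CONTACT"
    CONTAINER_CONTACT = "CONTAINER_CONTACT"
    INSTRUMENT_CLASH = "INSTRUMENT_CLASH"
    OVAL_CONTACT = "OVAL_CONTACT"
    REMOVAL = "REMOVAL"
    REINSERTION = "REINSERTION"
    BURN_ON_TARGET = "BURN_ON_TARGET"
    BURN_OFF_TARGET = "BURN_OFF_TARGET"
    OFF_PATH_INTERVAL = "OFF_PATH_INTERVAL"
    TASK_COMPLETE = "TASK_COMPLETE"


@dataclass(frozen=True)
class Event:
    kind: EventKind
    hand: str                  # "left" | "right" | "both"
    t_start: float
    t_end: float
    payload: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.t_end < self.t_start:
            raise ValueError("event with t_end < t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class EventLog:
    events: List[Event]
    task_id: int

    def __post_init__(self):
        self.events = sorted(
            self.events,
            key=lambda e: (e.t_start, e.t_end, e.kind.value, e.hand,
                           str(e.payload.get("target", ""))),
        )

    def of_kind(self, *kinds: EventKind) -> List[Event]:
        return [e for e in self.events if e.kind in kinds]

    @property
    def completed(self) -> bool:
        return any(e.kind is EventKind.TASK_COMPLETE for e in self.events)

    @property
    def completion_time(self) -> Optional[float]:
        for e in self.events:
            if e.kind is EventKind.TASK_COMPLETE:
                return e.t_start
        return None

    def off_path_seconds(self, hand: Optional[str] = None) -> float:
        total = 0.0
        for e in self.of_kind(EventKind.OFF_PATH_INTERVAL):
            if hand is None or e.hand == hand:
                total += e.duration
        return total

    def to_jsonl(self) -> str:
        import json

        lines = []
        for e in self.events:
            lines.append(json.dumps(
                {"kind": e.kind.value, "hand": e.hand,
                 "t_start": e.t_start, "t_end": e.t_end, "payload": e.payload},
                separators=(",", ":"), sort_keys=True))
        return "\n".join(lines) + "\n"

    @staticmethod
    def from_jsonl(text: str, task_id: int = 0) -> "EventLog":
        import json

        events = []
        for line in text.splitlines():
            if not line.strip():
                continue
            doc = json.loads(line)
            events.append(Event(EventKind(doc["kind"]), doc["hand"],
                                doc["t_start"], doc["t_end"], doc.get("payload", {})))
        return EventLog(events, task_id)


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the detection layer (all lengths mm, times s)."""

    contact_eps_mm: float = 1.0       # tolerance beyond a shape's surface
    debounce_s: float = 0.1           # contact episodes separated by less merge
    tip_zone_mm: float = 5.0          # distal shaft length that counts as "tip"
    grasp_radius_mm: float = 10.0     # jaw-close within this of the object grasps it
    corridor_mm: float = 10.0         # ideal-path corridor radius
    clash_distance_mm: float = 2.0    # shaft-to-shaft distance that counts as a clash
    removal_depth_mm: float = 60.0    # tip depth along the insertion axis = "inside"
    removal_hysteresis_mm: float = 10.0


# --------------------------------------------------------------------------
# interval machinery


def intervals_from_signal(
    t: np.ndarray,
    g: np.ndarray,
    threshold: float = 0.0,
    above: bool = False,
    debounce_s: float = 0.0,
) -> List[Tuple[float, float]]:
    """Maximal intervals where ``g <= threshold`` (or ``> threshold``).

    Interval bounds are linearly interpolated on ``g`` at threshold
    crossings; a non-finite neighbour (used to mask out samples for
    state-dependent suppression) pins the bound to the run's own sample
    time.  Intervals separated by a gap shorter than ``debounce_s`` merge.
    """
    t = np.asarray(t, dtype=float)
    g = np.asarray(g, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = (g > threshold) if above else (g <= threshold)
    mask &= np.isfinite(g)
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    # split into runs of consecutive indices
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    out: List[Tuple[float, float]] = []
    for i0, i1 in zip(starts, ends):
        if i0 == 0 or not np.isfinite(g[i0 - 1]):
            ts = float(t[i0])
        else:
            ts = _cross_time(t[i0 - 1], t[i0], g[i0 - 1], g[i0], threshold)
        if i1 == len(t) - 1 or not np.isfinite(g[i1 + 1]):
            te = float(t[i1])
        else:
            te = _cross_time(t[i1], t[i1 + 1], g[i1], g[i1 + 1], threshold)
        out.append((ts, te))
    if debounce_s > 0 and len(out) > 1:
        merged = [out[0]]
        for ts, te in out[1:]:
            if ts - merged[-1][1] < debounce_s:
                merged[-1] = (merged[-1][0], te)
            else:
                merged.append((ts, te))
        out = merged
    return out


def _cross_time(t0, t1, g0, g1, thr) -> float:
    return float(t0 + (t1 - t0) * (thr - g0) / (g1 - g0))


# --------------------------------------------------------------------------
# object (graspable sphere) state machine


@dataclass
class _ObjectTrace:
    pos: np.ndarray                       # (n, 3) object centre per sample
    held_by: np.ndarray                   # (n,) -1 none / 0 left / 1 right
    parked: np.ndarray                    # (n,) released and not re-grasped
    grasp_events: List[Event]
    release_events: List[Event]
    placement_events: List[Event]
    grasp_times: Dict[str, List[float]]
    disengage_times: Dict[str, List[float]]
    grasp_hands_sequence: List[Tuple[str, float]]


def _simulate_object(traj: Trajectory, task: TaskDefinition,
                     params: DetectionParams) -> Optional[_ObjectTrace]:
    if task.grasp_target is None:
        return None
    target: Sphere = task.scene[task.grasp_target]  # type: ignore[assignment]
    n = traj.n_samples
    t = traj.t
    tips = traj.tips
    jaw = traj.jaw_closed
    goal = task.scene.get(task.completion.goal_shape) if task.completion.goal_shape else None

    pos = np.empty((n, 3))
    held = np.full(n, -1, dtype=np.int8)
    parked = np.zeros(n, dtype=bool)
    obj = np.array(target.center, dtype=float)
    holder: Optional[str] = None
    is_parked = False
    grasps, releases, placements = [], [], []
    grasp_times = {h: [] for h in HANDS}
    disengage = {h: [] for h in HANDS}
    sequence: List[Tuple[str, float]] = []

    for i in range(n):
        if holder is not None:
            obj = tips[holder][i]
        # grasp / handoff: jaw closing within grasp radius of the object
        for hand in HANDS:
            closing = jaw[hand][i] and (i > 0 and not jaw[hand][i - 1])
            if closing and hand != holder:
                if float(np.linalg.norm(tips[hand][i] - obj)) <= params.grasp_radius_mm:
                    if holder is not None:
                        disengage[holder].append(float(t[i]))
                    holder = hand
                    is_parked = False
                    obj = tips[hand][i]
                    ev = Event(EventKind.GRASP, hand, float(t[i]), float(t[i]),
                               {"object": task.grasp_target})
                    grasps.append(ev)
                    grasp_times[hand].append(float(t[i]))
                    sequence.append((hand, float(t[i])))
        # release
        for hand in HANDS:
            opening = (i > 0 and jaw[hand][i - 1]) and not jaw[hand][i]
            if opening and holder == hand:
                holder = None
                is_parked = True
                disengage[hand].append(float(t[i]))
                releases.append(Event(EventKind.RELEASE, hand, float(t[i]), float(t[i]),
                                      {"object": task.grasp_target}))
                if goal is not None and bool(contains_many(goal, obj[None, :])[0]):
                    placements.append(Event(
                        EventKind.PLACEMENT, hand, float(t[i]), float(t[i]),
                        {"object": task.grasp_target, "goal": task.completion.goal_shape,
                         "position": [float(x) for x in obj]}))
        pos[i] = obj
        held[i] = -1 if holder is None else HANDS.index(holder)
        parked[i] = is_parked
    return _ObjectTrace(pos, held, parked, grasps, releases, placements,
                        grasp_times, disengage, sequence)


# --------------------------------------------------------------------------
# per-signal detectors


def _shaft_arrays(traj: Trajectory, task: TaskDefinition, hand: str,
                  tip_zone_mm: float):
    """Per-sample truncated shaft (tip-zone excluded) and full shaft."""
    tips = traj.tips[hand]
    pivot = np.broadcast_to(task.pivots[hand], tips.shape)
    d = pivot - tips
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    safe = np.maximum(norms, 1e-12)
    frac = np.minimum(tip_zone_mm / safe, 1.0)
    shaft_start = tips + frac * d
    return shaft_start, np.array(pivot)


def _signed_clearance(ws: Cuboid, pts: np.ndarray) -> np.ndarray:
    """+distance to the workspace wall when inside, −distance when outside."""
    d = surface_distance(ws, pts)
    inside = contains_many(ws, pts)
    return np.where(inside, d, -d)


def off_path_intervals(traj: Trajectory, hand: str, ideal_path: Polyline3,
                       corridor_mm: float) -> List[Tuple[float, float]]:
    """Maximal intervals where the tip is farther than the corridor radius
    from the ideal path (bounds interpolated, no debouncing)."""
    d = distance_points_to_polyline(traj.tips[hand], ideal_path)
    return intervals_from_signal(traj.t, d - corridor_mm, 0.0, above=True)


def burn_episodes(traj: Trajectory, task: TaskDefinition,
                  params: Optional[DetectionParams] = None
                  ) -> List[Tuple[Optional[str], str, float, float, bool]]:
    """Maximal diathermy-pedal activation runs per hand.

    Returns (target_name_or_None, hand, t_start, t_end, on_target); an
    episode is on-target iff the tip is within contact tolerance of a
    designated cautery target at episode start.
    """
    params = params or DetectionParams()
    targets = [(name, task.scene[name]) for name in task.completion.targets]
    out = []
    t = traj.t
    for hand in HANDS:
        on = traj.diathermy_on[hand]
        if not on.any():
            continue
        idx = np.flatnonzero(on)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([idx[0]], idx[breaks + 1]))
        ends = np.concatenate((idx[breaks], [idx[-1]]))
        for i0, i1 in zip(starts, ends):
            tip = traj.tips[hand][i0]
            best_name, best_d = None, np.inf
            for name, sph in targets:
                d = float(np.linalg.norm(tip - sph.center)) - sph.radius
                if d < best_d:
                    best_name, best_d = name, d
            on_target = best_d <= params.contact_eps_mm
            out.append((best_name if on_target else None, hand,
                        float(t[i0]), float(t[i1]), bool(on_target)))
    out.sort(key=lambda e: (e[2], e[1]))
    return out


# --------------------------------------------------------------------------
# main detector


def detect_events(traj: Trajectory, task: TaskDefinition,
                  params: Optional[DetectionParams] = None) -> EventLog:
    """Classify a full trajectory into the task's event log."""
    params = params or DetectionParams()
    if traj.task_id and traj.task_id != task.task_id:
        raise ValueError(
            f"trajectory is for task {traj.task_id}, definition is task {task.task_id}")
    if traj.n_samples < 2:
        raise ValueError("empty trajectory")

    t = traj.t
    eps = params.contact_eps_mm
    events: List[Event] = []
    obj = _simulate_object(traj, task, params)
    if obj is not None:
        events += obj.grasp_events + obj.release_events + obj.placement_events

    shafts = {h: _shaft_arrays(traj, task, h, params.tip_zone_mm) for h in HANDS}

    # ---- tip-target contact (graspable object), with grasp/disengage exemption
    if obj is not None:
        target: Sphere = task.scene[task.grasp_target]  # type: ignore[assignment]
        for hi, hand in enumerate(HANDS):
            d = np.linalg.norm(traj.tips[hand] - obj.pos, axis=1)
            g = d - (target.radius + eps)
            g = np.where(obj.held_by == hi, np.inf, g)
            exempt_times = obj.grasp_times[hand] + obj.disengage_times[hand]
            # a grasp registers on the first held sample, one sample after the
            # contact episode's masked end — allow that gap
            margin = 2.0 * float(np.max(np.diff(t)))
            for ts, te in intervals_from_signal(t, g, 0.0, debounce_s=params.debounce_s):
                exempt = any(ts <= tx <= te + margin for tx in exempt_times)
                events.append(Event(EventKind.TIP_TARGET_CONTACT, hand, ts, te,
                                    {"target": task.grasp_target, "exempt": exempt}))

    # ---- off-tip contact: truncated shaft touches a target while tip does not
    offtip_targets: List[Tuple[str, np.ndarray, float, Optional[int]]] = []
    if obj is not None:
        tgt: Sphere = task.scene[task.grasp_target]  # type: ignore[assignment]
        offtip_targets.append((task.grasp_target, obj.pos, tgt.radius, None))
    if task.oval is not None:
        sph: Sphere = task.scene[task.oval]  # type: ignore[assignment]
        offtip_targets.append((task.oval, sph.center[None, :], sph.radius, None))
    for name in task.completion.targets:
        sph = task.scene[name]  # type: ignore[assignment]
        offtip_targets.append((name, sph.center[None, :], sph.radius, None))

    for hi, hand in enumerate(HANDS):
        shaft_start, pivot = shafts[hand]
        for name, centers, radius, _ in offtip_targets:
            pts = np.broadcast_to(centers, traj.tips[hand].shape)
            d_shaft = segment_pairs_distance(shaft_start, pivot, pts, pts)
            d_tip = np.linalg.norm(traj.tips[hand] - pts, axis=1)
            g = d_shaft - (radius + eps)
            # anything within one tip-zone length of the tip is tip approach,
            # not shaft contact
            suppress = d_tip - (radius + eps + params.tip_zone_mm) <= 0
            if obj is not None and name == task.grasp_target:
                # a released, parked object is out of play for off-tip contact
                suppress |= (obj.held_by == hi) | obj.parked
            g = np.where(suppress, np.inf, g)
            for ts, te in intervals_from_signal(t, g, 0.0, debounce_s=params.debounce_s):
                events.append(Event(EventKind.OFFTIP_TARGET_CONTACT, hand, ts, te,
                                    {"target": name}))

    # ---- workspace boundary contact
    ws = task.workspace
    for hand in HANDS:
        clearance = _signed_clearance(ws, traj.tips[hand])
        for ts, te in intervals_from_signal(t, clearance - eps, 0.0,
                                            debounce_s=params.debounce_s):
            events.append(Event(EventKind.BOUNDARY_CONTACT, hand, ts, te, {}))

    # ---- container margin contact (instrument tip or carried/resting sphere)
    if task.container is not None:
        wall = task.scene[task.container]
        for hand in HANDS:
            g = surface_distance(wall, traj.tips[hand]) - eps
            for ts, te in intervals_from_signal(t, g, 0.0, debounce_s=params.debounce_s):
                events.append(Event(EventKind.CONTAINER_CONTACT, hand, ts, te,
                                    {"source": "tip"}))
        if obj is not None:
            tgt = task.scene[task.grasp_target]
            g = surface_distance(wall, obj.pos) - (tgt.radius + eps)
            for ts, te in intervals_from_signal(t, g, 0.0, debounce_s=params.debounce_s):
                events.append(Event(EventKind.CONTAINER_CONTACT, "both", ts, te,
                                    {"source": "object"}))

    # ---- instrument clash (full shaft vs full shaft)
    if task.task_id in (3, 4):
        d = segment_pairs_distance(traj.tips["left"],
                                   np.broadcast_to(task.pivots["left"], traj.tips["left"].shape),
                                   traj.tips["right"],
                                   np.broadcast_to(task.pivots["right"], traj.tips["right"].shape))
        for ts, te in intervals_from_signal(t, d - params.clash_distance_mm, 0.0,
                                            debounce_s=params.debounce_s):
            events.append(Event(EventKind.INSTRUMENT_CLASH, "both", ts, te, {}))

    # ---- oval contact
    if task.oval is not None:
        sph = task.scene[task.oval]
        for hand in HANDS:
            g = np.linalg.norm(traj.tips[hand] - sph.center, axis=1) - (sph.radius + eps)
            for ts, te in intervals_from_signal(t, g, 0.0, debounce_s=params.debounce_s):
                events.append(Event(EventKind.OVAL_CONTACT, hand, ts, te,
                                    {"target": task.oval}))

    # ---- removal / reinsertion (hysteresis on depth along the insertion axis)
    if task.removal_hand is not None:
        hand = task.removal_hand
        pivot = task.pivots[hand]
        axis = ws.center - pivot
        axis = axis / np.linalg.norm(axis)
        s = (traj.tips[hand] - pivot) @ axis
        lo = params.removal_depth_mm
        hi_thr = params.removal_depth_mm + params.removal_hysteresis_mm
        inside = s[0] > lo
        for i in range(1, len(s)):
            if inside and s[i] < lo:
                tc = _cross_time(t[i - 1], t[i], s[i - 1], s[i], lo)
                events.append(Event(EventKind.REMOVAL, hand, tc, tc, {"depth_mm": lo}))
                inside = False
            elif not inside and s[i] > hi_thr:
                tc = _cross_time(t[i - 1], t[i], s[i - 1], s[i], hi_thr)
                events.append(Event(EventKind.REINSERTION, hand, tc, tc,
                                    {"depth_mm": hi_thr}))
                inside = True

    # ---- burn episodes
    episodes = []
    if task.completion.targets or any(traj.diathermy_on[h].any() for h in HANDS):
        episodes = burn_episodes(traj, task, params)
        for name, hand, ts, te, on_target in episodes:
            kind = EventKind.BURN_ON_TARGET if on_target else EventKind.BURN_OFF_TARGET
            events.append(Event(kind, hand, ts, te, {"target": name}))

    # ---- off-path intervals
    for hand, path in task.ideal_path.items():
        if task.task_id == 3:
            continue  # traversal uses the corridor for completion, not off-path
        for ts, te in off_path_intervals(traj, hand, path, params.corridor_mm):
            events.append(Event(EventKind.OFF_PATH_INTERVAL, hand, ts, te, {}))

    # ---- completion
    tc = _completion_time(traj, task, params, obj, events)
    if tc is not None:
        events.append(Event(EventKind.TASK_COMPLETE, "both", tc, tc, {}))

    return EventLog(events, task.task_id)


def _completion_time(traj, task, params, obj, events) -> Optional[float]:
    kind = task.completion.kind
    placements = sorted((e for e in events if e.kind is EventKind.PLACEMENT),
                        key=lambda e: e.t_start)
    if kind is CompletionKind.PLACED_IN_SHAPE:
        return placements[0].t_start if placements else None
    if kind is CompletionKind.TRANSFER_THEN_PLACED:
        if obj is None or not placements:
            return None
        for p in placements:
            hands_before = {h for h, tg in obj.grasp_hands_sequence if tg <= p.t_start}
            if len(hands_before) >= 2:
                return p.t_start
        return None
    if kind is CompletionKind.TRAVERSAL_COMPLETE:
        times = []
        for hand, path in task.ideal_path.items():
            th = _traversal_time(traj, hand, path, params.corridor_mm,
                                 task.completion.traversal_fraction)
            if th is None:
                return None
            times.append(th)
        return max(times) if times else None
    if kind is CompletionKind.REMOVE_REINSERT_COUNT:
        reins = sorted(e.t_start for e in events if e.kind is EventKind.REINSERTION)
        k = task.completion.reinsertion_count
        return reins[k - 1] if len(reins) >= k else None
    if kind is CompletionKind.ALL_TARGETS_CAUTERIZED:
        return _all_burned_time(task, events)
    if kind is CompletionKind.PLACED_AND_CAUTERIZED:
        if not placements:
            return None
        tb = _all_burned_time(task, events)
        if tb is None:
            return None
        return max(placements[0].t_start, tb)
    return None


def _all_burned_time(task, events) -> Optional[float]:
    done = {}
    for e in events:
        if e.kind is EventKind.BURN_ON_TARGET:
            name = e.payload.get("target")
            if name in task.completion.targets and name not in done:
                done[name] = e.t_end
    if set(done) >= set(task.completion.targets):
        return max(done.values())
    return None


def _traversal_time(traj, hand, path: Polyline3, corridor_mm: float,
                    fraction: float, step_mm: float = 2.0) -> Optional[float]:
    """Time at which the tip has visited the required fraction of the path
    arc length (a point is visited when the tip passes within the corridor)."""
    verts = path.vertices
    seglens = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    total = seglens.sum()
    n_pts = max(int(np.ceil(total / step_mm)) + 1, 2)
    s = np.linspace(0.0, total, n_pts)
    cum = np.concatenate(([0.0], np.cumsum(seglens)))
    arc_pts = np.empty((n_pts, 3))
    for k, sk in enumerate(s):
        j = min(int(np.searchsorted(cum, sk, side="right")) - 1, len(seglens) - 1)
        frac = (sk - cum[j]) / seglens[j]
        arc_pts[k] = verts[j] + frac * (verts[j + 1] - verts[j])
    tips = traj.tips[hand]
    # first sample index at which each arc point is visited
    d2 = ((tips[:, None, :] - arc_pts[None, :, :]) ** 2).sum(axis=2)
    within = d2 <= corridor_mm ** 2
    any_visit = within.any(axis=0)
    first_idx = np.where(any_visit, within.argmax(axis=0), -1)
    need = int(np.ceil(fraction * n_pts))
    visited_idx = np.sort(first_idx[first_idx >= 0])
    if visited_idx.size < need:
        return None
    return float(traj.t[visited_idx[need - 1]])
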