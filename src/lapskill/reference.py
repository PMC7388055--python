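"""Per-sample reference classifier (ground-truth annotator).

A deliberately plain, loop-based re-statement of the detection conventions:
it walks the trajectory sample by sample, computes each contact signal with
the scalar geometry queries, extracts threshold runs with the same
linear-interpolation rule, and counts errors with the same exemption and
discretisation rules as the scoring pipeline.  No debouncing is applied
(debounce window 0).

Two uses: the simulator annotates every generated trajectory with the
expected error tally (the injection manifest's ground truth), and the test
suite holds the vectorised detector to exact agreement with this
implementation.  It is independent of :mod:`lapskill.events` — it shares
only the scalar geometry primitives, which are themselves checked against
dense-sampling brute force separately.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple

import numpy as np

from .geometry import (
    Segment3,
    contains,
    distance_point_to_polyline,
    distance_point_to_segment,
    distance_segment_segment,
    surface_distance,
)
from .metrics import EXCESS_BURN_THRESHOLD_S, ErrorTally
from .events import DetectionParams
from .tasks import APPLICABLE_TASKS, ErrorClass, HANDS, TaskDefinition
from .trajio import Trajectory

__all__ = ["reference_tally"]


def _runs(t, g, threshold=0.0, above=False) -> List[Tuple[float, float]]:
    """Maximal runs of the thresholded signal, bounds interpolated on g;
    a non-finite neighbour pins the bound to the run's own sample time."""
    intervals = []
    n = len(g)
    i = 0

    def ok(k):
        return math.isfinite(g[k]) and ((g[k] > threshold) if above else (g[k] <= threshold))

    while i < n:
        if not ok(i):
            i += 1
            continue
        j = i
        while j + 1 < n and ok(j + 1):
            j += 1
        if i == 0 or not math.isfinite(g[i - 1]):
            ts = float(t[i])
        else:
            ts = float(t[i - 1] + (t[i] - t[i - 1]) * (threshold - g[i - 1]) / (g[i] - g[i - 1]))
        if j == n - 1 or not math.isfinite(g[j + 1]):
            te = float(t[j])
        else:
            te = float(t[j] + (t[j + 1] - t[j]) * (threshold - g[j]) / (g[j + 1] - g[j]))
        intervals.append((ts, te))
        i = j + 1
    return intervals


def reference_tally(traj: Trajectory, task: TaskDefinition,
                    params: Optional[DetectionParams] = None) -> ErrorTally:
    """Ground-truth error tally of a trajectory, per-sample brute force."""
    params = params or DetectionParams()
    eps = params.contact_eps_mm
    t = traj.t
    n = traj.n_samples
    counts = {c: 0 for c in ErrorClass}

    # ---- object state machine (graspable sphere)
    obj_pos = None
    held_by = [None] * n
    parked = [False] * n
    grasp_times: Dict[str, List[float]] = {h: [] for h in HANDS}
    disengage_times: Dict[str, List[float]] = {h: [] for h in HANDS}
    if task.grasp_target is not None:
        target = task.scene[task.grasp_target]
        obj_pos = np.empty((n, 3))
        obj = np.array(target.center, dtype=float)
        holder = None
        is_parked = False
        for i in range(n):
            if holder is not None:
                obj = traj.tips[holder][i]
            for hand in HANDS:
                closing = traj.jaw_closed[hand][i] and (
                    i > 0 and not traj.jaw_closed[hand][i - 1])
                if closing and hand != holder:
                    if float(np.linalg.norm(traj.tips[hand][i] - obj)) <= params.grasp_radius_mm:
                        if holder is not None:
                            disengage_times[holder].append(float(t[i]))
                        holder = hand
                        is_parked = False
                        obj = traj.tips[hand][i]
                        grasp_times[hand].append(float(t[i]))
            for hand in HANDS:
                opening = (i > 0 and traj.jaw_closed[hand][i - 1]) and not traj.jaw_closed[hand][i]
                if opening and holder == hand:
                    holder = None
                    is_parked = True
                    disengage_times[hand].append(float(t[i]))
            obj_pos[i] = obj
            held_by[i] = holder
            parked[i] = is_parked

    # ---- tip-target contacts with grasp/disengage exemption
    if obj_pos is not None:
        target = task.scene[task.grasp_target]
        margin = 2.0 * max(float(t[k + 1] - t[k]) for k in range(n - 1))
        for hand in HANDS:
            g = []
            for i in range(n):
                if held_by[i] == hand:
                    g.append(math.inf)
                else:
                    g.append(float(np.linalg.norm(traj.tips[hand][i] - obj_pos[i]))
                             - (target.radius + eps))
            exempt_times = grasp_times[hand] + disengage_times[hand]
            for ts, te in _runs(t, g):
                if not any(ts <= tx <= te + margin for tx in exempt_times):
                    counts[ErrorClass.TARGET_CONTACT_EXCESS] += 1

    # ---- off-tip contacts: truncated shaft touches a target, tip does not
    offtip: List[Tuple[str, object, float]] = []
    if task.grasp_target is not None:
        offtip.append((task.grasp_target, None, task.scene[task.grasp_target].radius))
    if task.oval is not None:
        offtip.append((task.oval, task.scene[task.oval].center, task.scene[task.oval].radius))
    for name in task.completion.targets:
        offtip.append((name, task.scene[name].center, task.scene[name].radius))
    for hand in HANDS:
        pivot = task.pivots[hand]
        for name, center, radius in offtip:
            g = []
            for i in range(n):
                tip = traj.tips[hand][i]
                c = obj_pos[i] if center is None else center
                if center is None and (held_by[i] == hand or parked[i]):
                    g.append(math.inf)
                    continue
                d_tip = float(np.linalg.norm(tip - c))
                if d_tip <= radius + eps + params.tip_zone_mm:
                    g.append(math.inf)
                    continue
                to_pivot = pivot - tip
                dist_tp = float(np.linalg.norm(to_pivot))
                frac = min(params.tip_zone_mm / max(dist_tp, 1e-12), 1.0)
                start = tip + frac * to_pivot
                g.append(distance_point_to_segment(c, start, pivot) - (radius + eps))
            counts[ErrorClass.OFF_TIP_CONTACT] += len(_runs(t, g))

    # ---- workspace boundary
    ws = task.workspace
    for hand in HANDS:
        g = []
        for i in range(n):
            tip = traj.tips[hand][i]
            d = float(surface_distance(ws, tip[None, :])[0])
            clearance = d if contains(ws, tip) else -d
            g.append(clearance - eps)
        counts[ErrorClass.WORKSPACE_BOUNDARY] += len(_runs(t, g))

    # ---- container margins (tip of either hand, and the sphere itself)
    if task.container is not None:
        wall = task.scene[task.container]
        for hand in HANDS:
            g = [float(surface_distance(wall, traj.tips[hand][i][None, :])[0]) - eps
                 for i in range(n)]
            counts[ErrorClass.CONTAINER_CONTACT] += len(_runs(t, g))
        if obj_pos is not None:
            r = task.scene[task.grasp_target].radius
            g = [float(surface_distance(wall, obj_pos[i][None, :])[0]) - (r + eps)
                 for i in range(n)]
            counts[ErrorClass.CONTAINER_CONTACT] += len(_runs(t, g))

    # ---- instrument clash
    if task.task_id in (3, 4):
        g = []
        for i in range(n):
            s1 = Segment3(traj.tips["left"][i], task.pivots["left"])
            s2 = Segment3(traj.tips["right"][i], task.pivots["right"])
            g.append(distance_segment_segment(s1, s2) - params.clash_distance_mm)
        counts[ErrorClass.INSTRUMENT_CLASH] += len(_runs(t, g))

    # ---- oval contacts beyond the permitted number
    if task.oval is not None:
        sph = task.scene[task.oval]
        n_contacts = 0
        for hand in HANDS:
            g = [float(np.linalg.norm(traj.tips[hand][i] - sph.center))
                 - (sph.radius + eps) for i in range(n)]
            n_contacts += len(_runs(t, g))
        counts[ErrorClass.OVAL_CONTACT_EXCESS] = max(
            0, n_contacts - task.permitted_oval_contacts)

    # ---- burns
    excess = 0.0
    targets = [(name, task.scene[name]) for name in task.completion.targets]
    for hand in HANDS:
        on = traj.diathermy_on[hand]
        i = 0
        while i < n:
            if not on[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and on[j + 1]:
                j += 1
            tip = traj.tips[hand][i]
            best_d = math.inf
            for _name, sph in targets:
                best_d = min(best_d, float(np.linalg.norm(tip - sph.center)) - sph.radius)
            if best_d <= eps:
                excess += max(0.0, float(t[j] - t[i]) - EXCESS_BURN_THRESHOLD_S)
            else:
                counts[ErrorClass.DIATHERMY_OFF_TARGET] += 1
            i = j + 1
    counts[ErrorClass.EXCESS_BURN_TIME] = int(math.ceil(excess)) if excess > 0 else 0

    # ---- off-path time
    off_path = {h: 0.0 for h in HANDS}
    if task.task_id != 3:
        for hand, path in task.ideal_path.items():
            g = [distance_point_to_polyline(traj.tips[hand][i], path)
                 - params.corridor_mm for i in range(n)]
            for ts, te in _runs(t, g, above=True):
                off_path[hand] += te - ts
    total_off = sum(off_path.values())
    counts[ErrorClass.OFF_PATH_TIME] = int(math.ceil(total_off)) if total_off > 0 else 0

    for c in ErrorClass:
        if task.task_id not in APPLICABLE_TASKS[c]:
            counts[c] = 0
    return ErrorTally(counts=counts, off_path_seconds=off_path,
                      excess_burn_seconds=excess)
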