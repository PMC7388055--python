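"""Seeded synthetic-trajectory generator at configurable skill levels.

Stands in for the tracked instruments and a human operator: for each task it
scripts a sequence of waypoints that executes the task's completion
criterion (approach, grasp, transport, place, withdraw/reinsert, cauterise),
interpolates tip motion between waypoints with minimum-jerk profiles, and
perturbs the result with two exponentially-correlated (Ornstein–Uhlenbeck)
noise processes: fast physiological tremor and slower lateral path
deviation.  Noise amplitude is modulated by planned tip speed (0.3–1×),
reflecting the speed–accuracy trade-off: a hand dwelling on a precision
action is steadier than one in mid-transport.

Errors are injected explicitly — boundary excursions, instrument-clash
sweeps, open-jaw target pokes, container-wall sweeps, off-tip shaft
touches, off-target burns, burn over-holds — at rates set by the skill
profile, and logged to an injection manifest.  Because correlated noise can
also create (or, for thin-surface contacts, occasionally mask) incidental
contact episodes, the manifest additionally carries the ground-truth error
tally of the *final* trajectory, annotated by the per-sample reference
classifier at debounce 0.  Identical (task, profile, seed) inputs give
bitwise-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .geometry import Cuboid, Cylinder, Sphere, as_point
from .metrics import ErrorTally
from .reference import reference_tally
from .tasks import ErrorClass, HANDS, TaskDefinition, load_task
from .trajio import Trajectory, write_trajectory

__all__ = [
    "SkillProfile",
    "PROFILES",
    "InjectedError",
    "InjectionManifest",
    "simulate_trajectory",
    "generate_cohort",
]


@dataclass(frozen=True)
class SkillProfile:
    """Kinematic and error-rate parameters of a simulated operator.

    Rates are per active hand; lengths mm, times s.
    """

    name: str
    speed_mm_s: float             # nominal transport speed
    tremor_sd_mm: float           # fast tremor amplitude (per axis, stationary SD)
    tremor_corr_time_s: float     # tremor correlation time
    path_deviation_sd_mm: float   # slow lateral deviation amplitude
    overshoot_prob: float         # per-opportunity probability of a precision blunder
    boundary_hit_rate_per_min: float
    clash_rate_per_min: float     # only meaningful where clash is an error (tasks 3-4)
    off_target_burn_prob: float   # per-target probability of an off-target activation
    burn_overhold_sd_s: float     # spread of extra on-target burn hold
    hesitation_s: float = 0.3     # pause at each waypoint
    wander_rate_per_min: float = 0.0  # aimless mid-task excursions

    def __post_init__(self):
        for f in ("speed_mm_s", "tremor_sd_mm", "tremor_corr_time_s",
                  "path_deviation_sd_mm", "boundary_hit_rate_per_min",
                  "clash_rate_per_min", "burn_overhold_sd_s", "hesitation_s",
                  "wander_rate_per_min"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if not (0 <= self.overshoot_prob <= 1 and 0 <= self.off_target_burn_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.speed_mm_s <= 0:
            raise ValueError("speed_mm_s must be > 0")


PROFILES: Dict[str, SkillProfile] = {
    "novice": SkillProfile(
        name="novice", speed_mm_s=25.0, tremor_sd_mm=3.0, tremor_corr_time_s=0.15,
        path_deviation_sd_mm=8.0, overshoot_prob=0.5,
        boundary_hit_rate_per_min=8.0, clash_rate_per_min=4.0,
        off_target_burn_prob=0.5, burn_overhold_sd_s=1.2,
        hesitation_s=2.0, wander_rate_per_min=6.0),
    "intermediate": SkillProfile(
        name="intermediate", speed_mm_s=60.0, tremor_sd_mm=1.8, tremor_corr_time_s=0.15,
        path_deviation_sd_mm=4.0, overshoot_prob=0.25,
        boundary_hit_rate_per_min=2.5, clash_rate_per_min=1.5,
        off_target_burn_prob=0.2, burn_overhold_sd_s=0.6,
        hesitation_s=0.8, wander_rate_per_min=2.0),
    "expert": SkillProfile(
        name="expert", speed_mm_s=110.0, tremor_sd_mm=0.8, tremor_corr_time_s=0.15,
        path_deviation_sd_mm=2.0, overshoot_prob=0.05,
        boundary_hit_rate_per_min=0.2, clash_rate_per_min=0.1,
        off_target_burn_prob=0.02, burn_overhold_sd_s=0.2,
        hesitation_s=0.2, wander_rate_per_min=0.0),
}


@dataclass(frozen=True)
class InjectedError:
    error_class: ErrorClass
    hand: str
    t_nominal: float
    magnitude: float = 1.0


@dataclass
class InjectionManifest:
    task_id: int
    profile: str
    seed: int
    injected: List[InjectedError]
    expected_tally: Optional[ErrorTally]   # None when annotation is skipped

    @property
    def injected_counts(self) -> Dict[ErrorClass, int]:
        out = {c: 0 for c in ErrorClass}
        for e in self.injected:
            out[e.error_class] += 1
        return out

    def to_json(self) -> dict:
        return {
            "task_id": self.task_id, "profile": self.profile, "seed": self.seed,
            "injected": [
                {"error_class": e.error_class.value, "hand": e.hand,
                 "t_nominal": e.t_nominal, "magnitude": e.magnitude}
                for e in self.injected],
            "expected_tally": (self.expected_tally.to_json()
                               if self.expected_tally is not None else None),
        }

    @staticmethod
    def from_json(doc: dict) -> "InjectionManifest":
        return InjectionManifest(
            task_id=doc["task_id"], profile=doc["profile"], seed=doc["seed"],
            injected=[InjectedError(ErrorClass(e["error_class"]), e["hand"],
                                    e["t_nominal"], e["magnitude"])
                      for e in doc["injected"]],
            expected_tally=(ErrorTally.from_json(doc["expected_tally"])
                            if doc.get("expected_tally") is not None else None),
        )


# --------------------------------------------------------------------------
# keyframe tracks

_SUBMOVE_MM = 30.0       # long moves split into sub-reaches with a pause each
_MIN_MOVE_S = 0.15


class _Track:
    """Per-hand keyframe timeline: positions (min-jerk interpolated) plus
    piecewise-constant jaw and diathermy states."""

    def __init__(self, start, speed: float, hesitation: float):
        self.key_t = [0.0]
        self.key_p = [np.asarray(start, dtype=float)]
        self.jaw_changes: List[Tuple[float, bool]] = [(0.0, False)]
        self.dia_changes: List[Tuple[float, bool]] = [(0.0, False)]
        self.speed = speed
        self.hesitation = hesitation

    @property
    def now(self) -> float:
        return self.key_t[-1]

    @property
    def pos(self) -> np.ndarray:
        return self.key_p[-1]

    def _append(self, dt: float, p) -> None:
        self.key_t.append(self.now + dt)
        self.key_p.append(np.asarray(p, dtype=float))

    def move_timed(self, p, dur: float) -> None:
        self._append(max(dur, 1e-3), p)

    def move_direct(self, p) -> None:
        d = float(np.linalg.norm(np.asarray(p, dtype=float) - self.pos))
        self._append(max(d / self.speed, _MIN_MOVE_S), p)

    def move(self, p, hesitate: bool = True) -> None:
        """Reach toward p in sub-moves with a pause after each."""
        p = np.asarray(p, dtype=float)
        total = float(np.linalg.norm(p - self.pos))
        n_sub = max(1, int(math.ceil(total / _SUBMOVE_MM)))
        start = self.pos.copy()
        for k in range(1, n_sub + 1):
            self.move_direct(start + (p - start) * (k / n_sub))
            if hesitate and self.hesitation > 0:
                self.hold(self.hesitation)

    def hold(self, dur: float) -> None:
        self._append(max(dur, 1e-3), self.pos)

    def set_jaw(self, closed: bool) -> None:
        self.jaw_changes.append((self.now, closed))

    def set_dia(self, on: bool) -> None:
        self.dia_changes.append((self.now, on))

    def extend_to(self, t_end: float) -> None:
        if t_end > self.now:
            self._append(t_end - self.now, self.pos)


def _sample_track(track: _Track, ts: np.ndarray):
    kt = np.asarray(track.key_t)
    kp = np.asarray(track.key_p)
    idx = np.clip(np.searchsorted(kt, ts, side="right") - 1, 0, len(kt) - 2)
    t0, t1 = kt[idx], kt[idx + 1]
    tau = np.clip((ts - t0) / (t1 - t0), 0.0, 1.0)
    h = tau ** 3 * (10.0 - 15.0 * tau + 6.0 * tau ** 2)
    pos = kp[idx] + h[:, None] * (kp[idx + 1] - kp[idx])
    jaw = _sample_state(track.jaw_changes, ts)
    dia = _sample_state(track.dia_changes, ts)
    return pos, jaw, dia


def _sample_state(changes: List[Tuple[float, bool]], ts: np.ndarray) -> np.ndarray:
    ct = np.asarray([c[0] for c in changes])
    cv = np.asarray([c[1] for c in changes], dtype=bool)
    idx = np.clip(np.searchsorted(ct, ts, side="right") - 1, 0, len(ct) - 1)
    return cv[idx]


def _ou_noise(rng: np.random.Generator, n: int, sd: float, tau: float,
              dt: float) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck process, (n, 3), exact discretisation."""
    if sd == 0.0 or n == 0:
        return np.zeros((n, 3))
    a = math.exp(-dt / max(tau, 1e-6))
    xi = rng.standard_normal((n, 3))
    x0 = rng.standard_normal(3) * sd
    drive = xi * (sd * math.sqrt(1.0 - a * a))
    drive[0] = x0
    return lfilter([1.0], [1.0, -a], drive, axis=0)


# --------------------------------------------------------------------------
# scripting


class _Sim:
    def __init__(self, task: TaskDefinition, profile: SkillProfile,
                 rng: np.random.Generator):
        self.task = task
        self.profile = profile
        self.rng = rng
        self.rest = {h: self._default_rest(h) for h in HANDS}
        self.tracks = {h: _Track(self.rest[h], profile.speed_mm_s,
                                 profile.hesitation_s) for h in HANDS}
        self.injected: List[InjectedError] = []
        self._obstacles = [s for s in task.scene.values() if isinstance(s, Sphere)]

    def _default_rest(self, hand: str) -> np.ndarray:
        if hand in self.task.ideal_path:
            return np.array(self.task.ideal_path[hand].vertices[0], dtype=float)
        return np.array([-40.0 if hand == "left" else 40.0, 95.0, 40.0])

    def sync(self) -> None:
        t_end = max(tr.now for tr in self.tracks.values())
        for tr in self.tracks.values():
            tr.extend_to(t_end)

    # ---- injections ------------------------------------------------------

    def _clear_of_obstacles(self, p, margin: float = 15.0) -> bool:
        p = np.asarray(p, dtype=float)
        return all(float(np.linalg.norm(p - s.center)) > s.radius + margin
                   for s in self._obstacles)

    def boundary_excursion(self, hand: str) -> None:
        """Push the tip 12 mm beyond a workspace wall, dwell, return."""
        ws = self.task.workspace
        tr = self.tracks[hand]
        back = tr.pos.copy()
        for _ in range(10):
            axis = int(self.rng.integers(0, 3))
            side = 1 if self.rng.random() < 0.5 else 0
            out = back.copy()
            out[axis] = (ws.max_corner[axis] + 12.0) if side else (ws.min_corner[axis] - 12.0)
            if axis == 1 and side == 0:
                continue  # the floor side holds the ports; go elsewhere
            if self._clear_of_obstacles(out):
                break
        else:
            out = back.copy()
            out[1] = ws.max_corner[1] + 12.0
        tr.move_direct(out)
        self.injected.append(InjectedError(ErrorClass.WORKSPACE_BOUNDARY, hand, tr.now))
        tr.hold(0.35)
        tr.move_direct(back)

    def wander(self, hand: str) -> None:
        """Aimless excursion to a random clear interior point and back."""
        ws = self.task.workspace
        tr = self.tracks[hand]
        back = tr.pos.copy()
        lo = ws.min_corner + 25.0
        hi = ws.max_corner - 25.0
        for _ in range(10):
            p = lo + self.rng.random(3) * (hi - lo)
            # wanders are local fidgeting, not cross-workspace trips
            d = float(np.linalg.norm(p - back))
            if d > 45.0:
                p = back + (p - back) * (45.0 / d)
            if self._clear_of_obstacles(p) and np.all((p >= lo) & (p <= hi)):
                break
        else:
            return
        tr.move_direct(p)
        tr.hold(0.2)
        tr.move_direct(back)

    def clash_sweep(self) -> None:
        """Sweep the two instruments through each other mid-workspace."""
        y, z = 185.0 + self.rng.uniform(-5, 5), 40.0 + self.rng.uniform(-5, 5)
        left, right = self.tracks["left"], self.tracks["right"]
        back = {h: self.tracks[h].pos.copy() for h in HANDS}
        left.move_direct(np.array([-12.0, y, z]))
        right.move_direct(np.array([12.0, y, z]))
        self.sync()
        dur = max(0.6, 24.0 / self.profile.speed_mm_s)
        left.move_timed(np.array([12.0, y, z]), dur)
        right.move_timed(np.array([-12.0, y, z]), dur)
        self.injected.append(InjectedError(ErrorClass.INSTRUMENT_CLASH, "both", left.now))
        left.hold(0.3)
        right.hold(0.3)
        left.move_timed(np.array([-12.0, y, z]), dur)
        right.move_timed(np.array([12.0, y, z]), dur)
        left.move_direct(back["left"])
        right.move_direct(back["right"])
        self.sync()

    def poke_target(self, hand: str, target: Sphere, approach: np.ndarray) -> None:
        """Open-jaw touch of the target sphere (an undue contact)."""
        tr = self.tracks[hand]
        tr.move_direct(target.center)
        self.injected.append(InjectedError(ErrorClass.TARGET_CONTACT_EXCESS, hand, tr.now))
        tr.hold(0.15)
        tr.move_direct(approach)

    def offtip_touch(self, hand: str, target: Sphere) -> None:
        """Place the tip beyond the target so the shaft crosses it."""
        pivot = self.task.pivots[hand]
        u = target.center - pivot
        u = u / np.linalg.norm(u)
        beyond = target.center + 25.0 * u
        ws = self.task.workspace
        if not np.all((beyond >= ws.min_corner + 5) & (beyond <= ws.max_corner - 5)):
            return
        tr = self.tracks[hand]
        # route around the target so the tip itself never pierces it
        lateral = np.cross(u, np.array([0.0, 1.0, 0.0]))
        if np.linalg.norm(lateral) < 1e-6:
            lateral = np.array([1.0, 0.0, 0.0])
        lateral = lateral / np.linalg.norm(lateral)
        side = target.center + 30.0 * lateral
        back = tr.pos.copy()
        tr.move_direct(side)
        tr.move_direct(beyond)
        self.injected.append(InjectedError(ErrorClass.OFF_TIP_CONTACT, hand, tr.now))
        tr.hold(0.3)
        tr.move_direct(side)
        tr.move_direct(back)

    def container_sweep(self, hand: str, wall: Cylinder) -> None:
        """Drag the tip through the container wall and back out."""
        tr = self.tracks[hand]
        mid = 0.5 * (wall.axis_a + wall.axis_b)
        axis = wall.axis_b - wall.axis_a
        axis = axis / np.linalg.norm(axis)
        radial = np.cross(axis, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(radial) < 1e-6:
            radial = np.cross(axis, np.array([0.0, 0.0, 1.0]))
        radial = radial / np.linalg.norm(radial)
        back = tr.pos.copy()
        tr.move_direct(mid + (wall.radius + 24.0) * radial)
        tr.move_direct(mid + 2.0 * radial)
        self.injected.append(InjectedError(ErrorClass.CONTAINER_CONTACT, hand, tr.now))
        tr.hold(0.1)
        tr.move_direct(mid + (wall.radius + 24.0) * radial)
        tr.move_direct(back)

    def n_events(self, rate_per_min: float, est_duration_s: float) -> int:
        if rate_per_min <= 0:
            return 0
        return int(self.rng.poisson(rate_per_min * est_duration_s / 60.0))

    def flip_coin(self, p: float) -> bool:
        return bool(self.rng.random() < p)

    def burn(self, hand: str, on_target: bool, duration: float,
             target_name: Optional[str] = None) -> None:
        tr = self.tracks[hand]
        tr.set_dia(True)
        if not on_target:
            self.injected.append(InjectedError(
                ErrorClass.DIATHERMY_OFF_TARGET, hand, tr.now, duration))
        elif duration > 2.0:
            self.injected.append(InjectedError(
                ErrorClass.EXCESS_BURN_TIME, hand, tr.now, duration - 2.0))
        tr.hold(duration)
        tr.set_dia(False)
        tr.hold(0.1)

    def burn_duration(self) -> float:
        base = 1.2 + 2.0 * abs(float(self.rng.normal(0.0, self.profile.burn_overhold_sd_s)))
        return min(base, 6.0)


# per-task nominal motion extent, used only to scale injection counts
_EST_PATH_MM = {1: 230.0, 2: 330.0, 3: 200.0, 4: 220.0, 5: 260.0, 6: 420.0}


def _estimate_duration_s(task: TaskDefinition, profile: SkillProfile) -> float:
    L = _EST_PATH_MM[task.task_id]
    n_wp = L / _SUBMOVE_MM
    base = L / profile.speed_mm_s + n_wp * profile.hesitation_s + 2.0
    if task.task_id in (5, 6):
        base += len(task.completion.targets) * 1.5
    return base


def _grasp(sim: _Sim, hand: str, target: Sphere) -> None:
    """Approach (with optional pokes / off-tip touch), then grasp."""
    tr = sim.tracks[hand]
    approach = target.center + 25.0 * _unit(sim.rest[hand] - target.center)
    tr.move(approach)
    n_pokes = 0
    while n_pokes < 2 and sim.flip_coin(sim.profile.overshoot_prob):
        sim.poke_target(hand, target, approach)
        n_pokes += 1
    if sim.flip_coin(sim.profile.overshoot_prob * 0.5):
        sim.offtip_touch(hand, target)
    tr.move_direct(target.center)
    tr.set_jaw(True)
    tr.hold(0.25)


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else np.array([0.0, 1.0, 0.0])


def _cautery_round(sim: _Sim, hand: str, off_point: np.ndarray) -> None:
    """Visit and burn every designated target, with off-target slips."""
    task = sim.task
    tr = sim.tracks[hand]
    for name in task.completion.targets:
        sph: Sphere = task.scene[name]  # type: ignore[assignment]
        if sim.flip_coin(sim.profile.off_target_burn_prob):
            tr.move(off_point)
            sim.burn(hand, on_target=False, duration=0.8)
        tr.move(sph.center)
        sim.burn(hand, on_target=True, duration=sim.burn_duration(),
                 target_name=name)


def _script_task(sim: _Sim) -> None:
    task, profile = sim.task, sim.profile
    est = _estimate_duration_s(task, profile)
    dom = task.dominant_hand
    other = "left" if dom == "right" else "right"

    engaged = {3: HANDS, 2: HANDS, 4: HANDS, 6: HANDS}.get(task.task_id, (dom,))
    n_boundary = {h: sim.n_events(profile.boundary_hit_rate_per_min, est)
                  for h in engaged}
    n_wander = {h: sim.n_events(profile.wander_rate_per_min, est) for h in engaged}
    n_clash = sim.n_events(profile.clash_rate_per_min, est) if task.task_id in (3, 4) else 0

    for h in engaged:
        sim.tracks[h].hold(0.3)
    sim.sync()
    # early flailing: boundary hits and clashes cluster before fine work
    for h in engaged:
        for _ in range(n_boundary[h]):
            sim.boundary_excursion(h)
    sim.sync()
    for _ in range(n_clash):
        sim.clash_sweep()

    def wander_slot(h):
        if n_wander.get(h, 0) > 0:
            sim.wander(h)
            n_wander[h] -= 1

    if task.task_id == 1:
        target: Sphere = task.scene["target"]  # type: ignore[assignment]
        goal: Cylinder = task.scene["goal"]    # type: ignore[assignment]
        tr = sim.tracks[dom]
        wander_slot(dom)
        _grasp(sim, dom, target)
        verts = task.ideal_path[dom].vertices
        above = np.array(verts[-2])
        inside = np.array(verts[-1])
        for wp in verts[2:-2]:
            tr.move(np.array(wp))
        tr.move(above)
        wander_slot(dom)
        if sim.flip_coin(profile.overshoot_prob):
            sim.container_sweep(dom, goal)
        tr.move_direct(inside)
        tr.set_jaw(False)
        tr.hold(0.3)

    elif task.task_id == 2:
        target = task.scene["target"]
        container: Cylinder = task.scene["container"]  # type: ignore[assignment]
        transfer = np.array(task.ideal_path[other].vertices[-1])
        ta, tb = sim.tracks[other], sim.tracks[dom]
        wander_slot(other)
        _grasp(sim, other, target)
        ta.move(transfer)
        tb.move(transfer + np.array([0.0, 4.0, 0.0]))
        sim.sync()
        tb.set_jaw(True)          # handoff: receiving jaw closes on the sphere
        tb.hold(0.15)
        ta.extend_to(tb.now)
        ta.set_jaw(False)
        ta.hold(0.15)
        # retrace the grab path so the empty hand stays in its corridor
        for wp in task.ideal_path[other].vertices[::-1][1:]:
            ta.move(np.array(wp))
        above = np.array(task.ideal_path[dom].vertices[2])
        inside = np.array(task.ideal_path[dom].vertices[3])
        tb.move(above)
        wander_slot(dom)
        if sim.flip_coin(profile.overshoot_prob):
            sim.container_sweep(dom, container)
        tb.move_direct(inside)
        tb.set_jaw(False)
        tb.hold(0.2)
        tb.move_direct(above)
        sim.sync()

    elif task.task_id == 3:
        for h in HANDS:
            path = task.ideal_path[h]
            end = np.array(path.vertices[-1])
            sim.tracks[h].move(end)
        sim.sync()
        for h in HANDS:
            wander_slot(h)
        sim.sync()

    elif task.task_id == 4:
        oval: Sphere = task.scene["oval"]  # type: ignore[assignment]
        stab = other if task.removal_hand == dom else dom
        rem = task.removal_hand or dom
        stab_point = oval.center + np.array(
            [16.0 if stab == "right" else -16.0, 10.0, 6.0])
        sim.tracks[stab].move(stab_point)
        tr = sim.tracks[rem]
        hold_pt = np.array(task.ideal_path[rem].vertices[1])
        retract = np.array(task.ideal_path[rem].vertices[2])
        tr.move(hold_pt)
        n_oval = sum(sim.flip_coin(profile.overshoot_prob) for _ in range(4))
        for k in range(n_oval):
            tr.move_direct(oval.center)
            if k >= task.permitted_oval_contacts:
                sim.injected.append(InjectedError(
                    ErrorClass.OVAL_CONTACT_EXCESS, rem, tr.now))
            tr.hold(0.15)
            tr.move_direct(hold_pt)
        for _ in range(task.completion.reinsertion_count):
            wander_slot(rem)
            tr.move(retract)
            tr.hold(0.4)
            tr.move(hold_pt)
        sim.sync()

    elif task.task_id == 5:
        base: Sphere = task.scene["base"]  # type: ignore[assignment]
        off_point = base.center + np.array([0.0, -40.0, 40.0])
        wander_slot(dom)
        _cautery_round(sim, dom, off_point)
        sim.sync()

    elif task.task_id == 6:
        target = task.scene["target"]
        cube: Cuboid = task.scene["cube"]  # type: ignore[assignment]
        base = task.scene["base"]
        off_point = base.center + np.array([0.0, -45.0, 35.0])
        # the two hands work in parallel: dominant places, the other cauterises
        tr = sim.tracks[dom]
        wander_slot(dom)
        _grasp(sim, dom, target)
        tr.move(np.array(cube.center))
        tr.set_jaw(False)
        tr.hold(0.2)
        wander_slot(other)
        _cautery_round(sim, other, off_point)
        sim.sync()

    for h in HANDS:
        sim.tracks[h].hold(0.3)
    sim.sync()


# --------------------------------------------------------------------------
# public API


def simulate_trajectory(
    task: TaskDefinition,
    profile: SkillProfile,
    seed: int,
    duration_cap_s: Optional[float] = None,
    sample_rate_hz: float = 60.0,
    annotate: bool = True,
) -> Tuple[Trajectory, InjectionManifest]:
    """Generate one seeded session trajectory plus its injection manifest.

    The manifest lists every deliberately injected error and carries the
    ground-truth error tally of the generated trajectory (reference
    classifier, debounce 0); pass ``annotate=False`` to skip the (slow)
    annotation when only the trajectory is needed.
    """
    rng = np.random.default_rng(seed)
    sim = _Sim(task, profile, rng)
    _script_task(sim)

    t_end = max(tr.now for tr in sim.tracks.values())
    if duration_cap_s is not None:
        t_end = min(t_end, duration_cap_s)
    dt = 1.0 / sample_rate_hz
    n = max(int(math.floor(t_end / dt)) + 1, 2)
    ts = np.arange(n) * dt

    tips, jaw, dia = {}, {}, {}
    for hand in HANDS:
        plan, jaw[hand], dia[hand] = _sample_track(sim.tracks[hand], ts)
        speed = np.linalg.norm(np.gradient(plan, dt, axis=0), axis=1)
        scale = 0.3 + 0.7 * np.clip(speed / profile.speed_mm_s, 0.0, 1.0)
        tremor = _ou_noise(rng, n, profile.tremor_sd_mm,
                           profile.tremor_corr_time_s, dt)
        drift = _ou_noise(rng, n, profile.path_deviation_sd_mm, 0.8, dt)
        tips[hand] = plan + scale[:, None] * (tremor + drift)

    traj = Trajectory(
        t=ts, tips=tips, jaw_closed=jaw, diathermy_on=dia,
        task_id=task.task_id, dominant_hand=task.dominant_hand,
        sample_rate_hz=sample_rate_hz,
        metadata={"profile": profile.name, "seed": int(seed), "synthetic": True},
    )
    tally = reference_tally(traj, task) if annotate else None
    manifest = InjectionManifest(task.task_id, profile.name, int(seed),
                                 sim.injected, tally)
    return traj, manifest


def generate_cohort(
    task_ids: Sequence[int],
    profiles: Sequence[SkillProfile],
    n_per_cell: int,
    base_seed: int,
    out_dir,
    fmt: str = "csv",
) -> "pd.DataFrame":
    """Simulate ``n_per_cell`` sessions per (task, profile) cell.

    Writes one trajectory file and one manifest JSON per session plus an
    ``index.csv``; seeds derive deterministically from ``base_seed`` by
    counter.  Returns the index as a DataFrame.
    """
    import pandas as pd

    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    counter = 0
    for task_id in task_ids:
        task = load_task(task_id)
        for profile in profiles:
            for rep in range(n_per_cell):
                seed = (int(base_seed) * 1000003 + counter) % (2 ** 31 - 1)
                counter += 1
                traj, manifest = simulate_trajectory(task, profile, seed)
                stem = f"task{task_id}_{profile.name}_rep{rep:03d}"
                fname = f"{stem}.{ 'jsonl' if fmt == 'jsonl' else 'csv' }"
                write_trajectory(traj, out / fname, fmt)
                (out / f"{stem}.manifest.json").write_text(
                    json.dumps(manifest.to_json(), indent=2) + "\n")
                row = {"file": fname, "task_id": task_id, "profile": profile.name,
                       "seed": seed, "rep": rep,
                       "duration_s": traj.duration}
                for c in ErrorClass:
                    row[f"injected_{c.value}"] = manifest.injected_counts[c]
                    row[f"expected_{c.value}"] = manifest.expected_tally.counts[c]  # annotated
                rows.append(row)
    index = pd.DataFrame(rows)
    index.to_csv(out / "index.csv", index=False)
    return index
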