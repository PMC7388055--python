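"""Registry of the six training tasks and the weighted error taxonomy.

The simulator assesses six abstract minimally-invasive-surgery tasks (grip
and placement, transfer, bimanual traversal, instrument withdrawal and
reinsertion, diathermy, combined manipulation plus diathermy).  Performance
errors fall into nine classes, each applicable to a fixed subset of tasks
and weighted 1–5 (1 least important, 5 most); the final score is
``100 - sum(count * weight)``.

Scene layouts ship as package defaults and can be overridden by a scene JSON
file; the dimensions themselves (workspace cube, sphere radii, trocar pivot
positions) are engine defaults chosen to sit comfortably inside a
~20–600 mm optical-tracking volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .geometry import Cuboid, Cylinder, Point3, Polyline3, Shape, Sphere, as_point

__all__ = [
    "ErrorClass",
    "APPLICABLE_TASKS",
    "DEFAULT_WEIGHTS",
    "CompletionKind",
    "CompletionCriterion",
    "TaskDefinition",
    "TASK_IDS",
    "load_task",
    "default_weights",
    "validate_weights",
    "merge_weights",
    "task_error_classes",
]

TASK_IDS: Tuple[int, ...] = (1, 2, 3, 4, 5, 6)

HANDS = ("left", "right")


class ErrorClass(str, Enum):
    """The nine performance-error classes."""

    OFF_TIP_CONTACT = "OFF_TIP_CONTACT"              # target touched by shaft, not tip
    WORKSPACE_BOUNDARY = "WORKSPACE_BOUNDARY"        # instrument hits workspace limits
    TARGET_CONTACT_EXCESS = "TARGET_CONTACT_EXCESS"  # undue contacts with target sphere
    CONTAINER_CONTACT = "CONTAINER_CONTACT"          # instrument/sphere hits container margin
    INSTRUMENT_CLASH = "INSTRUMENT_CLASH"            # undue contact between the instruments
    OVAL_CONTACT_EXCESS = "OVAL_CONTACT_EXCESS"      # contacts with the oval beyond permitted
    OFF_PATH_TIME = "OFF_PATH_TIME"                  # seconds the tip spent off the ideal path
    DIATHERMY_OFF_TARGET = "DIATHERMY_OFF_TARGET"    # burn outside the stated objectives
    EXCESS_BURN_TIME = "EXCESS_BURN_TIME"            # on-target burn beyond 2 s


# Per-task applicability of each error class.
APPLICABLE_TASKS: Dict[ErrorClass, frozenset] = {
    ErrorClass.OFF_TIP_CONTACT: frozenset({1, 2, 3, 4, 5, 6}),
    ErrorClass.WORKSPACE_BOUNDARY: frozenset({1, 2, 3, 4, 5, 6}),
    ErrorClass.TARGET_CONTACT_EXCESS: frozenset({1, 2}),
    ErrorClass.CONTAINER_CONTACT: frozenset({1, 2}),
    ErrorClass.INSTRUMENT_CLASH: frozenset({3, 4}),
    ErrorClass.OVAL_CONTACT_EXCESS: frozenset({4}),
    ErrorClass.OFF_PATH_TIME: frozenset({1, 2, 4, 6}),
    ErrorClass.DIATHERMY_OFF_TARGET: frozenset({5, 6}),
    ErrorClass.EXCESS_BURN_TIME: frozenset({5, 6}),
}

# Off-target diathermy carries the maximum weight 5; the remaining classes
# rank by severity within [1, 5] and are fully user-configurable.
DEFAULT_WEIGHTS: Dict[ErrorClass, int] = {
    ErrorClass.OFF_TIP_CONTACT: 3,
    ErrorClass.WORKSPACE_BOUNDARY: 2,
    ErrorClass.TARGET_CONTACT_EXCESS: 2,
    ErrorClass.CONTAINER_CONTACT: 2,
    ErrorClass.INSTRUMENT_CLASH: 2,
    ErrorClass.OVAL_CONTACT_EXCESS: 3,
    ErrorClass.OFF_PATH_TIME: 1,
    ErrorClass.DIATHERMY_OFF_TARGET: 5,
    ErrorClass.EXCESS_BURN_TIME: 4,
}


class CompletionKind(str, Enum):
    PLACED_IN_SHAPE = "PLACED_IN_SHAPE"
    TRANSFER_THEN_PLACED = "TRANSFER_THEN_PLACED"
    TRAVERSAL_COMPLETE = "TRAVERSAL_COMPLETE"
    REMOVE_REINSERT_COUNT = "REMOVE_REINSERT_COUNT"
    ALL_TARGETS_CAUTERIZED = "ALL_TARGETS_CAUTERIZED"
    PLACED_AND_CAUTERIZED = "PLACED_AND_CAUTERIZED"


COMPLETION_BY_TASK = {
    1: CompletionKind.PLACED_IN_SHAPE,
    2: CompletionKind.TRANSFER_THEN_PLACED,
    3: CompletionKind.TRAVERSAL_COMPLETE,
    4: CompletionKind.REMOVE_REINSERT_COUNT,
    5: CompletionKind.ALL_TARGETS_CAUTERIZED,
    6: CompletionKind.PLACED_AND_CAUTERIZED,
}


@dataclass(frozen=True)
class CompletionCriterion:
    kind: CompletionKind
    goal_shape: Optional[str] = None          # placement goal (tasks 1, 2, 6)
    traversal_fraction: float = 0.95          # task 3
    reinsertion_count: int = 1                # task 4, per configured hand
    targets: Tuple[str, ...] = ()             # cautery targets (tasks 5, 6)


@dataclass(frozen=True)
class TaskDefinition:
    task_id: int
    name: str
    surgical_equivalent: str
    scene: Dict[str, Shape]
    pivots: Dict[str, Point3]                 # trocar pivot per hand
    ideal_path: Dict[str, Polyline3]          # per hand; may be empty per hand
    completion: CompletionCriterion
    dominant_hand: str = "right"
    dominant_hand_configurable: bool = True
    bimanual: bool = False
    grasp_target: Optional[str] = None        # graspable sphere name
    container: Optional[str] = None           # container shape name (tasks 1, 2)
    oval: Optional[str] = None                # task 4
    permitted_oval_contacts: int = 2          # task 4
    removal_hand: Optional[str] = None        # task 4: hand that withdraws/reinserts

    @property
    def workspace(self) -> Cuboid:
        ws = self.scene["workspace"]
        assert isinstance(ws, Cuboid)
        return ws

    @property
    def error_classes(self) -> Tuple[ErrorClass, ...]:
        return task_error_classes(self.task_id)

    def to_json(self) -> dict:
        return {
            "task_id": self.task_id,
            "name": self.name,
            "surgical_equivalent": self.surgical_equivalent,
            "shapes": [_shape_to_json(n, s) for n, s in self.scene.items()],
            "pivots": {h: list(map(float, p)) for h, p in self.pivots.items()},
            "ideal_path": {
                h: [list(map(float, v)) for v in p.vertices]
                for h, p in self.ideal_path.items()
            },
            "completion": {
                "kind": self.completion.kind.value,
                "goal_shape": self.completion.goal_shape,
                "traversal_fraction": self.completion.traversal_fraction,
                "reinsertion_count": self.completion.reinsertion_count,
                "targets": list(self.completion.targets),
            },
            "dominant_hand": self.dominant_hand,
            "dominant_hand_configurable": self.dominant_hand_configurable,
            "bimanual": self.bimanual,
            "grasp_target": self.grasp_target,
            "container": self.container,
            "oval": self.oval,
            "permitted_oval_contacts": self.permitted_oval_contacts,
            "removal_hand": self.removal_hand,
        }

    @staticmethod
    def from_json(doc: dict) -> "TaskDefinition":
        _require(doc, "task_id", int, "$")
        scene = {}
        for i, sh in enumerate(doc.get("shapes", [])):
            name, shape = _shape_from_json(sh, f"$.shapes[{i}]")
            scene[name] = shape
        comp = doc["completion"]
        return TaskDefinition(
            task_id=doc["task_id"],
            name=doc["name"],
            surgical_equivalent=doc["surgical_equivalent"],
            scene=scene,
            pivots={h: as_point(p) for h, p in doc["pivots"].items()},
            ideal_path={
                h: Polyline3(np.asarray(v, dtype=float))
                for h, v in doc.get("ideal_path", {}).items()
            },
            completion=CompletionCriterion(
                kind=CompletionKind(comp["kind"]),
                goal_shape=comp.get("goal_shape"),
                traversal_fraction=comp.get("traversal_fraction", 0.95),
                reinsertion_count=comp.get("reinsertion_count", 1),
                targets=tuple(comp.get("targets", ())),
            ),
            dominant_hand=doc.get("dominant_hand", "right"),
            dominant_hand_configurable=doc.get("dominant_hand_configurable", True),
            bimanual=doc.get("bimanual", False),
            grasp_target=doc.get("grasp_target"),
            container=doc.get("container"),
            oval=doc.get("oval"),
            permitted_oval_contacts=doc.get("permitted_oval_contacts", 2),
            removal_hand=doc.get("removal_hand"),
        )


def task_error_classes(task_id: int) -> Tuple[ErrorClass, ...]:
    _check_task_id(task_id)
    return tuple(c for c in ErrorClass if task_id in APPLICABLE_TASKS[c])


def default_weights() -> Dict[ErrorClass, int]:
    return dict(DEFAULT_WEIGHTS)


def merge_weights(base: Dict[ErrorClass, int], override: Dict) -> Dict[ErrorClass, int]:
    """Apply a user override (class name or ErrorClass keyed) onto a table."""
    out = dict(base)
    for k, v in override.items():
        out[ErrorClass(k)] = v
    return out


def validate_weights(table: Dict[ErrorClass, int]) -> List[str]:
    """Return a list of human-readable violations; empty list means valid."""
    violations = []
    for cls in ErrorClass:
        if cls not in table:
            violations.append(f"missing class {cls.value}")
            continue
        v = table[cls]
        if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
            violations.append(f"weight for {cls.value} must be an integer, got {v!r}")
        elif not (1 <= v <= 5):
            violations.append(f"weight for {cls.value} must lie in [1, 5], got {v}")
    for k in table:
        if not isinstance(k, ErrorClass):
            violations.append(f"unknown error class {k!r}")
    return violations


# --------------------------------------------------------------------------
# Default scene geometry (mm).  Workspace: 200 mm cube centred 150 mm above
# the pad origin; trocar pivots sit below/outside it like body-wall ports.

_WORKSPACE = Cuboid((-100.0, 50.0, -100.0), (100.0, 250.0, 100.0))
_PIVOTS = {"left": as_point((-60.0, 40.0, 60.0)), "right": as_point((60.0, 40.0, 60.0))}
# per-hand rest position: where an idle instrument parks, and where each
# ideal path begins
_REST = {"left": as_point((-40.0, 95.0, 40.0)), "right": as_point((40.0, 95.0, 40.0))}

_TASK_NAMES = {
    1: ("Grip and placement",
        "Gripping and retraction of a tissue to a given position, placement of "
        "clips and hemostasis, and use of extractor bags"),
    2: ("Transfer and placement of an object",
        "Transfer of a needle between a clamp and a needle holder"),
    3: ("Cross", "Small intestine exploration"),
    4: ("Removal and reinsertion of instruments",
        "One instrument stabilizes one organ while the other is removed from "
        "the field and reintroduced"),
    5: ("Diathermy", "Cauterize a bleeding blood vessel"),
    6: ("Target manipulation and diathermy", "Present and set a target to cauterize"),
}


def _cautery_targets(center, base_radius: float, target_radius: float = 5.0, n: int = 5):
    """n small target spheres along a horizontal arc on the front of a base
    sphere.  Keeping the targets at one height means the instrument shaft
    (which descends steeply toward the trocar pivot) clears the neighbouring
    targets while one of them is being cauterised."""
    center = as_point(center)
    phis = np.deg2rad(np.linspace(-80.0, 80.0, n))
    dirs = np.stack([np.sin(phis), np.full(n, 0.28), np.cos(phis)], axis=1)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    shapes = {}
    for i, d in enumerate(dirs):
        shapes[f"target_{i + 1}"] = Sphere(center + base_radius * d, target_radius)
    return shapes


def _mirror_x(p):
    p = as_point(p)
    return np.array([-p[0], p[1], p[2]])


def _build_default_task(task_id: int, dominant_hand: str) -> TaskDefinition:
    name, equiv = _TASK_NAMES[task_id]
    scene: Dict[str, Shape] = {"workspace": _WORKSPACE}
    other = "left" if dominant_hand == "right" else "right"
    sgn = 1.0 if dominant_hand == "right" else -1.0

    def flip(p):
        return as_point(p) if sgn > 0 else _mirror_x(p)

    if task_id == 1:
        target = Sphere(flip((-30.0, 120.0, 0.0)), 8.0)
        goal = Cylinder(flip((40.0, 115.0, 30.0)), flip((40.0, 160.0, 30.0)), 15.0, hollow=True)
        scene.update(target=target, goal=goal)
        lift = flip((-30.0, 185.0, 0.0))      # lift clear of the rim first
        above = flip((40.0, 185.0, 30.0))
        inside = flip((40.0, 135.0, 30.0))
        ideal = Polyline3(
            np.array([_REST[dominant_hand], target.center, lift, above, inside])
        )
        return TaskDefinition(
            task_id=1, name=name, surgical_equivalent=equiv, scene=scene,
            pivots=dict(_PIVOTS), ideal_path={dominant_hand: ideal},
            completion=CompletionCriterion(CompletionKind.PLACED_IN_SHAPE, goal_shape="goal"),
            dominant_hand=dominant_hand, grasp_target="target", container="goal",
        )

    if task_id == 2:
        target = Sphere(flip((-45.0, 140.0, 0.0)), 8.0)
        container = Cylinder(flip((45.0, 100.0, 0.0)), flip((45.0, 145.0, 0.0)), 15.0, hollow=True)
        scene.update(target=target, container=container)
        transfer = as_point((0.0, 160.0, 10.0))
        inside = flip((45.0, 120.0, 0.0))
        above = flip((45.0, 170.0, 0.0))
        path_grab = Polyline3(np.array([_REST[other], target.center, transfer]))
        path_recv = Polyline3(np.array([_REST[dominant_hand], transfer, above, inside]))
        return TaskDefinition(
            task_id=2, name=name, surgical_equivalent=equiv, scene=scene,
            pivots=dict(_PIVOTS),
            ideal_path={other: path_grab, dominant_hand: path_recv},
            completion=CompletionCriterion(CompletionKind.TRANSFER_THEN_PLACED, goal_shape="container"),
            dominant_hand=dominant_hand, grasp_target="target", container="container",
        )

    if task_id == 3:
        tube = Cylinder((-50.0, 150.0, 0.0), (50.0, 150.0, 0.0), 20.0)
        scene.update(tube=tube)
        left_path = Polyline3(np.array([(-50.0, 170.0, 0.0), (50.0, 170.0, 0.0)]))
        right_path = Polyline3(np.array([(-50.0, 150.0, 20.0), (50.0, 150.0, 20.0)]))
        return TaskDefinition(
            task_id=3, name=name, surgical_equivalent=equiv, scene=scene,
            pivots=dict(_PIVOTS),
            ideal_path={"left": left_path, "right": right_path},
            completion=CompletionCriterion(CompletionKind.TRAVERSAL_COMPLETE, traversal_fraction=0.95),
            dominant_hand="right", dominant_hand_configurable=False, bimanual=True,
        )

    if task_id == 4:
        oval = Sphere((0.0, 150.0, 0.0), 12.0)
        scene.update(oval=oval)
        pivot = _PIVOTS[dominant_hand]
        axis = _WORKSPACE.center - pivot
        axis = axis / np.linalg.norm(axis)
        hold = flip((25.0, 135.0, 20.0))
        retract = pivot + 52.0 * axis
        # out and back: the reinsertion return leg is part of the ideal motion
        ideal = Polyline3(np.array([_REST[dominant_hand], hold, retract, hold]))
        return TaskDefinition(
            task_id=4, name=name, surgical_equivalent=equiv, scene=scene,
            pivots=dict(_PIVOTS), ideal_path={dominant_hand: ideal},
            completion=CompletionCriterion(CompletionKind.REMOVE_REINSERT_COUNT, reinsertion_count=1),
            dominant_hand=dominant_hand, oval="oval", permitted_oval_contacts=2,
            removal_hand=dominant_hand,
        )

    if task_id == 5:
        base = Sphere((0.0, 150.0, -30.0), 20.0)
        targets = _cautery_targets(base.center, base.radius)
        scene.update(base=base, **targets)
        return TaskDefinition(
            task_id=5, name=name, surgical_equivalent=equiv, scene=scene,
            pivots=dict(_PIVOTS), ideal_path={},
            completion=CompletionCriterion(
                CompletionKind.ALL_TARGETS_CAUTERIZED, targets=tuple(sorted(targets))
            ),
            dominant_hand=dominant_hand,
        )

    if task_id == 6:
        # the grasp/place lane (toward the user, +z) stays clear of the
        # cautery hand's shaft plane, which hangs below the elevated targets
        target = Sphere(flip((-50.0, 120.0, 45.0)), 8.0)
        cube = flip_cuboid((20.0, 115.0, -25.0), (70.0, 165.0, 25.0), sgn)
        base = Sphere(flip((-20.0, 195.0, -20.0)), 18.0)
        targets = _cautery_targets(base.center, base.radius)
        scene.update(target=target, cube=cube[0], base=base, **targets)
        ideal = Polyline3(
            np.array([_REST[dominant_hand], target.center, cube[0].center])
        )
        return TaskDefinition(
            task_id=6, name=name, surgical_equivalent=equiv, scene=scene,
            pivots=dict(_PIVOTS), ideal_path={dominant_hand: ideal},
            completion=CompletionCriterion(
                CompletionKind.PLACED_AND_CAUTERIZED, goal_shape="cube",
                targets=tuple(sorted(targets)),
            ),
            dominant_hand=dominant_hand, grasp_target="target",
        )

    raise AssertionError(task_id)


def flip_cuboid(lo, hi, sgn):
    """Mirror an axis-aligned box across the x=0 plane when sgn < 0."""
    lo, hi = as_point(lo), as_point(hi)
    if sgn > 0:
        return (Cuboid(lo, hi),)
    lo2 = np.array([-hi[0], lo[1], lo[2]])
    hi2 = np.array([-lo[0], hi[1], hi[2]])
    return (Cuboid(lo2, hi2),)


def _check_task_id(task_id: int) -> None:
    if task_id not in TASK_IDS:
        raise ValueError(f"unknown task_id {task_id!r}; expected one of {TASK_IDS}")


def load_task(
    task_id: int,
    scene_file: Optional[str] = None,
    dominant_hand: str = "right",
) -> TaskDefinition:
    """Build a task definition, optionally overridden by a scene JSON file.

    Task 3 is bimanual and ignores ``dominant_hand``.
    """
    _check_task_id(task_id)
    if dominant_hand not in HANDS:
        raise ValueError(f"dominant_hand must be 'left' or 'right', got {dominant_hand!r}")
    task = _build_default_task(task_id, dominant_hand)
    if scene_file is not None:
        doc = json.loads(Path(scene_file).read_text())
        task = _apply_scene_override(task, doc)
    return task


def _apply_scene_override(task: TaskDefinition, doc: dict) -> TaskDefinition:
    if not isinstance(doc, dict):
        raise SceneError("$", "scene document must be a JSON object")
    if "task_id" in doc and doc["task_id"] != task.task_id:
        raise SceneError("$.task_id", f"scene is for task {doc['task_id']}, not {task.task_id}")
    scene = dict(task.scene)
    for i, sh in enumerate(doc.get("shapes", [])):
        name, shape = _shape_from_json(sh, f"$.shapes[{i}]")
        scene[name] = shape
    pivots = dict(task.pivots)
    for h, p in doc.get("pivots", {}).items():
        if h not in HANDS:
            raise SceneError("$.pivots", f"unknown hand {h!r}")
        pivots[h] = as_point(p)
    ideal = dict(task.ideal_path)
    for h, verts in doc.get("ideal_path", {}).items():
        if h not in HANDS:
            raise SceneError("$.ideal_path", f"unknown hand {h!r}")
        ideal[h] = Polyline3(np.asarray(verts, dtype=float))
    kwargs = {}
    if "permitted_oval_contacts" in doc:
        kwargs["permitted_oval_contacts"] = int(doc["permitted_oval_contacts"])
    if "targets" in doc:
        kwargs["completion"] = replace(task.completion, targets=tuple(doc["targets"]))
    return replace(task, scene=scene, pivots=pivots, ideal_path=ideal, **kwargs)


class SceneError(ValueError):
    """Scene JSON violation, reported with the JSON path of the offence."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


def _require(doc: dict, key: str, typ, path: str):
    if key not in doc:
        raise SceneError(f"{path}.{key}", "missing required field")
    if typ is not None and not isinstance(doc[key], typ):
        raise SceneError(f"{path}.{key}", f"expected {typ.__name__}")
    return doc[key]


def _shape_to_json(name: str, s: Shape) -> dict:
    if isinstance(s, Sphere):
        return {"name": name, "kind": "sphere", "center": list(map(float, s.center)),
                "radius": s.radius}
    if isinstance(s, Cylinder):
        return {"name": name, "kind": "cylinder", "axis_a": list(map(float, s.axis_a)),
                "axis_b": list(map(float, s.axis_b)), "radius": s.radius, "hollow": s.hollow}
    if isinstance(s, Cuboid):
        return {"name": name, "kind": "cuboid", "min_corner": list(map(float, s.min_corner)),
                "max_corner": list(map(float, s.max_corner))}
    raise TypeError(type(s).__name__)


def _shape_from_json(doc: dict, path: str):
    name = _require(doc, "name", str, path)
    kind = _require(doc, "kind", str, path)
    try:
        if kind == "sphere":
            return name, Sphere(_require(doc, "center", list, path),
                                float(_require(doc, "radius", (int, float), path)))
        if kind == "cylinder":
            return name, Cylinder(_require(doc, "axis_a", list, path),
                                  _require(doc, "axis_b", list, path),
                                  float(_require(doc, "radius", (int, float), path)),
                                  bool(doc.get("hollow", False)))
        if kind == "cuboid":
            return name, Cuboid(_require(doc, "min_corner", list, path),
                                _require(doc, "max_corner", list, path))
    except ValueError as e:
        raise SceneError(path, str(e)) from e
    raise SceneError(f"{path}.kind", f"unknown shape kind {kind!r}")
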