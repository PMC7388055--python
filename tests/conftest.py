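import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from lapskill.tasks import HANDS, TaskDefinition, load_task
from lapskill.trajio import Trajectory


@pytest.fixture(scope="session")
def tasks() -> dict:
    return {tid: load_task(tid) for tid in range(1, 7)}


def make_trajectory(t, right_tips, left_tips=None, right_jaw=None,
                    right_dia=None, left_jaw=None, left_dia=None,
                    task_id=0) -> Trajectory:
    """Build a trajectory from per-sample arrays; the left hand parks at a
    fixed point unless given."""
    t = np.asarray(t, dtype=float)
    n = t.size
    right_tips = np.asarray(right_tips, dtype=float)
    if left_tips is None:
        left_tips = np.tile(np.array([-40.0, 95.0, 40.0]), (n, 1))
    zeros = np.zeros(n, dtype=bool)
    return Trajectory(
        t=t,
        tips={"left": np.asarray(left_tips, float), "right": right_tips},
        jaw_closed={"left": zeros.copy() if left_jaw is None else np.asarray(left_jaw, bool),
                    "right": zeros.copy() if right_jaw is None else np.asarray(right_jaw, bool)},
        diathermy_on={"left": zeros.copy() if left_dia is None else np.asarray(left_dia, bool),
                      "right": zeros.copy() if right_dia is None else np.asarray(right_dia, bool)},
        task_id=task_id,
    )


def random_smooth_trajectory(rng: np.random.Generator, task: TaskDefinition,
                             duration_s: float = 3.0, fs: float = 60.0) -> Trajectory:
    """Random correlated motion roaming around the task scene, with random
    jaw and diathermy toggles — input for oracle-equivalence checks."""
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    center = task.workspace.center
    tips, jaw, dia = {}, {}, {}
    for hand in HANDS:
        steps = rng.normal(0.0, 6.0, (n, 3))
        walk = np.cumsum(steps, axis=0)
        # low-pass the walk and keep it loosely tethered to the scene centre
        kernel = np.ones(9) / 9.0
        sm = np.stack([np.convolve(walk[:, k], kernel, mode="same")
                       for k in range(3)], axis=1)
        sm -= sm.mean(axis=0)
        offset = center + rng.normal(0.0, 40.0, 3)
        tips[hand] = offset + sm * 0.9
        jaw[hand] = rng.random(n) < 0.5
        # longer coherent jaw/dia stretches
        jaw[hand] = np.repeat(jaw[hand][::10], 10)[:n]
        dia_runs = rng.random(n // 15 + 1) < 0.3
        dia[hand] = np.repeat(dia_runs, 15)[:n]
    return Trajectory(t=t, tips=tips, jaw_closed=jaw, diathermy_on=dia,
                      task_id=task.task_id)
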