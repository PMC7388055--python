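from dataclasses import replace

import numpy as np
import pytest

from lapskill.events import DetectionParams, detect_events
from lapskill.metrics import movement_efficiency, score_session, tally_errors
from lapskill.simulator import (
    PROFILES,
    InjectionManifest,
    SkillProfile,
    generate_cohort,
    simulate_trajectory,
)
from lapskill.tasks import ErrorClass, load_task
from lapskill.trajio import read_trajectory, write_trajectory


def _noiseless(profile: SkillProfile) -> SkillProfile:
    return replace(profile, name="custom", tremor_sd_mm=0.0,
                   path_deviation_sd_mm=0.0, overshoot_prob=0.0,
                   boundary_hit_rate_per_min=0.0, clash_rate_per_min=0.0,
                   off_target_burn_prob=0.0, burn_overhold_sd_s=0.0,
                   wander_rate_per_min=0.0)


class TestProfiles:
    def test_skill_ordering_of_noise_parameters(self):
        nov, mid, exp = (PROFILES[k] for k in ("novice", "intermediate", "expert"))
        assert exp.tremor_sd_mm <= mid.tremor_sd_mm <= nov.tremor_sd_mm
        assert exp.path_deviation_sd_mm <= mid.path_deviation_sd_mm <= nov.path_deviation_sd_mm

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            replace(PROFILES["expert"], boundary_hit_rate_per_min=-1.0)


class TestNoiselessLimit:
    @pytest.mark.parametrize("tid", [1, 4, 6])
    def test_follows_ideal_path_exactly(self, tid):
        """With zero tremor/deviation and no injections the dominant hand
        stays on the ideal path: no off-path time, negligible path excess."""
        task = load_task(tid)
        profile = _noiseless(PROFILES["expert"])
        traj, manifest = simulate_trajectory(task, profile, seed=5, annotate=False)
        hand = task.dominant_hand
        excess, off = movement_efficiency(traj, hand, task)
        assert off == 0.0
        assert excess < 1.0
        assert manifest.injected == []

    @pytest.mark.parametrize("tid", range(1, 7))
    def test_completes_every_task(self, tid):
        task = load_task(tid)
        traj, _ = simulate_trajectory(task, _noiseless(PROFILES["expert"]),
                                      seed=6, annotate=False)
        assert score_session(traj, task).completed

    @pytest.mark.parametrize("tid", range(1, 7))
    def test_noiseless_run_commits_no_errors(self, tid):
        task = load_task(tid)
        traj, _ = simulate_trajectory(task, _noiseless(PROFILES["expert"]),
                                      seed=7, annotate=False)
        res = score_session(traj, task)
        assert res.final_score == 100.0


class TestDeterminism:
    def test_same_seed_gives_identical_csv_bytes(self, tmp_path):
        task = load_task(3)
        for name in ("a", "b"):
            traj, _ = simulate_trajectory(task, PROFILES["novice"], seed=77)
            write_trajectory(traj, tmp_path / f"{name}.csv", "csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_different_seeds_differ(self):
        task = load_task(1)
        t1, _ = simulate_trajectory(task, PROFILES["novice"], seed=1, annotate=False)
        t2, _ = simulate_trajectory(task, PROFILES["novice"], seed=2, annotate=False)
        assert not (t1.n_samples == t2.n_samples
                    and np.array_equal(t1.tips["right"], t2.tips["right"]))


class TestFulcrumConsistency:
    def test_shaft_passes_through_pivot(self):
        """Reconstructed shaft from any sample contains the trocar pivot."""
        from lapskill.trajio import pose_at
        from lapskill.geometry import distance_point_to_segment

        task = load_task(2)
        traj, _ = simulate_trajectory(task, PROFILES["intermediate"], seed=8,
                                      annotate=False)
        rng = np.random.default_rng(0)
        for i in rng.integers(0, traj.n_samples, 25):
            for hand in ("left", "right"):
                pose = pose_at(traj, hand, int(i), task)
                d = distance_point_to_segment(task.pivots[hand],
                                              pose.shaft.a, pose.shaft.b)
                assert d < 1e-6


class TestNoiseScaling:
    def test_doubling_tremor_increases_off_path_time(self):
        """Paired one-sided sign test over seeds: doubling the tremor SD
        produces more off-path time in (almost) every pair."""
        task = load_task(1)
        base = replace(PROFILES["intermediate"], name="custom",
                       overshoot_prob=0.0, boundary_hit_rate_per_min=0.0,
                       clash_rate_per_min=0.0, wander_rate_per_min=0.0,
                       tremor_sd_mm=4.0, path_deviation_sd_mm=4.0)
        doubled = replace(base, tremor_sd_mm=8.0, path_deviation_sd_mm=8.0)
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            offs = []
            for prof in (base, doubled):
                traj, _ = simulate_trajectory(task, prof, seed=seed, annotate=False)
                _, off = movement_efficiency(traj, task.dominant_hand, task)
                offs.append(off)
            wins += offs[1] > offs[0]
        # one-sided binomial: >= 21/30 rejects "no effect" at p < 0.025
        assert wins >= 21


class TestManifest:
    def test_injected_events_are_detected(self):
        """Injected boundary hits and off-target burns always surface as
        detected episodes (they are geometrically deep injections)."""
        task = load_task(5)
        traj, manifest = simulate_trajectory(task, PROFILES["novice"], seed=31)
        log = detect_events(traj, task, DetectionParams(debounce_s=0.0))
        from lapskill.events import EventKind
        n_bnd = len(log.of_kind(EventKind.BOUNDARY_CONTACT))
        n_off = len(log.of_kind(EventKind.BURN_OFF_TARGET))
        counts = manifest.injected_counts
        assert n_bnd >= counts[ErrorClass.WORKSPACE_BOUNDARY]
        assert n_off >= counts[ErrorClass.DIATHERMY_OFF_TARGET]

    def test_manifest_json_round_trip(self):
        task = load_task(4)
        _, manifest = simulate_trajectory(task, PROFILES["novice"], seed=13)
        back = InjectionManifest.from_json(manifest.to_json())
        assert back.to_json() == manifest.to_json()


class TestCohort:
    def test_file_count_and_index(self, tmp_path):
        index = generate_cohort([1, 3], [PROFILES["expert"]], 2, base_seed=5,
                                out_dir=tmp_path)
        assert len(index) == 4
        csvs = sorted(p.name for p in tmp_path.glob("task*_*.csv"))
        assert len(csvs) == 4
        manifests = list(tmp_path.glob("*.manifest.json"))
        assert len(manifests) == 4
        assert (tmp_path / "index.csv").exists()

    def test_regeneration_is_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            generate_cohort([2], [PROFILES["expert"]], 2, base_seed=9, out_dir=d)
        for p1 in sorted(d1.iterdir()):
            p2 = d2 / p1.name
            assert p1.read_bytes() == p2.read_bytes(), p1.name

    def test_cohort_files_rescore_from_disk(self, tmp_path):
        generate_cohort([1], [PROFILES["expert"]], 1, base_seed=3, out_dir=tmp_path)
        [csv] = tmp_path.glob("task*.csv")
        task = load_task(1)
        traj = read_trajectory(csv, task=task)
        res = score_session(traj, task)
        assert res.time_s > 0
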