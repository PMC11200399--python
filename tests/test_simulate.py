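"""Ground-truth generator: determinism, calibration, and recovery."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from ethotrack import (
    BehaviorLabel,
    PlateauConfig,
    Posture,
    RatioConfig,
    SyntheticScenario,
    budget_from_detections,
    budget_from_manual,
    detect_plateaus,
    extract_coordinate_series,
    make_study_fixture,
    posture_series,
    read_detections_csv,
    read_manual_csv,
    reclassify_false_positives,
    simulate_behavior_sequence,
    simulate_detections,
    simulate_session,
    simulate_trajectory,
)
from ethotrack.simulate import STUDY_BEHAVIOR_MIX, read_truth_csv

B = BehaviorLabel


def small_scenario(**overrides) -> SyntheticScenario:
    defaults = dict(total_frames=1000)
    defaults.update(overrides)
    return SyntheticScenario(**defaults)


class TestBehaviorSequence:
    def test_degenerate_mix_single_behavior(self):
        scenario = small_scenario(behavior_mix={B.INACTIVE: 1.0})
        truth = simulate_behavior_sequence(scenario, seed=3)
        assert set(truth.behaviors) == {B.INACTIVE}
        assert len(truth.behaviors) == 1000

    def test_same_seed_identical_sequences(self):
        scenario = small_scenario()
        a = simulate_behavior_sequence(scenario, seed=5)
        b = simulate_behavior_sequence(scenario, seed=5)
        assert a.behaviors == b.behaviors
        assert a.bouts == b.bouts

    def test_out_of_view_occupancy_converges(self):
        scenario = SyntheticScenario(total_frames=100_000)
        truth = simulate_behavior_sequence(scenario, seed=1)
        frac = sum(
            1 for b in truth.behaviors if b is B.OUT_OF_VIEW_NOT_LABELED
        ) / len(truth.behaviors)
        assert abs(frac - 0.413) <= 0.02

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_scenario(behavior_mix={B.INACTIVE: 0.5})

    def test_bout_lengths_partition_the_session(self):
        truth = simulate_behavior_sequence(small_scenario(), seed=9)
        assert truth.bouts[0].start == 0
        assert truth.bouts[-1].end == 1000
        for prev, cur in zip(truth.bouts, truth.bouts[1:]):
            assert cur.start == prev.end


class TestTrajectory:
    def test_zero_jitter_stationary_bouts_constant(self):
        scenario = small_scenario(stationary_jitter_sd=0.0)
        truth = simulate_behavior_sequence(scenario, seed=4)
        truth = simulate_trajectory(truth, scenario, seed=4)
        for bout in truth.bouts:
            if bout.behavior in (B.INACTIVE, B.COVERED_INACTIVE, B.FORAGING_FEEDING):
                corners = {
                    truth.boxes[i].bottom_corner
                    for i in range(bout.start, bout.end)
                }
                assert len(corners) == 1

    def test_locomotion_bout_travels(self):
        scenario = small_scenario(
            behavior_mix={B.LOCOMOTION: 1.0},
            bout_mean_s={B.LOCOMOTION: 20.0},
            locomotion_speed=10.0,
        )
        truth = simulate_behavior_sequence(scenario, seed=2)
        truth = simulate_trajectory(truth, scenario, seed=2)
        for bout in truth.bouts:
            if bout.n_frames < 2:
                continue
            pts = np.array(
                [truth.boxes[i].bottom_corner for i in range(bout.start, bout.end)]
            )
            steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            # straight steps cover exactly the nominal speed; a wall
            # reflection folds the step, shortening net displacement
            assert steps.max() <= 10.0 + 1e-6
            assert np.median(steps) == pytest.approx(10.0)
            # the bout travels: path length at least one full step
            assert steps.sum() >= 10.0 - 1e-6

    def test_all_boxes_inside_arena(self):
        scenario = SyntheticScenario(total_frames=10_000)
        truth = simulate_behavior_sequence(scenario, seed=6)
        truth = simulate_trajectory(truth, scenario, seed=6)
        w, h = scenario.arena
        for box in truth.boxes:
            if box is None:
                continue
            assert 0 <= box.x_min and box.x_min + box.width <= w + 1e-9
            assert 0 <= box.y_min and box.y_min + box.height <= h + 1e-9

    def test_arena_smaller_than_box_rejected(self):
        scenario = small_scenario(arena=(100.0, 100.0))
        truth = simulate_behavior_sequence(scenario, seed=1)
        with pytest.raises(ValueError, match="arena"):
            simulate_trajectory(truth, scenario, seed=1)


class TestDetections:
    def test_zero_detect_prob_empty_track(self):
        scenario = small_scenario(detect_prob={b: 0.0 for b in B})
        track, _ = simulate_session(scenario, seed=3)
        assert len(track) == 0
        budget = budget_from_detections(track)
        assert budget.percent(B.OUT_OF_VIEW_NOT_LABELED) == 100.0

    def test_noise_free_limit_reproduces_truth_budget(self):
        detector = (B.LOCOMOTION, B.INACTIVE, B.COVERED_INACTIVE, B.FORAGING_FEEDING)
        scenario = small_scenario(
            behavior_mix={
                B.LOCOMOTION: 0.25,
                B.INACTIVE: 0.25,
                B.COVERED_INACTIVE: 0.25,
                B.FORAGING_FEEDING: 0.25,
            },
            detect_prob={b: 1.0 for b in detector},
            mislabel_matrix={b: {b: 1.0} for b in detector},
        )
        track, truth = simulate_session(scenario, seed=7)
        assert len(track) == 1000
        budget = budget_from_detections(track)
        tally = Counter(truth.behaviors)
        for b in detector:
            assert budget.counts[b.value] == tally[b]
        assert truth.fp_frames == frozenset()

    def test_frame_level_mislabel_count_in_binomial_interval(self):
        # per-frame confusion mode: planted FP frames ~ Binomial(n, 0.1)
        scenario = SyntheticScenario(
            total_frames=50_000, mislabel_per_bout=False, stationary_jitter_sd=0.5
        )
        track, truth = simulate_session(scenario, seed=11)
        n = sum(
            1
            for d in track
            if truth.behaviors[d.frame_index]
            in (B.INACTIVE, B.COVERED_INACTIVE, B.FORAGING_FEEDING)
        )
        lo, hi = stats.binom.interval(0.99, n, 0.1)
        assert lo <= len(truth.fp_frames) <= hi

    def test_bout_level_mislabel_count_in_binomial_interval(self):
        # default persistent mode: mislabeled *bouts* ~ Binomial(n_bouts, 0.1)
        scenario = SyntheticScenario(total_frames=50_000)
        track, truth = simulate_session(scenario, seed=13)
        fp_frames = truth.fp_frames
        stationary = (B.INACTIVE, B.COVERED_INACTIVE, B.FORAGING_FEEDING)
        detected_frames = {d.frame_index for d in track}
        n_bouts = n_fp_bouts = 0
        for bout in truth.bouts:
            if bout.behavior not in stationary:
                continue
            frames = set(range(bout.start, bout.end)) & detected_frames
            if not frames:
                continue
            n_bouts += 1
            if frames & fp_frames:
                assert frames <= fp_frames  # persistence: whole bout flips
                n_fp_bouts += 1
        lo, hi = stats.binom.interval(0.99, n_bouts, 0.1)
        assert lo <= n_fp_bouts <= hi


class TestFixture:
    def test_files_round_trip(self, tmp_path):
        scenario = SyntheticScenario()  # study-like defaults, 4,348 frames
        paths = make_study_fixture(scenario, seed=2, out_dir=tmp_path)
        track = read_detections_csv(paths["detections"])
        coding = read_manual_csv(paths["manual"])
        behaviors, fp, postures = read_truth_csv(paths["truth"])
        assert track.total_frames == 4348
        assert coding.total_frames == 4348
        assert len(behaviors) == 4348
        assert tuple(coding.behaviors_by_frame()) == tuple(behaviors)
        detected = {d.frame_index for d in track}
        assert fp <= detected  # planted FPs are always detected frames
        assert all(p in set(Posture) for p in postures)

    def test_seed_changes_data_not_schema(self, tmp_path):
        scenario = small_scenario()
        a = make_study_fixture(scenario, seed=1, out_dir=tmp_path / "a")
        b = make_study_fixture(scenario, seed=2, out_dir=tmp_path / "b")
        head_a = a["detections"].read_text().splitlines()[:3]
        head_b = b["detections"].read_text().splitlines()[:3]
        assert head_a[0] == head_b[0] and head_a[2] == head_b[2]
        assert a["detections"].read_text() != b["detections"].read_text()

    def test_identical_seed_byte_identical(self, tmp_path):
        scenario = small_scenario()
        a = make_study_fixture(scenario, seed=5, out_dir=tmp_path / "a")
        b = make_study_fixture(scenario, seed=5, out_dir=tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()

    def test_manual_budget_tracks_study_mix(self):
        # generator calibration: mean occupancy over replicates approaches
        # the published manual time budget
        scenario = SyntheticScenario(total_frames=100_000)
        sums = Counter()
        reps = 5
        for s in range(reps):
            truth = simulate_behavior_sequence(scenario, seed=s)
            budget = budget_from_manual(truth.manual_coding())
            for b in B:
                sums[b] += budget.percent(b)
        for b, target in STUDY_BEHAVIOR_MIX.items():
            assert sums[b] / reps == pytest.approx(100 * target, abs=2.0)


class TestEndToEndRecovery:
    def test_plateau_filter_recovers_planted_false_positives(self):
        """Sensitivity and specificity >= 0.9 on study-like sessions."""
        planted = caught = true_loco = wrongly_flagged = 0
        for seed in range(1, 11):
            track, truth = simulate_session(SyntheticScenario(), seed=seed)
            runs = detect_plateaus(
                extract_coordinate_series(track), PlateauConfig()
            )
            result = reclassify_false_positives(track, runs)
            loco_frames = {
                d.frame_index
                for d in track
                if d.behavior is B.LOCOMOTION
                and truth.behaviors[d.frame_index] is B.LOCOMOTION
            }
            planted += len(truth.fp_frames)
            caught += len(truth.fp_frames & result.fp_frames)
            true_loco += len(loco_frames)
            wrongly_flagged += len(loco_frames & result.fp_frames)
        assert planted > 0 and true_loco > 0
        assert caught / planted >= 0.9
        assert 1.0 - wrongly_flagged / true_loco >= 0.9

    def test_posture_recovery_with_bracketing_limits(self):
        scenario = SyntheticScenario(total_frames=3000, posture_bout_prob=0.5)
        track, truth = simulate_session(scenario, seed=8)
        series = posture_series(track, RatioConfig(upper_limit=2.0, lower_limit=0.6))
        calls = {c.frame_index: c.posture for c in series.calls}
        for det in track:
            true_posture = truth.postures[det.frame_index]
            if true_posture is not Posture.NEUTRAL:
                assert calls[det.frame_index] is true_posture
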