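import numpy as np
import pytest

from exerstep.detection import detect_arm_lifts, detect_steps, derive_single_support
from exerstep.errors import ConfigError, ScheduleInfeasible
from exerstep.gamelog import score_trial
from exerstep.simulator import (
    Anthropometry,
    ArmCommand,
    GameSettings,
    MovementPlan,
    PlayerPolicy,
    StepCommand,
    generate_object_schedule,
    ground_truth_from_plan,
    iter_cohort,
    make_cohort,
    simulate_play,
    synthesize_markers,
)
from exerstep.simulator.schedule import concurrency_profile


class TestSchedule:
    def test_low_speed_grape_concurrency_in_range(self):
        s = GameSettings.for_condition("low", "without")
        objs = generate_object_schedule(s, 0)
        prof = concurrency_profile(objs, "grape", s.trial_duration)
        assert prof.min() >= 1 and prof.max() <= 3

    def test_eleven_chickens(self):
        for speed in ("low", "high"):
            s = GameSettings.for_condition(speed, "with")
            objs = generate_object_schedule(s, 1)
            assert sum(o.kind == "chicken" for o in objs) == 11

    def test_chicken_windows_disjoint(self):
        s = GameSettings.for_condition("low", "without")
        chickens = [o for o in generate_object_schedule(s, 2)
                    if o.kind == "chicken"]
        chickens.sort(key=lambda o: o.spawn_time)
        for a, b in zip(chickens, chickens[1:]):
            assert a.arrival <= b.spawn_time + 1e-9

    def test_zero_duration_infeasible(self):
        s = GameSettings.for_condition("low", "without", trial_duration=0.0)
        with pytest.raises(ScheduleInfeasible):
            generate_object_schedule(s, 0)

    def test_too_short_for_chickens_infeasible(self):
        s = GameSettings.for_condition("low", "without", trial_duration=60.0)
        with pytest.raises(ScheduleInfeasible):
            generate_object_schedule(s, 0)

    def test_no_branches_without_obstacles(self):
        s = GameSettings.for_condition("high", "without")
        objs = generate_object_schedule(s, 3)
        assert all(o.kind != "branch" for o in objs)

    def test_fall_times_within_range(self):
        for speed, (lo, hi) in (("low", (8, 10)), ("high", (6, 9))):
            s = GameSettings.for_condition(speed, "with")
            for o in generate_object_schedule(s, 4):
                if o.kind in ("grape", "branch"):
                    assert lo <= o.fall_time <= hi

    def test_deterministic_under_seed(self):
        s = GameSettings.for_condition("high", "with")
        a = generate_object_schedule(s, 9)
        b = generate_object_schedule(s, 9)
        assert a == b

    def test_invalid_condition_raises(self):
        with pytest.raises(ConfigError):
            GameSettings.for_condition("medium", "with")


@pytest.fixture(scope="module")
def played():
    s = GameSettings.for_condition("low", "with")
    schedule = generate_object_schedule(s, 21)
    return s, schedule, simulate_play(schedule, PlayerPolicy(), s, 22)


class TestSimulatePlay:
    def test_score_identity(self, played):
        _, _, (avatar, log, plan) = played
        summary = score_trial(log)
        assert log.score == summary.score
        assert summary.score == (summary.grapes_caught
                                 + 3 * summary.chickens_caught
                                 - 2 * summary.branches_hit)

    def test_conservation(self, played):
        _, _, (avatar, log, plan) = played
        for kind, good, bad in (("grape", "caught", "missed"),
                                ("chicken", "caught", "missed"),
                                ("branch", "avoided", "hit")):
            counts = log.counts(kind)
            resolved = counts.get(good, 0) + counts.get(bad, 0)
            assert resolved + counts.get("pending", 0) == counts["presented"]

    def test_clock_accounting(self, played):
        _, _, (avatar, log, plan) = played
        pause = sum(e.duration for e in log.errors)
        assert log.duration_game + pause == pytest.approx(log.duration_wall,
                                                          abs=0.1)

    def test_avatar_stays_reasonable(self, played):
        _, _, (avatar, log, plan) = played
        assert np.all(np.abs(avatar[:, 0]) < 1.3)

    def test_never_style_catches_no_chickens(self):
        s = GameSettings.for_condition("low", "without")
        schedule = generate_object_schedule(s, 5)
        _, log, _ = simulate_play(schedule, PlayerPolicy(arm_style="never"), s, 6)
        assert log.counts("chicken").get("caught", 0) == 0

    def test_parked_player_catches_scripted_grape(self):
        # hand-traced: one grape falls exactly where the player starts
        from exerstep.simulator.settings import GameObject
        s = GameSettings.for_condition("low", "without", chickens_per_trial=0,
                                       trial_duration=15.0)
        schedule = [GameObject("grape", 0.0, 0.0, 0.0, 8.0)]
        policy = PlayerPolicy(forward_drift_rate=0.0, lateral_noise=0.0)
        _, log, plan = simulate_play(schedule, policy, s, 1)
        assert log.objects[0].outcome == "caught"

    def test_far_parked_player_misses_scripted_grape(self):
        from exerstep.simulator.settings import GameObject
        s = GameSettings.for_condition("low", "without", chickens_per_trial=0,
                                       trial_duration=5.0)
        # arrives after 2 s, 0.9 m away: unreachable given reaction + stepping
        schedule = [GameObject("grape", 0.0, 0.9, 0.0, 2.0)]
        policy = PlayerPolicy(forward_drift_rate=0.0, reaction_delay=1.5)
        _, log, plan = simulate_play(schedule, policy, s, 1)
        assert log.objects[0].outcome == "missed"

    def test_determinism(self):
        s = GameSettings.for_condition("high", "without")
        schedule = generate_object_schedule(s, 30)
        r1 = simulate_play(schedule, PlayerPolicy(), s, 31)
        schedule2 = generate_object_schedule(s, 30)
        r2 = simulate_play(schedule2, PlayerPolicy(), s, 31)
        np.testing.assert_array_equal(r1[0], r2[0])
        assert r1[1].score == r2[1].score
        assert r1[2].steps == r2[2].steps


class TestSynthesizeMarkers:
    def test_empty_plan_static(self):
        plan = MovementPlan(duration=2.0, start_x=0.0, start_y=-0.5)
        rec = synthesize_markers(plan, PlayerPolicy(), noise_sd=0.0, seed=0)
        assert rec.n_frames == 240
        for name, arr in rec.positions.items():
            assert np.ptp(arr, axis=0).max() == pytest.approx(0.0, abs=1e-12)

    def test_single_step_displacement(self):
        plan = MovementPlan(duration=3.0, start_x=0.0, start_y=-0.5,
                            steps=[StepCommand("left", 1.0, 0.4, 0.25, 0.0)])
        rec = synthesize_markers(plan, PlayerPolicy(), noise_sd=0.0, seed=0)
        toe = rec["toe_L"]
        assert toe[-1, 0] - toe[0, 0] == pytest.approx(0.25, abs=1e-6)
        ankle = rec["ankle_L"]
        assert ankle[-1, 0] - ankle[0, 0] == pytest.approx(0.25, abs=1e-6)
        # contralateral foot and body move half
        assert rec["toe_R"][-1, 0] - rec["toe_R"][0, 0] == pytest.approx(0.0)
        st = rec["sternum"]
        assert st[-1, 0] - st[0, 0] == pytest.approx(0.125, abs=1e-6)

    def test_arm_lift_exceeds_head_during_interval(self):
        plan = MovementPlan(duration=4.0, start_x=0.0, start_y=-0.5,
                            arms=[ArmCommand(("left",), t0=1.0)])
        rec = synthesize_markers(plan, PlayerPolicy(), noise_sd=0.0, seed=0)
        head_z = np.mean([rec[h][:, 2] for h in rec.markers.head], axis=0)
        above = rec["wrist_L"][:, 2] > head_z
        t = rec.time
        cmd = plan.arms[0]
        # fully above during the hold, fully below outside the command
        hold = (t >= cmd.t0 + cmd.t_raise) & (t <= cmd.t0 + cmd.t_raise + cmd.t_hold)
        assert above[hold].all()
        outside = (t < cmd.t0) | (t > cmd.end)
        assert not above[outside].any()
        assert not (rec["wrist_R"][:, 2] > head_z).any()

    def test_bad_anthropometry_raises(self):
        with pytest.raises(ConfigError):
            Anthropometry(height=-1.7)

    def test_noise_reproducible(self):
        plan = MovementPlan(duration=1.0, start_x=0.0, start_y=-0.5)
        a = synthesize_markers(plan, PlayerPolicy(), noise_sd=0.002, seed=4)
        b = synthesize_markers(plan, PlayerPolicy(), noise_sd=0.002, seed=4)
        np.testing.assert_array_equal(a["sternum"], b["sternum"])


class TestGroundTruthConsistency:
    def test_noise_free_recovery_single_trial(self):
        s = GameSettings.for_condition("low", "with")
        schedule = generate_object_schedule(s, 77)
        policy = PlayerPolicy()
        _, log, plan = simulate_play(schedule, policy, s, 78)
        rec = synthesize_markers(plan, policy, noise_sd=0.0, seed=0)
        truth = ground_truth_from_plan(plan, log)
        steps = detect_steps(rec)
        for foot in ("left", "right"):
            assert len(steps[foot]) == sum(1 for st in truth.steps
                                           if st[0] == foot)
        lifts = detect_arm_lifts(rec)
        assert len(lifts) == len(truth.arm_lifts)
        # boundaries within one frame
        det = sorted(steps["left"] + steps["right"], key=lambda e: e.start)
        tru = sorted(truth.steps, key=lambda st: st[1])
        for d, (foot, start, end, size) in zip(det, tru):
            assert abs(d.start - start) <= 1.0 / rec.rate
            assert abs(d.end - end) <= 1.0 / rec.rate

    def test_support_totals_match(self):
        s = GameSettings.for_condition("high", "without")
        schedule = generate_object_schedule(s, 55)
        policy = PlayerPolicy()
        _, log, plan = simulate_play(schedule, policy, s, 56)
        rec = synthesize_markers(plan, policy, noise_sd=0.0, seed=0)
        truth = ground_truth_from_plan(plan, log)
        support = derive_single_support(detect_steps(rec), rec.duration)
        for foot in ("left", "right"):
            total = sum(iv.duration for iv in support[foot])
            tol = 2.0 * max(1, len(support[foot])) / rec.rate
            assert total == pytest.approx(truth.support_total(foot), abs=tol)


class TestCohort:
    def test_empty_cohort(self):
        assert make_cohort(0, 0) == []

    def test_trial_count_and_conditions(self, small_settings_overrides):
        trials = make_cohort(2, 3, trial_duration=40.0,
                             settings_overrides=small_settings_overrides)
        assert len(trials) == 16
        for pid in ("P01", "P02"):
            own = [t for t in trials if t.recording.meta.participant == pid]
            combos = [(t.recording.meta.speed, t.recording.meta.obstacles,
                       t.recording.meta.repetition) for t in own]
            assert len(set(combos)) == 8
            for speed in ("low", "high"):
                for obstacles in ("without", "with"):
                    n = sum(1 for c in combos if c[:2] == (speed, obstacles))
                    assert n == 2    # each condition exactly twice

    def test_counterbalanced_orders_differ(self, small_settings_overrides):
        trials = make_cohort(2, 3, trial_duration=40.0,
                             settings_overrides=small_settings_overrides)
        orders = {}
        for t in trials:
            m = t.recording.meta
            orders.setdefault(m.participant, []).append((m.speed, m.obstacles))
        assert orders["P01"][:4] != orders["P02"][:4]

    def test_determinism(self, small_settings_overrides):
        a = make_cohort(1, 5, trial_duration=40.0,
                        settings_overrides=small_settings_overrides)
        b = make_cohort(1, 5, trial_duration=40.0,
                        settings_overrides=small_settings_overrides)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.recording["sternum"],
                                          tb.recording["sternum"])
            assert ta.log.score == tb.log.score

    def test_gender_split_at_fifteen(self):
        from exerstep.simulator.cohort import assign_genders
        g = assign_genders(15)
        assert g.count("female") == 7 and g.count("male") == 8

    def test_expected_trial_total_at_study_size(self):
        from exerstep.simulator.cohort import assign_genders, condition_order
        # 15 participants x 8 trials = 120 without simulating them
        n = sum(2 * len(condition_order(i)) for i in range(15))
        assert n == 120
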