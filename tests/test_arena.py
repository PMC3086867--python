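"""Arena kinematics, sensing, delivery scoring and trial determinism."""

import numpy as np
import pytest

import kinforage as kf
from kinforage.arena import ArenaConfig, ArenaState


def make_state(cfg, robot_xy, headings, item_xy=()):
    """Hand-built world with any number of inactive slots disabled."""
    R = cfg.n_robots
    I = cfg.n_items
    rpos = np.full((R, 2), 5.0)
    # park unused robots in distinct far corners of the bottom edge
    rpos[:, 0] = 3.0 + 3.0 * np.arange(R)
    rpos[:, 1] = 2.0
    rhead = np.zeros(R)
    for i, xy in enumerate(robot_xy):
        rpos[i] = xy
    for i, h in enumerate(headings):
        rhead[i] = h
    ipos = np.full((I, 2), 1.5)
    ipos[:, 0] = 1.5 + 3.0 * np.arange(I)
    iactive = np.zeros(I, dtype=bool)
    for i, xy in enumerate(item_xy):
        ipos[i] = xy
        iactive[i] = True
    return ArenaState(robot_pos=rpos, robot_heading=rhead, item_pos=ipos,
                      item_active=iactive,
                      item_pusher=np.full(I, -1, dtype=np.int64))


def zero_networks(n=8):
    return [kf.ControllerNetwork(np.zeros((7, 3)), np.zeros((4, 3)))] * n


def drive_networks(left, right, share=-1.0, n=8):
    """Saturated constant-output controllers via huge bias->output weights."""
    w_out = np.zeros((4, 3))
    w_out[3] = [-50.0 * left, -50.0 * right, -50.0 * share]
    return [kf.ControllerNetwork(np.zeros((7, 3)), w_out, weight_range=50.0)] * n


class TestSense:
    def test_empty_neighborhood_black_wall_all_minus_one(self):
        cfg = ArenaConfig()
        # centre of the arena facing the bottom (black) wall; one robot,
        # everything else parked far away
        st = make_state(cfg, [(25.0, 25.0)], [-np.pi / 2])
        st.robot_pos[1:] = [[45.0, 45.0]] * 7
        st.robot_pos[1:, 0] = np.linspace(5, 45, 7)
        st.robot_pos[1:, 1] = 45.0
        s = kf.sense(st, cfg, 0)
        assert np.allclose(s, -1.0)

    def test_item_ahead_triggers_front_ir_not_long_ir(self):
        cfg = ArenaConfig()
        # item surface 1.5 cm from the robot surface, dead ahead
        d = cfg.robot_radius + cfg.item_radius + 1.5
        st = make_state(cfg, [(25.0, 25.0)], [0.0], item_xy=[(25.0 + d, 25.0)])
        s = kf.sense(st, cfg, 0)
        assert s[1] == pytest.approx(1.0 - 2 * 1.5 / cfg.short_ir_range)
        assert s[3] == -1.0  # long-range IR sees robots only

    def test_robot_ahead_triggers_long_ir(self):
        cfg = ArenaConfig()
        d = 2 * cfg.robot_radius + 4.0  # beyond short range, inside long range
        st = make_state(cfg, [(25.0, 25.0), (25.0 + d, 25.0)], [0.0, 0.0])
        s = kf.sense(st, cfg, 0)
        assert s[3] == pytest.approx(1.0 - 2 * 4.0 / cfg.long_ir_range)
        assert s[1] == -1.0

    def test_facing_white_wall_both_vision_channels_on(self):
        cfg = ArenaConfig()
        st = make_state(cfg, [(25.0, 30.0)], [np.pi / 2])
        s = kf.sense(st, cfg, 0)
        assert s[4] == 1.0 and s[5] == 1.0

    def test_vision_oblique_half_fields_disagree(self):
        cfg = ArenaConfig()
        # heading 45 deg from a corner-ish spot: left half-field ray exits
        # through the white wall, right one through the black side wall
        st = make_state(cfg, [(40.0, 40.0)], [np.pi / 4])
        s = kf.sense(st, cfg, 0)
        assert s[4] == 1.0 and s[5] == -1.0

    def test_sensor_values_bounded(self, rng):
        cfg = ArenaConfig()
        st = kf.initial_state(cfg, rng)
        for r in range(cfg.n_robots):
            s = kf.sense(st, cfg, r)
            assert np.all(s >= -1.0) and np.all(s <= 1.0)

    def test_invalid_index(self, rng):
        cfg = ArenaConfig()
        st = kf.initial_state(cfg, rng)
        with pytest.raises(IndexError):
            kf.sense(st, cfg, 8)


class TestStep:
    def test_zero_motors_leave_state_unchanged(self, rng):
        cfg = ArenaConfig()
        st = kf.initial_state(cfg, rng)
        new = kf.step(st, zero_networks(), cfg)
        assert np.allclose(new.robot_pos, st.robot_pos)
        assert np.allclose(new.robot_heading, st.robot_heading)
        assert new.time == pytest.approx(cfg.time_step)

    def test_equal_wheels_advance_straight(self):
        cfg = ArenaConfig()
        st = make_state(cfg, [(25.0, 25.0)], [0.0])
        nets = drive_networks(1.0, 1.0)
        new = kf.step(st, nets, cfg)
        speed = np.tanh(50.0)  # saturated wheel output
        assert new.robot_pos[0, 0] == pytest.approx(
            25.0 + speed * cfg.max_wheel_speed * cfg.time_step)
        assert new.robot_pos[0, 1] == pytest.approx(25.0)
        assert new.robot_heading[0] == pytest.approx(0.0)

    def test_opposite_wheels_rotate_in_place(self):
        cfg = ArenaConfig()
        st = make_state(cfg, [(25.0, 25.0)], [0.0])
        new = kf.step(st, drive_networks(-1.0, 1.0), cfg)
        assert np.allclose(new.robot_pos[0], (25.0, 25.0))
        expected = 2 * np.tanh(50.0) * cfg.max_wheel_speed * cfg.time_step / (
            2 * cfg.robot_radius)
        assert new.robot_heading[0] == pytest.approx(expected)


class TestScoreDeliveries:
    def test_item_outside_band_no_event(self):
        cfg = ArenaConfig()
        st = make_state(cfg, [(25.0, 25.0)], [0.0],
                        item_xy=[(25.0, cfg.side - 5.0)])
        new, events = kf.score_deliveries(st, zero_networks(), cfg)
        assert events == [] and new.item_active[0]

    def test_item_in_band_credited_and_labelled(self):
        cfg = ArenaConfig()
        st = make_state(cfg, [(25.0, 40.0)], [0.0],
                        item_xy=[(25.0, cfg.side - 2.0)])
        st.item_pusher[0] = 0
        new, events = kf.score_deliveries(st, drive_networks(0.0, 0.0, share=1.0), cfg)
        assert events == [(0, 0, True)]
        assert not new.item_active[0]
        # never-share controller labels the same delivery selfish
        st2 = make_state(cfg, [(25.0, 40.0)], [0.0],
                         item_xy=[(25.0, cfg.side - 2.0)])
        _, ev2 = kf.score_deliveries(st2, drive_networks(0.0, 0.0, share=-1.0), cfg)
        assert ev2 == [(0, 0, False)]


class TestRunTrial:
    def test_zero_weight_controllers_deliver_nothing(self):
        cfg = ArenaConfig()
        res = kf.run_trial(None, cfg, seed=0, networks=zero_networks())
        assert res.total_delivered == 0

    def test_same_seed_identical_result(self):
        cfg = ArenaConfig(trial_duration=30.0)
        genes = kf.make_fixtures("random", seed=11)
        a = kf.run_trial(genes, cfg, seed=42)
        b = kf.run_trial(genes, cfg, seed=42)
        assert np.array_equal(a.n_selfish, b.n_selfish)
        assert np.array_equal(a.n_shared, b.n_shared)

    def test_wall_seeker_delivers_on_aligned_layout(self):
        # robot directly behind an item, both facing the white wall:
        # driving forward must push the item into the band within 60 s
        cfg = ArenaConfig()
        st = make_state(cfg, [(25.0, 36.0)], [np.pi / 2],
                        item_xy=[(25.0, 39.0)])
        genes = kf.make_fixtures("wall-seeker")
        nets = [kf.decode_genome(kf.Genome(g)) for g in genes]
        delivered = 0
        for _ in range(cfg.n_steps):
            st = kf.step(st, nets, cfg)
            st, events = kf.score_deliveries(st, nets, cfg)
            delivered += len(events)
            # invariants along the way: robots stay inside the arena
            assert np.all(st.robot_pos >= cfg.robot_radius - 1e-9)
            assert np.all(st.robot_pos <= cfg.side - cfg.robot_radius + 1e-9)
            if delivered:
                break
        assert delivered >= 1

    def test_item_count_conserved_every_step(self, fast_cfg):
        cfg = fast_cfg
        genes = kf.make_fixtures("wall-seeker")
        selfish, shared, events = kf.simulate_worlds(
            *kf.arena.genomes_to_arrays(np.repeat(genes[None], 4, axis=0)),
            cfg, np.random.default_rng(5), record_events=True)
        # every delivery event deactivates exactly one item, so
        # deliveries + counts always reconcile
        assert len(events) == selfish.sum() + shared.sum()
        assert selfish.sum() + shared.sum() <= 4 * cfg.n_items
        items = [i for (_, b, r, i, f) in events]
        assert len(events) == len(set(zip([b for (_, b, _, _, _) in events], items)))


class TestFixtures:
    def test_share_fixtures_force_altruism_levels(self):
        cfg = ArenaConfig()
        for kind, expect in (("always-share", 1.0), ("never-share", 0.0)):
            ev = kf.evaluate_group(kf.make_fixtures(kind), cfg, n_trials=8, seed=3)
            total = ev.n_selfish.sum() + ev.n_shared.sum()
            assert total >= 1, "fixture group must deliver at least one item"
            assert ev.n_shared.sum() / total == expect

    def test_random_fixture_deterministic(self):
        a = kf.make_fixtures("random", seed=9)
        b = kf.make_fixtures("random", seed=9)
        assert np.array_equal(a, b)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            kf.make_fixtures("teleporter")


class TestEvaluateGroup:
    def test_counts_are_sums_of_trials(self):
        cfg = ArenaConfig(trial_duration=20.0)
        genes = kf.make_fixtures("wall-seeker")
        ev = kf.evaluate_group(genes, cfg, n_trials=6, seed=1)
        assert ev.per_trial_selfish.shape == (6, 8)
        assert np.array_equal(ev.n_selfish, ev.per_trial_selfish.sum(axis=0))
        assert ev.mean_items_per_trial == pytest.approx(
            (ev.per_trial_selfish.sum() + ev.per_trial_shared.sum()) / 6)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ArenaConfig(target_depth=60.0)
        with pytest.raises(ValueError):
            ArenaConfig(time_step=-0.1)
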