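"""Ghost-model machinery: windowing, training phases, DAgger contracts, rollout."""

import numpy as np
import pytest

from gridghost import ghosting, roles, synth, tracking
from gridghost.ghosting import (GhostConfig, GhostModel, TrainingWindow,
                                window_bounds)


class TestWindowBounds:
    def test_forty_frames_gives_two_full_windows(self):
        assert window_bounds(40) == [(0, 25), (15, 40)]

    def test_exact_window_length_gives_one(self):
        assert window_bounds(25) == [(0, 25)]

    def test_twenty_six_frames_keeps_short_tail(self):
        assert window_bounds(26) == [(0, 25), (15, 26)]

    def test_stride_arithmetic_exact_for_all_lengths(self):
        """Brute-force enumeration of the stride rule for lengths 1..200."""
        for n in range(1, 201):
            bounds = window_bounds(n)
            assert bounds[0][0] == 0
            assert bounds[-1][1] == n
            for (s1, e1), (s2, e2) in zip(bounds, bounds[1:]):
                assert s2 - s1 == 15
                assert e1 - s1 == 25
            assert all(e - s <= 25 for s, e in bounds)


@pytest.fixture(scope="module")
def small_model(man_fixture_plays):
    cfg = GhostConfig(hidden_size=8, pretrain_epochs=4, dagger_iters=2,
                      dagger_refit_epochs=2, joint_iters=1,
                      joint_refit_epochs=2, seed=0)
    model = GhostModel(cfg)
    model.fit_role_models(man_fixture_plays[:20])
    return model


@pytest.fixture(scope="module")
def small_windows(small_model, man_fixture_plays):
    return ghosting.make_training_windows(
        small_model.tensors(man_fixture_plays[:20]))


class TestFeatureState:
    def test_state_dimension_and_order(self, small_model, man_fixture_plays):
        play = man_fixture_plays[0]
        pt = ghosting.build_play_tensor(play, small_model.assign_static(play),
                                        small_model.offense_role_model)
        assert pt.features.shape == (play.n_frames, ghosting.STATE_DIM)
        # defender block mirrors defender_pos in role order
        np.testing.assert_array_equal(
            pt.features[:, :14], pt.defender_pos.reshape(play.n_frames, -1))
        # metadata occupies the last three slots
        np.testing.assert_allclose(pt.features[0, -3:], [
            play.meta.yards_to_go, play.meta.down,
            play.meta.absolute_field_position])

    def test_role_entities_are_a_bijection(self, small_model, man_fixture_plays):
        play = man_fixture_plays[0]
        pt = ghosting.build_play_tensor(play, small_model.assign_static(play),
                                        small_model.offense_role_model)
        assert sorted(pt.role_entities) == play.defender_ids


class TestPretrain:
    def test_loss_trends_down_and_learns_constant_velocity(self):
        """Defenders moving at constant velocity are a closed-form-learnable
        one-step target; pretraining should reach a small MSE."""
        rng = np.random.default_rng(3)
        windows = []
        for k in range(40):
            T = 20
            vel = rng.normal(0, 0.3, (7, 2))
            pos0 = rng.uniform(10, 40, (7, 2))
            def_pos = pos0[None] + vel[None] * np.arange(T + 1)[:, None, None]
            feats = np.zeros((T, ghosting.STATE_DIM))
            feats[:, :14] = def_pos[:-1].reshape(T, -1)
            windows.append(TrainingWindow(("g", k), 0, T, feats,
                                          np.diff(def_pos, axis=0)[:T],
                                          def_pos))
        cfg = GhostConfig(hidden_size=24, pretrain_epochs=250,
                          learning_rate=1e-2, seed=0)
        model = GhostModel(cfg)
        model.init_policies()
        ghosting.pretrain_policies(model, windows)
        curves = model.manifest["phases"][-1]["loss_curves"]
        for r, curve in curves.items():
            assert curve[-1] < 0.01            # < 0.01 sq-yards one-step error
            assert curve[-1] < 0.3 * curve[0]  # trending down

    def test_same_seed_identical_weights(self, small_windows):
        hashes = []
        for _ in range(2):
            cfg = GhostConfig(hidden_size=8, pretrain_epochs=2, seed=4)
            m = GhostModel(cfg)
            m.init_policies()
            ghosting.pretrain_policies(m, small_windows)
            hashes.append([p.weights_hash() for p in m.policies])
        assert hashes[0] == hashes[1]

    def test_empty_windows_rejected(self, small_model):
        with pytest.raises(ValueError, match="no training windows"):
            ghosting.pretrain_policies(GhostModel(small_model.config), [])


class TestDagger:
    def test_aggregate_size_non_decreasing(self, small_model, small_windows):
        m = GhostModel(small_model.config)
        m.static_role_model = small_model.static_role_model
        m.offense_role_model = small_model.offense_role_model
        m.init_policies()
        ghosting.pretrain_policies(m, small_windows)
        ghosting.dagger_train_single(m, 0, small_windows)
        phase = m.manifest["phases"][-1]
        sizes = phase["aggregate_sizes"]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] == len(small_windows) * 3  # 2 iterations append fully

    def test_expert_policy_is_a_fixed_point(self, small_model, man_fixture_plays):
        """A policy that already emits the expert action keeps ~zero closed-loop
        error, so DAgger aggregation adds states but no corrective signal."""
        m = GhostModel(small_model.config)
        m.static_role_model = small_model.static_role_model
        m.offense_role_model = small_model.offense_role_model
        m.init_policies()
        windows = ghosting.make_training_windows(m.tensors(man_fixture_plays[:5]))

        class _Expert:
            """Replays the observed displacement for role 0 of one window."""

            def __init__(self, window):
                self.w = window
                self.t = 0

            def init_state(self, batch):
                self.t = 0
                return None

            def step(self, x, state):
                y = self.w.targets[min(self.t, len(self.w.targets) - 1), 0]
                self.t += 1
                return np.atleast_2d(y), state

        for w in windows:
            m.policies[0] = _Expert(w)
            visited, experts = ghosting._rollout_window(m, w, [0])
            np.testing.assert_allclose(experts[0], w.targets[:, 0, :], atol=1e-9)

    def test_role_out_of_range(self, small_model, small_windows):
        with pytest.raises(ValueError, match="out of range"):
            ghosting.dagger_train_single(small_model, 9, small_windows)


class TestJointAndRollout:
    def test_expert_policies_reproduce_ground_truth(self, small_model,
                                                    man_fixture_plays):
        """Zero-displacement stubs freeze ghosts at snap positions; replay stubs
        reproduce the observed trajectories exactly."""
        play = man_fixture_plays[0]
        a = small_model.assign_static(play)
        pt = ghosting.build_play_tensor(play, a, small_model.offense_role_model)

        class _Zero:
            def init_state(self, batch):
                return None

            def step(self, x, state):
                return np.zeros((np.atleast_2d(x).shape[0], 2)), state

        class _Replay:
            def __init__(self, r):
                self.r = r
                self.t = 0

            def init_state(self, batch):
                self.t = 0
                return None

            def step(self, x, state):
                y = pt.defender_pos[self.t + 1, self.r] - pt.defender_pos[self.t, self.r]
                self.t += 1
                return np.atleast_2d(y), state

        m = GhostModel(small_model.config)
        m.static_role_model = small_model.static_role_model
        m.offense_role_model = small_model.offense_role_model
        m.policies = [_Zero() for _ in range(7)]
        frozen = ghosting.rollout(m, play, a)
        for t in range(frozen.shape[0]):
            np.testing.assert_array_equal(frozen[t], pt.defender_pos[0])

        m.policies = [_Replay(r) for r in range(7)]
        replay = ghosting.rollout(m, play, a)
        np.testing.assert_allclose(replay, pt.defender_pos, atol=1e-9)

    def test_rollout_length_matches_play(self, small_model, small_windows,
                                         man_fixture_plays):
        m = GhostModel(small_model.config)
        m.static_role_model = small_model.static_role_model
        m.offense_role_model = small_model.offense_role_model
        m.init_policies()
        ghosting.pretrain_policies(m, small_windows)
        play = man_fixture_plays[0]
        g = ghosting.rollout(m, play)
        assert g.shape == (play.n_frames, 7, 2)

    def test_untrained_model_rejected(self, man_fixture_plays, small_model):
        m = GhostModel(GhostConfig(hidden_size=8))
        m.static_role_model = small_model.static_role_model
        m.offense_role_model = small_model.offense_role_model
        with pytest.raises(ValueError, match="no trained policies"):
            ghosting.rollout(m, man_fixture_plays[0])

    def test_joint_training_keeps_rollout_bounded(self, small_model,
                                                  small_windows,
                                                  man_fixture_plays):
        m = GhostModel(small_model.config)
        m.static_role_model = small_model.static_role_model
        m.offense_role_model = small_model.offense_role_model
        m.init_policies()
        ghosting.pretrain_policies(m, small_windows)
        ghosting.joint_train(m, small_windows)
        for play in man_fixture_plays[:5]:
            g = ghosting.rollout(m, play)
            assert np.all(g[:, :, 0] > -5) and np.all(g[:, :, 0] < tracking.FIELD_WIDTH + 5)
            assert np.all(g[:, :, 1] > -60) and np.all(g[:, :, 1] < 60)

    def test_joint_same_seed_reproducible(self, small_model, small_windows):
        hashes = []
        for _ in range(2):
            m = GhostModel(small_model.config)
            m.static_role_model = small_model.static_role_model
            m.offense_role_model = small_model.offense_role_model
            m.init_policies()
            ghosting.pretrain_policies(m, small_windows)
            ghosting.joint_train(m, small_windows)
            hashes.append([p.weights_hash() for p in m.policies])
        assert hashes[0] == hashes[1]


class TestAlternate:
    def test_returned_model_is_best_so_far(self, man_fixture_plays):
        cfg = GhostConfig(hidden_size=8, pretrain_epochs=3,
                          alternate_max_cycles=2, seed=0)
        m = GhostModel(cfg)
        train, val = man_fixture_plays[:15], man_fixture_plays[15:20]
        ghosting.alternate_optimize(m, train, val, use_dagger=False)
        history = m.manifest["alternate_history"]
        assert m.manifest["alternate_best_mae"] == pytest.approx(min(history))
        assert ghosting.validation_rollout_mae(m, val) == pytest.approx(
            min(history), rel=1e-6)

    def test_single_cycle_degenerates_to_one_training_pass(self, man_fixture_plays):
        cfg = GhostConfig(hidden_size=8, pretrain_epochs=3,
                          alternate_max_cycles=1, seed=0)
        m = GhostModel(cfg)
        ghosting.alternate_optimize(m, man_fixture_plays[:15],
                                    man_fixture_plays[15:18], use_dagger=False)
        assert len(m.manifest["alternate_history"]) == 1
        assert m.assignment_mode == "static"
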