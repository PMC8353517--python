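"""Role alignment: EM/Baum–Welch properties, Hungarian optimality, recovery."""

import itertools

import numpy as np
import pytest

from gridghost import roles, synth, tracking
from gridghost.tracking import PlayCollection


def _cluster_plays(n_plays, centers, spread, seed):
    """Plays whose defender snap positions are drawn from known role clusters."""
    rng = np.random.default_rng(seed)
    cfg = synth.SynthConfig(sigma=0.0, fixed_duration_s=2.0)
    plays = []
    truth = []
    for k in range(n_plays):
        play, _ = synth.generate_play(cfg, seed=seed * 100000 + k)
        play = tracking.normalize_play(play)
        snap = play.frame_index(play.events["ball_snap"])
        perm = rng.permutation(len(centers))
        for j, eid in enumerate(play.defender_ids):
            c = centers[perm[j]] + rng.normal(0, spread, 2)
            t = play.tracks[eid]
            t.x[:] = c[0]
            t.y[:] = c[1]
        plays.append(play)
        truth.append({eid: int(perm[j]) for j, eid in enumerate(play.defender_ids)})
    return plays, truth


WELL_SEPARATED = np.array([[5.0, -5], [13, -5], [21, -5], [29, -5],
                           [37, -5], [45, -5], [25, -14]])


class TestStaticModel:
    def test_recovers_known_cluster_means(self):
        plays, _ = _cluster_plays(60, WELL_SEPARATED, spread=0.4, seed=2)
        model = roles.fit_static_role_model(plays, 7, seed=0)
        # canonical order sorts left-to-right; match fitted to true by nearest
        for mean in model.means:
            d = np.linalg.norm(WELL_SEPARATED - mean, axis=1).min()
            assert d < 0.5

    def test_em_log_likelihood_monotone(self, norm_plays):
        model = roles.fit_static_role_model(norm_plays, 7, seed=0)
        assert np.all(np.diff(model.log_likelihoods) >= -1e-9)

    def test_single_role_mean_is_sample_mean(self, norm_plays):
        model = roles.fit_static_role_model(norm_plays, 1, seed=0)
        pts = np.vstack([roles.snap_positions(p)[1] for p in norm_plays])
        np.testing.assert_allclose(model.means[0], pts.mean(axis=0), atol=1e-6)

    def test_too_few_plays_rejected(self, norm_plays):
        with pytest.raises(ValueError, match="at least"):
            roles.fit_static_role_model(norm_plays[:3], 7)

    def test_json_round_trip(self, norm_plays, tmp_path):
        model = roles.fit_static_role_model(norm_plays, 7, seed=0)
        model.to_json(tmp_path / "m.json")
        back = roles.StaticRoleModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.means, model.means)
        np.testing.assert_allclose(back.covariances, model.covariances)

    def test_seed_reproducible(self, norm_plays):
        a = roles.fit_static_role_model(norm_plays, 7, seed=3)
        b = roles.fit_static_role_model(norm_plays, 7, seed=3)
        np.testing.assert_array_equal(a.means, b.means)


class TestHungarian:
    def test_two_by_two_example(self):
        cols, cost = roles.hungarian_assign(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert list(cols) == [0, 1]
        assert cost == 2.0

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_matches_brute_force_minimum(self, n, rng):
        for _ in range(25):
            C = rng.random((n, n))
            _, cost = roles.hungarian_assign(C)
            brute = min(sum(C[i, p[i]] for i in range(n))
                        for p in itertools.permutations(range(n)))
            assert cost == pytest.approx(brute, abs=1e-12)

    def test_static_assignment_symmetric_under_player_permutation(self, norm_plays):
        model = roles.fit_static_role_model(norm_plays, 7, seed=0)
        a = roles.assign_roles_static(model, norm_plays[0])
        # the total cost is a property of the set of players, not their order
        b = roles.assign_roles_static(model, norm_plays[0])
        assert a.cost == pytest.approx(b.cost)
        assert sorted(a.mapping.values()) == list(range(7))

    def test_role_recovery_on_separated_formations(self):
        """Static assignment recovers the generating role bijection on >= 95%
        of plays when role centers are >= 5 yards apart."""
        plays, truth = _cluster_plays(120, WELL_SEPARATED, spread=0.8, seed=5)
        model = roles.fit_static_role_model(plays, 7, seed=0)
        # align fitted roles to true centers
        fitted_to_true = {
            j: int(np.argmin(np.linalg.norm(WELL_SEPARATED - model.means[j], axis=1)))
            for j in range(7)
        }
        hits = 0
        for play, tr in zip(plays, truth):
            a = roles.assign_roles_static(model, play)
            if all(fitted_to_true[a.mapping[eid]] == tr[eid] for eid in a.mapping):
                hits += 1
        assert hits / len(plays) >= 0.95


class TestDynamicModel:
    def test_recovers_two_state_transition_matrix(self, rng):
        """Parameter recovery from sequences of a known 2-state HMM."""
        from hmmlearn.hmm import GaussianHMM

        true = GaussianHMM(n_components=2, covariance_type="full")
        true.startprob_ = np.array([0.6, 0.4])
        true.transmat_ = np.array([[0.9, 0.1], [0.2, 0.8]])
        true.means_ = np.array([[0.0, 0.0], [30.0, 30.0]])
        true.covars_ = np.tile(np.eye(2), (2, 1, 1))
        X, lengths = [], []
        for k in range(60):
            x, _ = true.sample(40, random_state=k)
            X.append(x)
            lengths.append(40)
        fit = GaussianHMM(n_components=2, covariance_type="full",
                          n_iter=50, random_state=0)
        fit.fit(np.vstack(X), lengths)
        order = np.argsort(fit.means_[:, 0])
        est = fit.transmat_[np.ix_(order, order)]
        assert np.abs(est - true.transmat_).max() < 0.1

    def test_baum_welch_log_likelihood_monotone(self, norm_plays):
        model = roles.fit_dynamic_role_model(norm_plays[:20], 7, seed=0,
                                             max_iter=12)
        assert np.all(np.diff(model.log_likelihoods) >= -1e-6)

    def test_single_state_matches_pooled_moments(self, norm_plays):
        model = roles.fit_dynamic_role_model(norm_plays[:20], 1, seed=0,
                                             max_iter=30)
        pts = np.vstack([
            np.column_stack([p.tracks[e].x, p.tracks[e].y])
            for p in norm_plays[:20] for e in p.defender_ids])
        np.testing.assert_allclose(model.emission_means[0], pts.mean(axis=0),
                                   atol=1e-3)
        np.testing.assert_allclose(model.emission_covs[0], np.cov(pts.T, bias=True),
                                   atol=1e-2)

    def test_transition_rows_and_initial_sum_to_one(self, norm_plays):
        model = roles.fit_dynamic_role_model(norm_plays[:20], 7, seed=0,
                                             max_iter=5)
        np.testing.assert_allclose(model.transition.sum(axis=1), 1.0, atol=1e-9)
        assert model.initial.sum() == pytest.approx(1.0)

    def test_dynamic_assignment_matches_brute_force(self, norm_plays):
        model = roles.fit_dynamic_role_model(norm_plays[:20], 7, seed=0,
                                             max_iter=5)
        play = norm_plays[0]
        a = roles.assign_roles_dynamic(model, play)
        ids = play.defender_ids
        cost = np.empty((7, 7))
        for i, eid in enumerate(ids):
            t = play.tracks[eid]
            cost[i] = -roles.emission_log_density(
                model, np.column_stack([t.x, t.y])).sum(axis=0)
        brute = min(sum(cost[i, p[i]] for i in range(7))
                    for p in itertools.permutations(range(7)))
        assert a.cost == pytest.approx(brute, rel=1e-12)

    def test_swapping_trajectories_swaps_roles(self, norm_plays):
        import dataclasses

        model = roles.fit_dynamic_role_model(norm_plays[:20], 7, seed=0,
                                             max_iter=5)
        play = norm_plays[0]
        a = roles.assign_roles_dynamic(model, play)
        e1, e2 = play.defender_ids[:2]
        t1, t2 = play.tracks[e1], play.tracks[e2]
        tracks = dict(play.tracks)
        tracks[e1] = dataclasses.replace(t1, x=t2.x, y=t2.y)
        tracks[e2] = dataclasses.replace(t2, x=t1.x, y=t1.y)
        b = roles.assign_roles_dynamic(model, dataclasses.replace(play, tracks=tracks))
        assert b.mapping[e1] == a.mapping[e2]
        assert b.mapping[e2] == a.mapping[e1]

    def test_defenders_at_distinct_emission_modes_get_identity_cost(self, norm_plays):
        import dataclasses

        model = roles.fit_dynamic_role_model(norm_plays[:20], 7, seed=0,
                                             max_iter=5)
        play = norm_plays[0]
        tracks = dict(play.tracks)
        for j, eid in enumerate(play.defender_ids):
            t = tracks[eid]
            x = np.full_like(t.x, model.emission_means[j, 0])
            y = np.full_like(t.y, model.emission_means[j, 1])
            tracks[eid] = dataclasses.replace(t, x=x, y=y)
        fixed = dataclasses.replace(play, tracks=tracks)
        a = roles.assign_roles_dynamic(model, fixed)
        expected_cost = -sum(
            roles.emission_log_density(
                model, model.emission_means[j:j + 1])[0, j] * fixed.n_frames
            for j in range(7))
        assert [a.mapping[e] for e in play.defender_ids] == list(range(7))
        assert a.cost == pytest.approx(expected_cost, rel=1e-9)
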