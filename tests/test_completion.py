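"""Pass-completion model: feature vector, augmentation, link function, metrics."""

import itertools

import numpy as np
import pytest
from scipy.special import expit

from gridghost import completion, synth, tracking


@pytest.fixture(scope="module")
def design(norm_plays):
    X = completion.design_matrix(norm_plays)
    return X


class TestFeatureVector:
    def test_nearest_two_defenders_ordered_and_relative_offsets(self, norm_plays):
        import dataclasses

        play = norm_plays[0]
        idx = play.frame_index(play.events["pass_forward"])
        # place receiver 0 at (10, -10); defenders at distances 1, 3, 5, ...
        tracks = dict(play.tracks)
        rec_ids = sorted(play.receiver_ids,
                         key=lambda e: (play.tracks[e].x[play.frame_index(play.events['ball_snap'])], e))
        r0 = rec_ids[0]
        t = tracks[r0]
        x, y = t.x.copy(), t.y.copy()
        x[idx], y[idx] = 10.0, -10.0
        tracks[r0] = dataclasses.replace(t, x=x, y=y)
        for k, eid in enumerate(play.defender_ids):
            t = tracks[eid]
            x, y = t.x.copy(), t.y.copy()
            x[idx], y[idx] = 10.0, -10.0 - (2 * k + 1)
            tracks[eid] = dataclasses.replace(t, x=x, y=y)
        fixed = dataclasses.replace(play, tracks=tracks)
        v = completion.build_feature_vector(fixed)
        block = v.receiver_blocks[0]
        np.testing.assert_allclose(block[:2], [10.0, -10.0])
        # nearest defender absolute position then relative offset (0, -1)
        np.testing.assert_allclose(block[3:5], [10.0, -11.0])
        np.testing.assert_allclose(block[5:7], [0.0, -1.0])
        # second nearest at relative (0, -3)
        np.testing.assert_allclose(block[10:12], [0.0, -3.0])

    def test_equidistant_defenders_tie_broken_by_entity_id(self, norm_plays):
        import dataclasses

        play = norm_plays[0]
        idx = play.frame_index(play.events["pass_forward"])
        tracks = dict(play.tracks)
        for eid in play.defender_ids:
            t = tracks[eid]
            x, y = t.x.copy(), t.y.copy()
            x[idx], y[idx] = 26.0, -20.0
            tracks[eid] = dataclasses.replace(t, x=x, y=y)
        fixed = dataclasses.replace(play, tracks=tracks)
        v = completion.build_feature_vector(fixed)
        w = completion.build_feature_vector(fixed)
        np.testing.assert_array_equal(v.flatten(), w.flatten())  # deterministic

    def test_vector_length_and_flat_round_trip(self, norm_plays):
        v = completion.build_feature_vector(norm_plays[0])
        flat = v.flatten()
        assert flat.shape == (completion.FEATURE_LEN,)
        back = completion.PassFeatureVector.from_flat(flat)
        np.testing.assert_array_equal(back.flatten(), flat)

    def test_translation_before_normalization_is_invariant(self):
        """The same physical formation at a different field position yields the
        same receiver/QB geometry blocks after normalization."""
        cfg = synth.SynthConfig(sigma=0.0, fixed_duration_s=3.0)
        play, _ = synth.generate_play(cfg, seed=3)
        n1 = tracking.clip_to_pass_window(tracking.normalize_play(play))
        shifted = tracking.mirror_play(play)
        n2 = tracking.clip_to_pass_window(tracking.normalize_play(shifted))
        v1 = completion.build_feature_vector(n1)
        v2 = completion.build_feature_vector(n2)
        np.testing.assert_allclose(v1.receiver_blocks, v2.receiver_blocks,
                                   atol=1e-9)
        np.testing.assert_allclose(v1.qb_block, v2.qb_block, atol=1e-9)


class TestPermuteReceivers:
    def test_identity_permutation(self, norm_plays):
        v = completion.build_feature_vector(norm_plays[0])
        same = completion.permute_receivers(v, permutation=np.arange(5))
        np.testing.assert_array_equal(same.flatten(), v.flatten())

    def test_permutation_then_inverse_is_identity(self, norm_plays):
        v = completion.build_feature_vector(norm_plays[0])
        perm = np.array([2, 0, 4, 1, 3])
        inv = np.argsort(perm)
        round_trip = completion.permute_receivers(
            completion.permute_receivers(v, permutation=perm), permutation=inv)
        np.testing.assert_array_equal(round_trip.flatten(), v.flatten())

    def test_qb_and_meta_blocks_untouched(self, norm_plays):
        v = completion.build_feature_vector(norm_plays[0])
        p = completion.permute_receivers(v, seed=9)
        np.testing.assert_array_equal(p.qb_block, v.qb_block)
        np.testing.assert_array_equal(p.meta_block, v.meta_block)

    def test_all_120_permutations_appear_over_seeded_draws(self, norm_plays):
        v = completion.build_feature_vector(norm_plays[0])
        rng = np.random.default_rng(123)
        seen = set()
        base = v.receiver_blocks[:, 0]
        for _ in range(1000):
            p = completion.permute_receivers(v, rng=rng)
            seen.add(tuple(np.searchsorted(np.sort(base), p.receiver_blocks[:, 0])))
        assert len(seen) == 120


class TestLinkFunction:
    def test_sigmoid_logit_round_trip_on_random_scores(self, rng):
        f = rng.normal(0, 4, 1000)
        p = expit(f)
        np.testing.assert_allclose(completion.score_to_logit(p), f, atol=1e-9)

    @pytest.mark.parametrize("backend", ["nn", "gbt"])
    def test_predict_proba_is_sigmoid_of_raw_score(self, backend, design,
                                                   small_collection):
        _, labels, _ = small_collection
        X = design
        cfg = completion.ClassifierConfig(backend=backend, seed=0,
                                          nn_max_epochs=10,
                                          gbt_n_estimators=20, augment=False)
        clf = completion.train_classifier(X, labels[:len(X)], cfg)
        p = completion.predict_proba(clf, X)
        f = completion.raw_score(clf, X)
        assert np.all((p > 0) & (p < 1))
        np.testing.assert_allclose(completion.score_to_logit(p), f, atol=1e-9)

    def test_shape_mismatch_rejected(self, design, small_collection):
        _, labels, _ = small_collection
        cfg = completion.ClassifierConfig(backend="gbt", seed=0,
                                          gbt_n_estimators=10, augment=False)
        clf = completion.train_classifier(design, labels[:len(design)], cfg)
        with pytest.raises(ValueError, match="dimension"):
            completion.predict_proba(clf, np.zeros((3, 5)))


class TestTraining:
    def test_separable_features_reach_perfect_training_accuracy(self, rng):
        X = rng.normal(0, 1, (400, completion.FEATURE_LEN))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += np.where(y == 1, 5.0, -5.0)
        cfg = completion.ClassifierConfig(backend="gbt", seed=0, augment=False,
                                          gbt_n_estimators=50)
        clf = completion.train_classifier(X, y, cfg)
        rep = completion.evaluate_classifier(clf, X, y)
        assert rep.accuracy == 1.0

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (50, completion.FEATURE_LEN))
        with pytest.raises(ValueError, match="single class"):
            completion.train_classifier(X, np.ones(50, dtype=int))

    def test_same_seed_same_predictions(self, design, small_collection):
        _, labels, _ = small_collection
        y = labels[:len(design)]
        cfg = completion.ClassifierConfig(backend="nn", seed=5, nn_max_epochs=15)
        p1 = completion.predict_proba(
            completion.train_classifier(design, y, cfg), design)
        p2 = completion.predict_proba(
            completion.train_classifier(design, y, cfg), design)
        np.testing.assert_array_equal(p1, p2)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            completion.ClassifierConfig(backend="forest")
        with pytest.raises(ValueError):
            completion.ClassifierConfig(nn_learning_rate=-1)


class TestEvaluation:
    def test_perfect_scores_give_accuracy_and_auroc_one(self):
        class _Stub:
            pass

        y = np.array([1, 1, 0, 0, 1])
        p = np.array([0.9, 0.9, 0.1, 0.1, 0.9])
        # exercise metric arithmetic directly via the brute-force oracle
        assert completion.auroc_brute_force(y, p) == 1.0

    def test_auroc_matches_brute_force_concordance(self, rng):
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        scores = rng.normal(0, 1, 100)
        from sklearn.metrics import roc_curve

        fpr, tpr, _ = roc_curve(y, scores)
        trapz = float(np.trapezoid(tpr, fpr))
        assert trapz == pytest.approx(completion.auroc_brute_force(y, scores),
                                      abs=1e-12)

    def test_label_independent_scores_have_half_auroc(self, rng):
        y = rng.integers(0, 2, 2000)
        scores = rng.normal(0, 1, 2000)
        assert completion.auroc_brute_force(y, scores) == pytest.approx(0.5,
                                                                        abs=0.03)

    def test_hand_computed_four_sample_roc(self):
        y = np.array([1, 0, 1, 0])
        p = np.array([0.9, 0.8, 0.6, 0.1])
        # threshold sweep by hand: pairs concordant except (0.6 vs 0.8)
        assert completion.auroc_brute_force(y, p) == pytest.approx(3 / 4)

    def test_report_fields(self, design, small_collection):
        _, labels, _ = small_collection
        y = labels[:len(design)]
        cfg = completion.ClassifierConfig(backend="gbt", seed=0,
                                          gbt_n_estimators=30, augment=False)
        clf = completion.train_classifier(design, y, cfg)
        rep = completion.evaluate_classifier(clf, design, y)
        assert 0 <= rep.auroc <= 1
        assert rep.miss_classification == pytest.approx(1 - rep.accuracy)
        assert rep.baseline_accuracy == pytest.approx(np.mean(y))
        assert np.all(np.diff(rep.roc_points[:, 1]) >= 0)  # tpr monotone

    def test_empty_input_rejected(self, design, small_collection):
        _, labels, _ = small_collection
        cfg = completion.ClassifierConfig(backend="gbt", seed=0,
                                          gbt_n_estimators=10, augment=False)
        clf = completion.train_classifier(design, labels[:len(design)], cfg)
        with pytest.raises(ValueError, match="empty"):
            completion.evaluate_classifier(clf, np.empty((0, completion.FEATURE_LEN)),
                                           np.empty(0))


class TestOrderInvariance:
    def test_score_zero_for_receiver_blind_model(self, design, small_collection):
        _, labels, _ = small_collection
        y = labels[:len(design)]
        X = design.copy()
        nr = completion.N_RECEIVER_BLOCKS * completion.RECEIVER_BLOCK_LEN
        X[:, :nr] = 0.0  # no receiver information at all
        cfg = completion.ClassifierConfig(backend="gbt", seed=0,
                                          gbt_n_estimators=20, augment=False)
        clf = completion.train_classifier(X, y, cfg)
        assert completion.order_invariance_score(clf, X[:5]) == 0.0

    def test_score_non_negative(self, design, small_collection):
        _, labels, _ = small_collection
        cfg = completion.ClassifierConfig(backend="gbt", seed=0,
                                          gbt_n_estimators=20, augment=False)
        clf = completion.train_classifier(design, labels[:len(design)], cfg)
        assert completion.order_invariance_score(clf, design[:3]) >= 0.0
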