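"""End-to-end reproduction studies on generator data.

Each function runs one self-contained experiment — generating its own synthetic
inputs, fitting the relevant models and measuring the result — and returns a flat
dict of numbers.  The test suite asserts properties of these dicts; the
acceptance script reports them.  Problem sizes are fixed study conditions chosen
to keep a full run on one CPU core in the tens of minutes (docs/methods.md
discusses the choices).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import expit

from . import completion, evaluation, ghosting, roles, synth, tracking


def _prep(coll: tracking.PlayCollection) -> list[tracking.Play]:
    return [tracking.clip_to_pass_window(tracking.normalize_play(p))
            for p in tracking.filter_plays(coll)]


# ---------------------------------------------------------------------------
# link function and assignment exactness
# ---------------------------------------------------------------------------

def sigmoid_logit_roundtrip(seed: int, n: int = 1000) -> dict:
    """Exactness of the logistic link: logit(sigmoid(f)) == f."""
    rng = np.random.default_rng(seed)
    f = rng.normal(0.0, 4.0, n)
    err = float(np.abs(completion.score_to_logit(expit(f)) - f).max())
    return {"max_abs_error": err, "n": n}


def hungarian_agreement(seed: int, n_matrices: int = 100) -> dict:
    """Hungarian vs exhaustive permutation minimum for sizes 2..7."""
    rng = np.random.default_rng(seed)
    agree = total = 0
    for _ in range(n_matrices):
        n = int(rng.integers(2, 8))
        C = rng.random((n, n))
        _, cost = roles.hungarian_assign(C)
        brute = min(sum(C[i, p[i]] for i in range(n))
                    for p in itertools.permutations(range(n)))
        agree += abs(cost - brute) < 1e-12
        total += 1
    return {"agreement_rate": agree / total, "n": total}


# ---------------------------------------------------------------------------
# role alignment
# ---------------------------------------------------------------------------

ROLE_CENTERS = np.array([[5.0, -5], [13, -5], [21, -5], [29, -5],
                         [37, -5], [45, -5], [25, -14]])


def role_recovery_study(seed: int, n_plays: int = 500) -> dict:
    """Static role recovery on formations drawn from 7 known clusters
    (centers >= 5 yards apart), plus EM/Baum–Welch likelihood monotonicity."""
    rng = np.random.default_rng(seed)
    cfg = synth.SynthConfig(sigma=0.0, fixed_duration_s=2.0)
    plays, truth = [], []
    for k in range(n_plays):
        play, _ = synth.generate_play(cfg, seed=seed * 100_003 % (2**30) + k)
        play = tracking.normalize_play(play)
        perm = rng.permutation(7)
        for j, eid in enumerate(play.defender_ids):
            c = ROLE_CENTERS[perm[j]] + rng.normal(0, 0.8, 2)
            play.tracks[eid].x[:] = c[0]
            play.tracks[eid].y[:] = c[1]
        plays.append(play)
        truth.append({eid: int(perm[j]) for j, eid in enumerate(play.defender_ids)})

    model = roles.fit_static_role_model(plays, 7, seed=seed)
    gmm_monotone = bool(np.all(np.diff(model.log_likelihoods) >= -1e-9))
    fitted_to_true = {
        j: int(np.argmin(np.linalg.norm(ROLE_CENTERS - model.means[j], axis=1)))
        for j in range(7)}
    hits = 0
    for play, tr in zip(plays, truth):
        a = roles.assign_roles_static(model, play)
        hits += all(fitted_to_true[a.mapping[e]] == tr[e] for e in a.mapping)

    hmm_plays = _prep(synth.generate_dataset(30, seed=seed + 1)[0])
    dyn = roles.fit_dynamic_role_model(hmm_plays, 7, seed=seed, max_iter=12)
    hmm_monotone = bool(np.all(np.diff(dyn.log_likelihoods) >= -1e-6))
    return {"recovery_rate": hits / n_plays, "n": n_plays,
            "gmm_loglik_monotone": gmm_monotone,
            "hmm_loglik_monotone": hmm_monotone}


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

def auroc_checks(seed: int, n_random: int = 2000) -> dict:
    """Trapezoidal-AUROC vs pairwise concordance, perfect and chance cases."""
    from sklearn.metrics import roc_curve

    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, 100)
    y[:2] = [0, 1]
    s = rng.normal(0, 1, 100)
    fpr, tpr, _ = roc_curve(y, s)
    impl = float(np.trapezoid(tpr, fpr))
    brute = completion.auroc_brute_force(y, s)

    y_perf = np.array([0] * 50 + [1] * 50)
    s_perf = np.concatenate([rng.uniform(0, 0.4, 50), rng.uniform(0.6, 1, 50)])
    perfect = completion.auroc_brute_force(y_perf, s_perf)

    y_rand = rng.integers(0, 2, n_random)
    s_rand = rng.normal(0, 1, n_random)
    chance = completion.auroc_brute_force(y_rand, s_rand)
    return {"impl_vs_brute_abs_diff": abs(impl - brute),
            "perfect_auroc": perfect, "chance_auroc": chance, "n": n_random}


_COMPLETION_CACHE: dict = {}


def _completion_dataset(seed: int, n_plays: int = 5000):
    """Low-noise completion dataset shared by the recovery and order-invariance
    studies (generation dominates their cost)."""
    key = (seed, n_plays)
    if key not in _COMPLETION_CACHE:
        cfg = synth.SynthConfig(sigma=0.05)
        coll, labels, probs = synth.generate_dataset(n_plays, cfg, seed=seed)
        plays = _prep(coll)
        X = completion.design_matrix(plays)
        _COMPLETION_CACHE.clear()  # keep at most one dataset in memory
        _COMPLETION_CACHE[key] = (X, labels[:len(X)], probs[:len(X)])
    return _COMPLETION_CACHE[key]


def completion_recovery_study(seed: int, n_plays: int = 5000,
                              backend: str = "nn") -> dict:
    """Held-out discrimination and decile calibration against the generator's
    known logistic ground truth at low reaction noise."""
    X, labels, probs = _completion_dataset(seed, n_plays)
    n_tr = int(0.8 * len(X))
    cfg = completion.ClassifierConfig(backend=backend, augment=True, seed=seed)
    clf = completion.train_classifier(X[:n_tr], labels[:n_tr], cfg)
    rep = completion.evaluate_classifier(clf, X[n_tr:], labels[n_tr:])
    p = completion.predict_proba(clf, X[n_tr:])
    pt = probs[n_tr:]
    edges = np.quantile(p, np.linspace(0, 1, 11))
    errs = [abs(p[m].mean() - pt[m].mean())
            for lo, hi in zip(edges[:-1], edges[1:])
            if (m := (p >= lo) & (p <= hi)).sum() > 5]
    return {"auroc": rep.auroc, "accuracy": rep.accuracy,
            "miss_classification": rep.miss_classification,
            "baseline_accuracy": rep.baseline_accuracy,
            "max_decile_calibration_error": float(max(errs)),
            "n_train": n_tr, "n_test": len(X) - n_tr}


def order_invariance_study(seed: int, n_plays: int = 5000,
                           n_probe: int = 40) -> dict:
    """Paired comparison: the network trained with per-epoch receiver-block
    permutation vs the identical architecture trained on ordered data."""
    X, labels, _ = _completion_dataset(seed, n_plays)
    n_tr = int(0.8 * len(X))
    out = {}
    for augment in (True, False):
        cfg = completion.ClassifierConfig(backend="nn", augment=augment,
                                          seed=seed)
        clf = completion.train_classifier(X[:n_tr], labels[:n_tr], cfg)
        rep = completion.evaluate_classifier(clf, X[n_tr:], labels[n_tr:])
        score = completion.order_invariance_score(clf, X[n_tr:n_tr + n_probe])
        tag = "augmented" if augment else "ordered"
        out[f"score_{tag}"] = score
        out[f"accuracy_{tag}"] = rep.accuracy
    out["n"] = n_tr
    return out


# ---------------------------------------------------------------------------
# imitation learning
# ---------------------------------------------------------------------------

def _man_fixture(seed: int, n_plays: int):
    cfg = synth.SynthConfig(sigma=0.2, fixed_duration_s=6.0,
                            gain_range=(0.3, 0.3))
    coll, _, _ = synth.generate_dataset(n_plays, cfg, seed=seed)
    return _prep(coll)


def imitation_study(seed: int, n_plays: int = 200) -> dict:
    """Scripted man-coverage reproduction: single-role rollout error of the
    pretrain+DAgger policies vs a pretrain-only arm given the same refit budget.
    """
    plays = _man_fixture(seed, n_plays)
    n_tr = int(0.8 * len(plays))
    train, val = plays[:n_tr], plays[n_tr:]
    gcfg = ghosting.GhostConfig(hidden_size=32, learning_rate=2e-3,
                                pretrain_epochs=40, dagger_iters=5,
                                dagger_refit_epochs=10, seed=seed)
    model = ghosting.GhostModel(gcfg)
    model.fit_role_models(train, seed)
    windows = ghosting.make_training_windows(model.tensors(train))
    ghosting.pretrain_policies(model, windows, seed=seed)

    # pretrain-only arm: the DAgger refit budget is spent on more
    # teacher-forced epochs instead (equal budget, paired seed)
    arm = ghosting.GhostModel(gcfg)
    arm.static_role_model = model.static_role_model
    arm.offense_role_model = model.offense_role_model
    arm.policies = [p.clone() for p in model.policies]
    inputs = [w.inputs for w in windows]
    extra = gcfg.dagger_iters * gcfg.dagger_refit_epochs
    for r in range(ghosting.N_ROLES):
        arm.policies[r].fit_windows(
            inputs, [w.targets[:, r, :] for w in windows],
            epochs=extra, batch_size=gcfg.batch_size, seed=seed + 100 + r)

    for r in range(ghosting.N_ROLES):
        ghosting.dagger_train_single(model, r, windows, seed=seed + r)

    prof_pre = ghosting.single_role_error_profiles(arm, val)
    prof_dag = ghosting.single_role_error_profiles(model, val)
    idx3 = min(30, prof_dag.shape[1] - 1)
    return {
        "dagger_mae_3s": float(prof_dag[:, idx3].mean()),
        "pretrain_mae_3s": float(prof_pre[:, idx3].mean()),
        "dagger_final_mae": float(prof_dag[:, -1].mean()),
        "pretrain_final_mae": float(prof_pre[:, -1].mean()),
        "n_plays": n_plays,
        "_model": model, "_val": val,  # reused by ghost_comparison_study
    }


def ghost_comparison_study(seed: int, imitation: dict | None = None) -> dict:
    """Completion-probability agreement between observed and ghosted defenses,
    scored by an independently trained completion classifier."""
    imitation = imitation or imitation_study(seed)
    model, val = imitation["_model"], imitation["_val"]
    X, labels, _ = _completion_dataset(seed)
    cfg = completion.ClassifierConfig(backend="gbt", augment=True, seed=seed)
    clf = completion.train_classifier(X, labels, cfg)
    ghosts = [ghosting.ghost_play(model, p) for p in val]
    cmp_ = evaluation.compare_completion(val, ghosts, clf)
    return {
        "pearson_r": cmp_.pearson_r if cmp_.pearson_r is not None else float("nan"),
        "mean_true_probability": float(cmp_.true_probs.mean()),
        "mean_ghost_probability": float(cmp_.ghost_probs.mean()),
        "n_plays": len(val),
    }


def coordination_study(seed: int, n_plays: int = 100) -> dict:
    """Role-switch fixture: alternating (cross-update) optimization vs training
    with the snap-frame static assignment, same seeds and budgets per cycle."""
    cfg = synth.SynthConfig(sigma=0.05, fixed_duration_s=5.0,
                            gain_range=(0.3, 0.3), routes=("hitch",) * 5)
    coll, _, _ = synth.generate_dataset(n_plays, cfg, seed=seed)
    rng = np.random.default_rng(seed + 1)
    switched = []
    for p in coll:
        pair = tuple(sorted(rng.choice(5, 2, replace=False)))
        t = 0 if rng.random() < 0.5 else int(rng.integers(10, 18))
        switched.append(synth.inject_role_switch(p, t, pair=pair))
    plays = _prep(tracking.PlayCollection(plays=switched))
    n_tr = int(0.8 * len(plays))
    train, val = plays[:n_tr], plays[n_tr:]
    gcfg = ghosting.GhostConfig(hidden_size=32, learning_rate=2e-3,
                                pretrain_epochs=60, alternate_max_cycles=2,
                                alternate_tol=1e-4, seed=seed)

    static_model = ghosting.GhostModel(gcfg)
    static_model.fit_role_models(train, seed)
    w_static = ghosting.make_training_windows(static_model.tensors(train))
    best = (np.inf, None)
    for cyc in range(gcfg.alternate_max_cycles):
        ghosting.train_policies_on_windows(static_model, w_static,
                                           seed=seed + 1000 * cyc,
                                           use_dagger=False)
        mae = ghosting.validation_rollout_mae(static_model, val)
        if mae < best[0]:
            best = (mae, [p.clone() for p in static_model.policies])
    static_model.policies = best[1]

    alt_model = ghosting.GhostModel(gcfg)
    alt_model.static_role_model = static_model.static_role_model
    alt_model.offense_role_model = static_model.offense_role_model
    ghosting.alternate_optimize(alt_model, train, val, seed=seed,
                                use_dagger=False)

    prof_static = ghosting.joint_rollout_error_profiles(static_model, val)
    prof_alt = ghosting.joint_rollout_error_profiles(alt_model, val)
    return {
        "static_mae": float(prof_static.mean()),
        "alternating_mae": float(prof_alt.mean()),
        "static_per_role": prof_static.mean(axis=1).tolist(),
        "alternating_per_role": prof_alt.mean(axis=1).tolist(),
        "n_plays": n_plays,
    }


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

def determinism_study(seed: int) -> dict:
    """Bit-reproducibility of generation and training under a fixed seed."""
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as d:
        files = {}
        for sub in ("a", "b"):
            coll, _, probs = synth.generate_dataset(5, seed=seed)
            synth.write_dataset(coll, probs, Path(d) / sub)
            files[sub] = sorted((Path(d) / sub).iterdir())
        gen_ok = all(x.read_bytes() == y.read_bytes()
                     for x, y in zip(files["a"], files["b"]))

    plays = _prep(synth.generate_dataset(30, seed=seed + 2)[0])
    X = completion.design_matrix(plays)
    y = np.array([1 if p.meta.pass_outcome == "complete" else 0 for p in plays])
    cfg = completion.ClassifierConfig(backend="nn", seed=seed, nn_max_epochs=10)
    p1 = completion.predict_proba(completion.train_classifier(X, y, cfg), X)
    p2 = completion.predict_proba(completion.train_classifier(X, y, cfg), X)
    clf_ok = bool(np.array_equal(p1, p2))

    from .policies import LSTMPolicy, PolicyConfig

    hashes = []
    rng = np.random.default_rng(seed)
    Xw = list(rng.normal(0, 3, (10, 8, 4)))
    Tw = list(rng.normal(0, 0.3, (10, 8, 2)))
    for _ in range(2):
        pol = LSTMPolicy(PolicyConfig(input_dim=4, hidden_size=8, seed=seed))
        pol.fit_windows(Xw, Tw, epochs=3, batch_size=4, seed=seed)
        hashes.append(pol.weights_hash())
    policy_ok = hashes[0] == hashes[1]
    return {"generation_bit_reproducible": gen_ok,
            "classifier_reproducible": clf_ok,
            "policy_reproducible": policy_ok}
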