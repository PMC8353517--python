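"""Formation-based pass-completion probability model.

A pass is treated as a single binary outcome for the whole formation (caught = 1,
incomplete or intercepted = 0), skipping the question of which receiver was
targeted.  The model scores the formation at the moment the quarterback releases
the ball:

    P(y = 1 | X) = 1 / (1 + exp(-f(X)))            (logistic link)
    logit P(y = 1 | X) = f(X)

where X is a fixed-length feature vector built from the five receivers (each with
its two nearest defenders), the quarterback, and game-state metadata, and f is a
feed-forward network or a gradient-boosted tree ensemble.  Because receiver slots
carry no intrinsic order, training can randomly permute the receiver blocks each
epoch, which teaches the model order invariance and is what lifts its accuracy
well above the all-catch baseline.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit as _logit
from sklearn.metrics import log_loss, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .tracking import Play

#: per-receiver block: own (x', y', s) then two nearest defenders, nearer first,
#: each as (abs x', abs y', rel dx, rel dy, speed)
RECEIVER_BLOCK_LEN = 3 + 2 * 5
QB_BLOCK_LEN = 3
META_BLOCK_LEN = 3
N_RECEIVER_BLOCKS = 5
FEATURE_LEN = N_RECEIVER_BLOCKS * RECEIVER_BLOCK_LEN + QB_BLOCK_LEN + META_BLOCK_LEN


@dataclass
class PassFeatureVector:
    """Formation encoding at the pass_forward frame."""

    receiver_blocks: np.ndarray  # (5, RECEIVER_BLOCK_LEN)
    qb_block: np.ndarray         # (QB_BLOCK_LEN,)
    meta_block: np.ndarray       # (yard line, down, yards_to_go)

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.receiver_blocks.ravel(),
                               self.qb_block, self.meta_block])

    @classmethod
    def from_flat(cls, flat: np.ndarray) -> "PassFeatureVector":
        if flat.shape[-1] != FEATURE_LEN:
            raise ValueError(f"expected length {FEATURE_LEN}, got {flat.shape[-1]}")
        nr = N_RECEIVER_BLOCKS * RECEIVER_BLOCK_LEN
        return cls(flat[:nr].reshape(N_RECEIVER_BLOCKS, RECEIVER_BLOCK_LEN),
                   flat[nr:nr + QB_BLOCK_LEN], flat[nr + QB_BLOCK_LEN:])


def build_feature_vector(play: Play, frame_id: int | None = None) -> PassFeatureVector:
    """Encode a normalized play's formation at the pass_forward frame.

    Receiver blocks are ordered by snap-frame x' (ties by entity id) so the raw
    ordering is deterministic; each receiver independently gets its two nearest
    defenders at the evaluation frame (nearer first, distance ties broken by
    ascending entity id), so a defender may appear in several blocks.  Passing a
    ``frame_id`` evaluates the same encoding at any other frame of the window
    (used for probability-over-time curves).
    """
    if not play.normalized:
        raise ValueError(f"play {play.key} must be normalized")
    if "pass_forward" not in play.events and frame_id is None:
        raise ValueError(f"play {play.key}: no pass_forward frame")
    fr = frame_id if frame_id is not None else play.events["pass_forward"]
    idx = play.frame_index(fr)
    snap_idx = play.frame_index(play.events["ball_snap"])

    rec_ids = sorted(play.receiver_ids,
                     key=lambda e: (play.tracks[e].x[snap_idx], e))
    def_ids = play.defender_ids
    dpos = np.array([[play.tracks[d].x[idx], play.tracks[d].y[idx]] for d in def_ids])
    dspeed = np.array([play.tracks[d].s[idx] for d in def_ids])

    blocks = np.empty((N_RECEIVER_BLOCKS, RECEIVER_BLOCK_LEN))
    for i, rid in enumerate(rec_ids):
        r = play.tracks[rid]
        rp = np.array([r.x[idx], r.y[idx]])
        dist = np.linalg.norm(dpos - rp, axis=1)
        # ties broken by entity id: def_ids is ascending and argsort is stable
        nearest = np.argsort(dist, kind="stable")[:2]
        feats = [rp[0], rp[1], r.s[idx]]
        for j in nearest:
            feats += [dpos[j, 0], dpos[j, 1],
                      dpos[j, 0] - rp[0], dpos[j, 1] - rp[1], dspeed[j]]
        blocks[i] = feats

    qb = play.tracks[play.qb_id]
    qb_block = np.array([qb.x[idx], qb.y[idx], qb.s[idx]])
    meta_block = np.array([play.meta.absolute_field_position,
                           float(play.meta.down), play.meta.yards_to_go])
    return PassFeatureVector(blocks, qb_block, meta_block)


def permute_receivers(vector: PassFeatureVector, seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      permutation: np.ndarray | None = None) -> PassFeatureVector:
    """Reorder the five receiver blocks by a seeded uniform-random permutation.

    The QB and metadata blocks are untouched.  An explicit ``permutation`` wins
    over ``rng`` which wins over ``seed``.
    """
    if permutation is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        permutation = rng.permutation(N_RECEIVER_BLOCKS)
    return replace(vector, receiver_blocks=vector.receiver_blocks[permutation])


def _permute_flat(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute the receiver blocks of each row of a design matrix."""
    n = len(X)
    nr = N_RECEIVER_BLOCKS * RECEIVER_BLOCK_LEN
    blocks = X[:, :nr].reshape(n, N_RECEIVER_BLOCKS, RECEIVER_BLOCK_LEN)
    perms = np.argsort(rng.random((n, N_RECEIVER_BLOCKS)), axis=1)
    permuted = blocks[np.arange(n)[:, None], perms]
    return np.concatenate([permuted.reshape(n, nr), X[:, nr:]], axis=1)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

@dataclass
class ClassifierConfig:
    """Hyperparameters for the completion classifiers.

    The network is three fully-connected layers (64, 64, 32) trained with Adam at
    learning rate 2e-3 and batch size 1024; the gradient-boosted trees use depth
    10, 60 leaves and learning rate 0.03.  ``augment`` resamples the receiver
    permutation independently every epoch (network) or materializes
    ``augment_copies`` permuted copies of the training set (trees).
    """

    backend: str = "nn"                     # nn | gbt
    nn_hidden: tuple[int, ...] = (64, 64, 32)
    nn_learning_rate: float = 2e-3
    nn_batch_size: int = 1024
    nn_max_epochs: int = 200
    nn_patience: int = 10
    gbt_max_depth: int = 10
    gbt_num_leaves: int = 60
    gbt_learning_rate: float = 0.03
    gbt_n_estimators: int = 300
    gbt_min_child_samples: int = 20  # lower it for tiny fixtures
    cv_folds: int = 7
    augment: bool = True
    augment_copies: int = 8
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.backend not in ("nn", "gbt"):
            raise ValueError(f"unknown backend {self.backend!r}")
        for name in ("nn_learning_rate", "nn_batch_size", "nn_max_epochs",
                     "gbt_max_depth", "gbt_num_leaves", "gbt_learning_rate",
                     "cv_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainedClassifier:
    backend: str
    model: object
    scaler: StandardScaler | None
    config: ClassifierConfig
    manifest: dict = field(default_factory=dict)


def raw_score(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """The model's raw score f(X): the logit of the completion probability."""
    X = np.atleast_2d(X)
    if clf.backend == "gbt":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return clf.model.predict(X, raw_score=True)
    Xs = clf.scaler.transform(X)
    # manual forward pass through the fitted MLP: relu hidden, linear output
    a = Xs
    n_layers = len(clf.model.coefs_)
    for li, (W, b) in enumerate(zip(clf.model.coefs_, clf.model.intercepts_)):
        a = a @ W + b
        if li < n_layers - 1:
            a = np.maximum(a, 0.0)
    return a.ravel()


def predict_proba(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Completion probabilities P(y=1|X) = sigmoid(f(X)), strictly inside (0, 1)."""
    X = np.atleast_2d(X)
    if X.shape[1] != FEATURE_LEN:
        raise ValueError(f"feature dimension {X.shape[1]} != {FEATURE_LEN}")
    return expit(raw_score(clf, X))


def score_to_logit(p: np.ndarray) -> np.ndarray:
    """Inverse of the logistic link (Eq. 2 consistency helper)."""
    return _logit(p)


def _fit_nn(X, y, config: ClassifierConfig) -> TrainedClassifier:
    rng = np.random.default_rng(config.seed)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=config.validation_fraction, stratify=y,
        random_state=config.seed)
    scaler = StandardScaler().fit(X_tr)
    mlp = MLPClassifier(hidden_layer_sizes=config.nn_hidden, solver="adam",
                        learning_rate_init=config.nn_learning_rate,
                        batch_size=min(config.nn_batch_size, len(X_tr)),
                        random_state=config.seed, max_iter=1, warm_start=False)
    classes = np.unique(y)
    best_loss, best_params, patience_left = np.inf, None, config.nn_patience
    epoch_losses = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for epoch in range(config.nn_max_epochs):
            X_ep = _permute_flat(X_tr, rng) if config.augment else X_tr
            order = rng.permutation(len(X_ep))
            mlp.partial_fit(scaler.transform(X_ep[order]), y_tr[order], classes=classes)
            val_loss = log_loss(y_val, mlp.predict_proba(scaler.transform(X_val)),
                                labels=classes)
            epoch_losses.append(float(val_loss))
            if val_loss < best_loss - 1e-5:
                best_loss = val_loss
                best_params = ([W.copy() for W in mlp.coefs_],
                               [b.copy() for b in mlp.intercepts_])
                patience_left = config.nn_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if best_params is not None:
        mlp.coefs_, mlp.intercepts_ = best_params
    manifest = {"backend": "nn", "epochs_run": len(epoch_losses),
                "val_loss": epoch_losses, "seed": config.seed,
                "augment": config.augment, "n_train": int(len(X_tr))}
    return TrainedClassifier("nn", mlp, scaler, config, manifest)


def _fit_gbt(X, y, config: ClassifierConfig) -> TrainedClassifier:
    import lightgbm as lgb

    rng = np.random.default_rng(config.seed)
    if config.augment:
        Xa = np.vstack([_permute_flat(X, rng) for _ in range(config.augment_copies)])
        ya = np.tile(y, config.augment_copies)
    else:
        Xa, ya = X, y
    model = lgb.LGBMClassifier(
        max_depth=config.gbt_max_depth, num_leaves=config.gbt_num_leaves,
        learning_rate=config.gbt_learning_rate,
        n_estimators=config.gbt_n_estimators,
        min_child_samples=config.gbt_min_child_samples,
        random_state=config.seed, deterministic=True, n_jobs=1, verbose=-1)
    model.fit(Xa, ya)
    manifest = {"backend": "gbt", "seed": config.seed, "augment": config.augment,
                "n_train": int(len(Xa))}
    return TrainedClassifier("gbt", model, None, config, manifest)


def train_classifier(X: np.ndarray, y: np.ndarray,
                     config: ClassifierConfig | None = None) -> TrainedClassifier:
    """Fit a completion classifier on flattened feature vectors.

    Requires both classes present.  With ``augment`` on, the network sees an
    independently permuted copy of every training row each epoch; the tree
    backend trains on several materialized permuted copies instead (trees have
    no epochs).  Training is deterministic for a fixed config seed.
    """
    config = config or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    if config.backend == "nn":
        return _fit_nn(X, y, config)
    return _fit_gbt(X, y, config)


def cross_validate(X: np.ndarray, y: np.ndarray,
                   config: ClassifierConfig | None = None) -> list[dict]:
    """Stratified k-fold cross-validation (default 7 folds); returns per-fold
    evaluation reports."""
    config = config or ClassifierConfig()
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed)
    reports = []
    for tr, te in skf.split(X, y):
        clf = train_classifier(X[tr], y[tr], config)
        reports.append(evaluate_classifier(clf, X[te], y[te]).__dict__)
    return reports


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    accuracy: float
    miss_classification: float
    auroc: float
    roc_points: np.ndarray        # (n, 2) of (fpr, tpr), monotone
    baseline_accuracy: float      # "every pass is a catch"
    n: int


def evaluate_classifier(clf: TrainedClassifier, X: np.ndarray,
                        y: np.ndarray) -> EvalReport:
    """Accuracy at threshold 0.5, full ROC sweep and trapezoidal AUROC, against
    the all-catch baseline."""
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    p = predict_proba(clf, X)
    acc = float(np.mean((p >= 0.5) == (y == 1)))
    fpr, tpr, _ = roc_curve(y, p)
    auroc = float(np.trapezoid(tpr, fpr))
    return EvalReport(accuracy=acc, miss_classification=1.0 - acc, auroc=auroc,
                      roc_points=np.column_stack([fpr, tpr]),
                      baseline_accuracy=float(np.mean(y == 1)), n=len(y))


def auroc_brute_force(y: np.ndarray, scores: np.ndarray) -> float:
    """Pairwise-concordance AUROC (independent oracle for small n)."""
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def order_invariance_score(clf: TrainedClassifier, X: np.ndarray) -> float:
    """Max over rows of (max − min predicted probability across all 120 receiver
    permutations).  A perfectly order-invariant model scores 0."""
    X = np.atleast_2d(X)
    nr = N_RECEIVER_BLOCKS * RECEIVER_BLOCK_LEN
    perms = np.array(list(itertools.permutations(range(N_RECEIVER_BLOCKS))))
    worst = 0.0
    blocks = X[:, :nr].reshape(len(X), N_RECEIVER_BLOCKS, RECEIVER_BLOCK_LEN)
    for row_blocks, rest in zip(blocks, X[:, nr:]):
        variants = np.concatenate(
            [row_blocks[perms].reshape(len(perms), nr),
             np.tile(rest, (len(perms), 1))], axis=1)
        p = predict_proba(clf, variants)
        worst = max(worst, float(p.max() - p.min()))
    return worst


def design_matrix(plays: list[Play]) -> np.ndarray:
    """Stack flattened pass-event feature vectors for a list of normalized plays."""
    return np.vstack([build_feature_vector(p).flatten() for p in plays])
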