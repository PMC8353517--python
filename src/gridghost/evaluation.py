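"""Ghost-fidelity metrics.

Two complementary views of how faithful simulated defenders are to the observed
ones: geometric error (mean absolute position error per timestep and per role over
the rollout), and a tactical "third-party" comparison — the trained
pass-completion model scores the formation with the observed defense and with the
ghost defense substituted, and the two probability series are correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from . import completion as completion_mod
from .ghosting import GhostModel, ghost_play
from .tracking import Play


@dataclass
class RolloutErrorProfile:
    """Rollout error on the 10 Hz grid: all entries in yards, all >= 0."""

    per_timestep_mae: np.ndarray  # (T,) mean over defenders
    per_role_mae: np.ndarray      # (7,) mean over timesteps
    per_role_per_timestep: np.ndarray  # (T, 7)
    overall_mae: float


@dataclass
class GhostComparison:
    """Completion-probability comparison between observed and ghost defenses."""

    true_probs: np.ndarray
    ghost_probs: np.ndarray
    pearson_r: float | None        # None flags undefined (zero variance)
    curve_true: np.ndarray | None  # per-timestep mean completion probability
    curve_ghost: np.ndarray | None


def rollout_mae(true_traj: np.ndarray, ghost_traj: np.ndarray) -> RolloutErrorProfile:
    """Euclidean position error between (T, n_defenders, 2) trajectories.

    Per-timestep MAE averages over defenders; per-role MAE averages over
    timesteps.  Raises on mismatched grids.
    """
    true_traj = np.asarray(true_traj)
    ghost_traj = np.asarray(ghost_traj)
    if true_traj.shape != ghost_traj.shape:
        raise ValueError(f"trajectory grids differ: {true_traj.shape} vs "
                         f"{ghost_traj.shape}")
    err = np.linalg.norm(true_traj - ghost_traj, axis=2)  # (T, n)
    return RolloutErrorProfile(
        per_timestep_mae=err.mean(axis=1),
        per_role_mae=err.mean(axis=0),
        per_role_per_timestep=err,
        overall_mae=float(err.mean()),
    )


def mae_at_time(profile: RolloutErrorProfile, seconds: float,
                frame_rate: float = 10.0) -> float:
    """Per-timestep MAE at a given time after the snap (clamped to the last frame)."""
    idx = min(int(round(seconds * frame_rate)), len(profile.per_timestep_mae) - 1)
    return float(profile.per_timestep_mae[idx])


def pearson_r(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson correlation; ``None`` (flagged null) when either side has zero
    variance instead of raising."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return None
    r = float(pearsonr(x, y).statistic)
    return r if np.isfinite(r) else None


def completion_curve(clf, play: Play) -> np.ndarray:
    """Completion probability evaluated at every frame of the play window.

    The pass-event feature builder is applied frame by frame — extending the
    pass-moment model over the whole window to get a probability-over-time curve.
    """
    probs = []
    for fr in play.frame_ids:
        v = completion_mod.build_feature_vector(play, frame_id=int(fr))
        probs.append(completion_mod.predict_proba(clf, v.flatten())[0])
    return np.asarray(probs)


def compare_completion(true_plays: list[Play], ghost_plays: list[Play],
                       clf, with_curves: bool = False) -> GhostComparison:
    """Score each play's formation at the pass event with observed vs ghost
    defense and correlate the probabilities over plays (order-invariant: plays
    are matched by key).

    ``with_curves`` additionally averages per-timestep probability curves over
    plays (aligned at the snap, averaged over plays still in progress).
    """
    ghost_by_key = {p.key: p for p in ghost_plays}
    tp, gp = [], []
    curves_t: list[np.ndarray] = []
    curves_g: list[np.ndarray] = []
    for play in sorted(true_plays, key=lambda p: p.key):
        if play.key not in ghost_by_key:
            raise ValueError(f"no ghost play for {play.key}")
        g = ghost_by_key[play.key]
        vt = completion_mod.build_feature_vector(play).flatten()
        vg = completion_mod.build_feature_vector(g).flatten()
        tp.append(completion_mod.predict_proba(clf, vt)[0])
        gp.append(completion_mod.predict_proba(clf, vg)[0])
        if with_curves:
            curves_t.append(completion_curve(clf, play))
            curves_g.append(completion_curve(clf, g))

    def _mean_curve(curves: list[np.ndarray]) -> np.ndarray:
        T = max(len(c) for c in curves)
        acc = np.zeros(T)
        cnt = np.zeros(T)
        for c in curves:
            acc[:len(c)] += c
            cnt[:len(c)] += 1
        return acc / np.maximum(cnt, 1)

    return GhostComparison(
        true_probs=np.asarray(tp), ghost_probs=np.asarray(gp),
        pearson_r=pearson_r(np.asarray(tp), np.asarray(gp)),
        curve_true=_mean_curve(curves_t) if with_curves else None,
        curve_ghost=_mean_curve(curves_g) if with_curves else None,
    )


def evaluate_ghosting(model: GhostModel, plays: list[Play], clf=None) -> dict:
    """End-to-end report: per-role/per-timestep rollout errors over a play set,
    plus the completion-probability comparison when a classifier is given."""
    from .ghosting import build_play_tensor, rollout as _rollout

    profiles = []
    ghosts = []
    for p in plays:
        a = model.play_assignment(p)
        pt = build_play_tensor(p, a, model.offense_role_model)
        g = _rollout(model, p, a)
        profiles.append(rollout_mae(pt.defender_pos, g))
        ghosts.append(ghost_play(model, p, a))
    out: dict = {
        "overall_mae": float(np.mean([pr.overall_mae for pr in profiles])),
        "per_role_mae": np.mean([pr.per_role_mae for pr in profiles], axis=0),
        "n_plays": len(plays),
    }
    if clf is not None:
        cmp_ = compare_completion(plays, ghosts, clf)
        out["completion_pearson_r"] = cmp_.pearson_r
        out["mean_true_prob"] = float(cmp_.true_probs.mean())
        out["mean_ghost_prob"] = float(cmp_.ghost_probs.mean())
    return out
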