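"""Defensive ghosting: per-role recurrent policies trained by multi-agent imitation.

Seven policies — one per aligned defensive role — each consume the full per-frame
game state (all defender positions in role order, receivers and QB, ball, and game
metadata) and predict their own role's next-step displacement.  Training follows
three phases:

1. **pretraining** — teacher-forced least-squares one-step prediction, every input
   taken from the observed play;
2. **single-policy rollout with dataset aggregation (DAgger)** — one role at a time
   replaces its own input positions with its integrated predictions while all other
   entities stay observed; the states the learner actually visits, paired with the
   corrective expert displacement (from the predicted position toward the next
   observed one), are aggregated into its training set and the policy is refit;
3. **joint rollout** — all seven roles impute their own predictions simultaneously
   (offense and ball stay observed), aggregating and refitting jointly, which
   stabilizes full-team simulation.

On top of this sits the alternating ("cross-update") optimization: train policies
with roles fixed, then refit the hidden-Markov role model and re-assign roles
window by window with the policies fixed, repeating while validation rollout error
improves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from . import roles as roles_mod
from .policies import LSTMPolicy, PolicyConfig
from .tracking import Play, Track

N_ROLES = 7
_MAX_EXPERT_STEP = 1.1  # yards/frame, the 11 yd/s physical cap
#: 7 defenders + 5 receivers + QB + ball, 2 coords each, + 3 metadata scalars
STATE_DIM = (N_ROLES + 6 + 1) * 2 + 3

WINDOW_LEN = 25
WINDOW_STRIDE = 15


def window_bounds(n_frames: int, length: int = WINDOW_LEN,
                  stride: int = WINDOW_STRIDE) -> list[tuple[int, int]]:
    """Split ``n_frames`` into [start, stop) windows of ``length`` with the given
    stride (overlap = length − stride); the trailing remainder is kept as a
    shorter final window ending exactly at ``n_frames``."""
    if n_frames <= 0:
        return []
    bounds = []
    s = 0
    while True:
        if s + length >= n_frames:
            bounds.append((s, n_frames))
            break
        bounds.append((s, s + length))
        s += stride
    return bounds


@dataclass
class PlayTensor:
    """A play converted to model arrays under one role alignment.

    ``features``: (T, STATE_DIM) per-frame game state, defender slots in role
    order; ``defender_pos``: (T, 7, 2); ``role_entities``: entity id occupying
    each role slot.
    """

    play: Play
    features: np.ndarray
    defender_pos: np.ndarray
    role_entities: list[int]


@dataclass
class TrainingWindow:
    """One contiguous training sub-sequence (inputs + per-role targets)."""

    play_key: tuple[int, int]
    start: int
    stop: int
    inputs: np.ndarray    # (T-1, STATE_DIM)
    targets: np.ndarray   # (T-1, 7, 2) next-step displacement per role
    defender_pos: np.ndarray  # (T, 7, 2)


def _offense_order(play: Play, offense_model: roles_mod.StaticRoleModel | None):
    """Receiver entity ids in role order (QB handled separately)."""
    if offense_model is not None:
        a = roles_mod.assign_roles_static(offense_model, play, team="offense")
        return a.role_order
    snap_idx = play.frame_index(play.events["ball_snap"])
    return sorted(play.receiver_ids, key=lambda e: (play.tracks[e].x[snap_idx], e))


def build_play_tensor(play: Play, assignment: roles_mod.RoleAssignment,
                      offense_model: roles_mod.StaticRoleModel | None = None
                      ) -> PlayTensor:
    """Assemble the (T, STATE_DIM) state sequence for a normalized, clipped play.

    State order per frame: 7 defenders (role order), 5 receivers (role order),
    QB, ball — (x', y') each — then yards_to_go, down, absolute field position.
    """
    if not play.normalized:
        raise ValueError(f"play {play.key} must be normalized")
    T = play.n_frames
    role_entities = assignment.role_order
    def_pos = np.empty((T, N_ROLES, 2))
    for r, eid in enumerate(role_entities):
        t = play.tracks[eid]
        def_pos[:, r, 0] = t.x
        def_pos[:, r, 1] = t.y
    rec_ids = _offense_order(play, offense_model)
    off = np.empty((T, 6, 2))
    for i, eid in enumerate(rec_ids):
        off[:, i, 0] = play.tracks[eid].x
        off[:, i, 1] = play.tracks[eid].y
    qb = play.tracks[play.qb_id]
    off[:, 5, 0] = qb.x
    off[:, 5, 1] = qb.y
    ball = np.column_stack([play.ball.x, play.ball.y])
    meta = np.tile([play.meta.yards_to_go, float(play.meta.down),
                    play.meta.absolute_field_position], (T, 1))
    features = np.concatenate([
        def_pos.reshape(T, -1), off.reshape(T, -1), ball, meta], axis=1)
    return PlayTensor(play, features, def_pos, role_entities)


def make_training_windows(tensors: list[PlayTensor], length: int = WINDOW_LEN,
                          stride: int = WINDOW_STRIDE) -> list[TrainingWindow]:
    """Deterministic windowing of play tensors (length 25, stride 15 by default).

    Windows shorter than 2 frames carry no displacement target and are dropped.
    """
    windows = []
    for pt in tensors:
        for s, e in window_bounds(pt.features.shape[0], length, stride):
            if e - s < 2:
                continue
            windows.append(TrainingWindow(
                play_key=pt.play.key, start=s, stop=e,
                inputs=pt.features[s:e - 1].copy(),
                targets=np.diff(pt.defender_pos[s:e], axis=0),
                defender_pos=pt.defender_pos[s:e].copy(),
            ))
    return windows


def _slot(r: int) -> slice:
    return slice(2 * r, 2 * r + 2)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class GhostConfig:
    """Training configuration for the ghost model.

    Defaults use the full-size architecture (two LSTM layers of 128 units, Adam
    at 2e-3); small-scale studies shrink ``hidden_size`` and epoch counts —
    comparisons between training arms must keep these budgets equal.
    """

    hidden_size: int = 128
    n_layers: int = 2
    learning_rate: float = 2e-3
    batch_size: int = 64
    pretrain_epochs: int = 30
    dagger_iters: int = 5
    dagger_refit_epochs: int = 6
    joint_iters: int = 2
    joint_refit_epochs: int = 6
    window_len: int = WINDOW_LEN
    window_stride: int = WINDOW_STRIDE
    alternate_max_cycles: int = 3
    alternate_tol: float = 1e-3
    seed: int = 0


@dataclass
class GhostModel:
    """Seven per-role policies plus the role-alignment machinery."""

    config: GhostConfig
    policies: list[LSTMPolicy] = field(default_factory=list)
    static_role_model: roles_mod.StaticRoleModel | None = None
    offense_role_model: roles_mod.StaticRoleModel | None = None
    dynamic_role_model: roles_mod.DynamicRoleModel | None = None
    #: which alignment the current policies were trained under; evaluation must
    #: route defenders to policies with the same indexation
    assignment_mode: str = "static"
    manifest: dict = field(default_factory=dict)

    def play_assignment(self, play: Play) -> roles_mod.RoleAssignment:
        """Role assignment for one play under the model's current alignment."""
        if self.assignment_mode == "dynamic" and self.dynamic_role_model is not None:
            seq = frame_assignment_sequence(self, play)
            return roles_mod.RoleAssignment(
                play.key, {int(e): r for r, e in enumerate(seq[0])}, 0.0)
        return self.assign_static(play)

    def init_policies(self) -> None:
        cfg = self.config
        self.policies = [
            LSTMPolicy(PolicyConfig(input_dim=STATE_DIM, hidden_size=cfg.hidden_size,
                                    n_layers=cfg.n_layers,
                                    learning_rate=cfg.learning_rate,
                                    seed=cfg.seed * 100 + r))
            for r in range(N_ROLES)
        ]

    def fit_role_models(self, plays: list[Play], seed: int | None = None) -> None:
        seed = self.config.seed if seed is None else seed
        self.static_role_model = roles_mod.fit_static_role_model(
            plays, N_ROLES, seed=seed)
        self.offense_role_model = roles_mod.fit_static_role_model(
            plays, 5, seed=seed, team="offense")

    def assign_static(self, play: Play) -> roles_mod.RoleAssignment:
        return roles_mod.assign_roles_static(self.static_role_model, play)

    def tensors(self, plays: list[Play],
                assignments: dict | None = None) -> list[PlayTensor]:
        out = []
        for p in plays:
            a = (assignments or {}).get(p.key) or self.play_assignment(p)
            out.append(build_play_tensor(p, a, self.offense_role_model))
        return out


# ---------------------------------------------------------------------------
# phase 1: teacher-forced pretraining
# ---------------------------------------------------------------------------

def pretrain_policies(model: GhostModel, windows: list[TrainingWindow],
                      seed: int | None = None,
                      epochs: int | None = None) -> GhostModel:
    """Least-squares one-step pretraining with perfect (observed) inputs."""
    if not windows:
        raise ValueError("no training windows")
    if not model.policies:
        model.init_policies()
    seed = model.config.seed if seed is None else seed
    epochs = model.config.pretrain_epochs if epochs is None else epochs
    inputs = [w.inputs for w in windows]
    losses = {}
    for r, pol in enumerate(model.policies):
        targets = [w.targets[:, r, :] for w in windows]
        losses[r] = pol.fit_windows(inputs, targets, epochs=epochs,
                                    batch_size=model.config.batch_size,
                                    seed=seed + r)
    model.manifest.setdefault("phases", []).append(
        {"phase": "pretrain", "seed": seed, "n_windows": len(windows),
         "final_loss": {r: ls[-1] for r, ls in losses.items()},
         "loss_curves": {r: ls for r, ls in losses.items()}})
    return model


# ---------------------------------------------------------------------------
# phase 2/3: rollout + dataset aggregation
# ---------------------------------------------------------------------------

def _rollout_window(model: GhostModel, window: TrainingWindow,
                    roles_to_impute: list[int]):
    """Roll the selected roles through one window with their own predictions.

    Returns per-imputed-role (visited_inputs, expert_targets): the expert action
    at an off-distribution state is the displacement from the policy's current
    predicted position toward the next observed position, capped at the physical
    speed limit.
    """
    visited, experts = _rollout_windows_batch(model, [window], roles_to_impute)
    return ({r: v[0] for r, v in visited.items()},
            {r: e[0] for r, e in experts.items()})


def _rollout_windows_batch(model: GhostModel, windows: list[TrainingWindow],
                           roles_to_impute: list[int]):
    """Vectorized window rollout: all windows of equal length advance together.

    Returns per-role lists aligned with ``windows`` of (T, D) visited inputs and
    (T, 2) capped expert corrections.
    """
    visited: dict[int, list] = {r: [None] * len(windows) for r in roles_to_impute}
    experts: dict[int, list] = {r: [None] * len(windows) for r in roles_to_impute}
    by_len: dict[int, list[int]] = {}
    for i, w in enumerate(windows):
        by_len.setdefault(w.inputs.shape[0], []).append(i)
    for T, idxs in by_len.items():
        B = len(idxs)
        X = np.stack([windows[i].inputs for i in idxs])          # (B, T, D)
        DP = np.stack([windows[i].defender_pos for i in idxs])   # (B, T+1, 7, 2)
        states = {r: model.policies[r].init_state(B) for r in roles_to_impute}
        pos = {r: DP[:, 0, r, :].copy() for r in roles_to_impute}
        vis = {r: np.empty_like(X) for r in roles_to_impute}
        exp = {r: np.empty((B, T, 2)) for r in roles_to_impute}
        for t in range(T):
            x = X[:, t].copy()
            for r in roles_to_impute:
                x[:, _slot(r)] = pos[r]
            for r in roles_to_impute:
                vis[r][:, t] = x
                corr = DP[:, t + 1, r, :] - pos[r]
                norm = np.linalg.norm(corr, axis=1, keepdims=True)
                scale = np.minimum(1.0, _MAX_EXPERT_STEP / np.maximum(norm, 1e-12))
                exp[r][:, t] = corr * scale
                y, states[r] = model.policies[r].step(x, states[r])
                pos[r] = pos[r] + y
        for r in roles_to_impute:
            for bi, i in enumerate(idxs):
                visited[r][i] = vis[r][bi]
                experts[r][i] = exp[r][bi]
    return visited, experts


def _closed_loop_role_mae(model: GhostModel, windows: list[TrainingWindow],
                          role: int) -> float:
    """Mean closed-loop position error of one role rolled alone over windows."""
    visited, _ = _rollout_windows_batch(model, windows, [role])
    errs = []
    for v, w in zip(visited[role], windows):
        T = v.shape[0]
        err = np.linalg.norm(v[:, 2 * role:2 * role + 2]
                             - w.defender_pos[:T, role, :], axis=1)
        errs.append(err.mean())
    return float(np.mean(errs))


def dagger_train_single(model: GhostModel, role: int,
                        windows: list[TrainingWindow],
                        seed: int | None = None,
                        iters: int | None = None,
                        val_windows: list[TrainingWindow] | None = None
                        ) -> GhostModel:
    """DAgger for one role: roll it out with imperfect self-information (all other
    entities observed), aggregate the visited states with expert corrections, and
    refit on the growing aggregate.  The aggregate size never decreases; following
    the original algorithm, the iterate with the best validation closed-loop
    error is the one kept."""
    if not (0 <= role < N_ROLES):
        raise ValueError(f"role {role} out of range")
    seed = model.config.seed if seed is None else seed
    iters = model.config.dagger_iters if iters is None else iters
    val = val_windows if val_windows is not None else windows
    agg_inputs = [w.inputs for w in windows]
    agg_targets = [w.targets[:, role, :] for w in windows]
    sizes = [len(agg_inputs)]
    pol = model.policies[role]
    best_err = _closed_loop_role_mae(model, val, role)
    best_params = pol.clone()
    val_errs = [best_err]
    for it in range(iters):
        visited, experts = _rollout_windows_batch(model, windows, [role])
        agg_inputs.extend(visited[role])
        agg_targets.extend(experts[role])
        sizes.append(len(agg_inputs))
        pol.reset_optimizer()
        pol.fit_windows(agg_inputs, agg_targets,
                        epochs=model.config.dagger_refit_epochs,
                        batch_size=model.config.batch_size,
                        seed=seed + 17 * it + role)
        err = _closed_loop_role_mae(model, val, role)
        val_errs.append(err)
        if err < best_err:
            best_err = err
            best_params = pol.clone()
    model.policies[role] = best_params
    model.manifest.setdefault("phases", []).append(
        {"phase": "dagger_single", "role": role, "seed": seed,
         "aggregate_sizes": sizes, "val_errors": val_errs})
    return model


def joint_train(model: GhostModel, windows: list[TrainingWindow],
                seed: int | None = None, iters: int | None = None) -> GhostModel:
    """Joint rollout training: all seven roles impute their own predicted
    positions simultaneously (offense and ball stay observed); aggregation and
    refitting as in DAgger, applied to every policy."""
    seed = model.config.seed if seed is None else seed
    iters = model.config.joint_iters if iters is None else iters
    all_roles = list(range(N_ROLES))

    def _joint_mae() -> float:
        visited, _ = _rollout_windows_batch(model, windows, all_roles)
        errs = []
        for i, w in enumerate(windows):
            T = visited[0][i].shape[0]
            pos = np.stack([visited[r][i][:, 2 * r:2 * r + 2] for r in all_roles],
                           axis=1)
            errs.append(np.linalg.norm(pos - w.defender_pos[:T], axis=2).mean())
        return float(np.mean(errs))

    agg_inputs = {r: [w.inputs for w in windows] for r in all_roles}
    agg_targets = {r: [w.targets[:, r, :] for w in windows] for r in all_roles}
    best_err = _joint_mae()
    best_policies = [p.clone() for p in model.policies]
    val_errs = [best_err]
    for it in range(iters):
        visited, experts = _rollout_windows_batch(model, windows, all_roles)
        for r in all_roles:
            agg_inputs[r].extend(visited[r])
            agg_targets[r].extend(experts[r])
        for r in all_roles:
            model.policies[r].reset_optimizer()
            model.policies[r].fit_windows(
                agg_inputs[r], agg_targets[r],
                epochs=model.config.joint_refit_epochs,
                batch_size=model.config.batch_size, seed=seed + 31 * it + r)
        err = _joint_mae()
        val_errs.append(err)
        if err < best_err:
            best_err = err
            best_policies = [p.clone() for p in model.policies]
    model.policies = best_policies
    model.manifest.setdefault("phases", []).append(
        {"phase": "joint", "seed": seed, "val_errors": val_errs,
         "aggregate_size": len(agg_inputs[0])})
    return model


# ---------------------------------------------------------------------------
# rollout on full plays
# ---------------------------------------------------------------------------

def batch_rollout(model: GhostModel, tensors: list[PlayTensor],
                  roles_to_impute: list[int] | None = None) -> list[np.ndarray]:
    """Autoregressive rollout over full plays, vectorized over equal-length plays.

    The selected roles follow their policies from the observed snap positions;
    every other defender (and all offense/ball/meta inputs) stays observed.
    Returns per-play (T, 7, 2) trajectories in role order.
    """
    if not model.policies:
        raise ValueError("model has no trained policies")
    roles_to_impute = list(range(N_ROLES)) if roles_to_impute is None else roles_to_impute
    out: list[np.ndarray | None] = [None] * len(tensors)
    by_len: dict[int, list[int]] = {}
    for i, pt in enumerate(tensors):
        by_len.setdefault(pt.features.shape[0], []).append(i)
    for T, idxs in by_len.items():
        B = len(idxs)
        X = np.stack([tensors[i].features for i in idxs])       # (B, T, D)
        ghost = np.stack([tensors[i].defender_pos for i in idxs]).copy()
        states = {r: model.policies[r].init_state(B) for r in roles_to_impute}
        pos = {r: ghost[:, 0, r, :].copy() for r in roles_to_impute}
        for t in range(T - 1):
            x = X[:, t].copy()
            for r in roles_to_impute:
                x[:, _slot(r)] = pos[r]
            for r in roles_to_impute:
                y, states[r] = model.policies[r].step(x, states[r])
                pos[r] = pos[r] + y
                ghost[:, t + 1, r, :] = pos[r]
        for bi, i in enumerate(idxs):
            out[i] = ghost[bi]
    return out  # type: ignore[return-value]


def rollout(model: GhostModel, play: Play,
            assignment: roles_mod.RoleAssignment | None = None,
            roles_to_impute: list[int] | None = None) -> np.ndarray:
    """Autoregressive ghost trajectories for one normalized, clipped play.

    Starting from the observed defender positions at the snap, every imputed
    role's policy produces its displacement each 0.1 s until the pass_forward
    frame; offense, ball and metadata inputs stay observed.  By default all
    seven roles are imputed (full-team simulation); passing ``roles_to_impute``
    rolls out a subset with the rest observed (single-policy evaluation).
    Returns (T, 7, 2) positions on the play's time grid (role order).
    """
    a = assignment or model.assign_static(play)
    pt = build_play_tensor(play, a, model.offense_role_model)
    return batch_rollout(model, [pt], roles_to_impute)[0]


def ghost_play(model: GhostModel, play: Play,
               assignment: roles_mod.RoleAssignment | None = None) -> Play:
    """A copy of the play whose defender tracks are replaced by ghost rollouts
    (speed recomputed from ghost displacements; entity ids preserved)."""
    a = assignment or model.assign_static(play)
    g = rollout(model, play, a)
    new_tracks = dict(play.tracks)
    for r, eid in enumerate(a.role_order):
        old = play.tracks[eid]
        xy = g[:, r, :]
        disp = np.linalg.norm(np.diff(xy, axis=0, prepend=xy[:1]), axis=1)
        new_tracks[eid] = Track(eid, old.team, old.position,
                                xy[:, 0].copy(), xy[:, 1].copy(),
                                disp * 10.0, old.o.copy())
    return _dc_replace(play, tracks=new_tracks)


# ---------------------------------------------------------------------------
# alternating (cross-update) optimization
# ---------------------------------------------------------------------------

def _dynamic_assignments(model: GhostModel, plays: list[Play]) -> dict:
    return {p.key: roles_mod.assign_roles_dynamic(model.dynamic_role_model, p)
            for p in plays}


def role_conditional_moments(windows: list[TrainingWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Per-role mean and covariance of defender positions under the windows'
    current role alignment (the hard-assignment M-step of the cross-update)."""
    means = np.empty((N_ROLES, 2))
    covs = np.empty((N_ROLES, 2, 2))
    for r in range(N_ROLES):
        pts = np.vstack([w.defender_pos[:, r, :] for w in windows])
        means[r] = pts.mean(axis=0)
        covs[r] = np.cov(pts.T) + 1e-6 * np.eye(2)
    return means, covs


def frame_assignment_sequence(model: GhostModel, play: Play,
                              hysteresis: float = 5.0) -> np.ndarray:
    """(T, 7) array of entity ids occupying each role at every frame.

    Each defender's forward–backward state posteriors under the dynamic role
    model are computed over its whole trajectory (temporal smoothing), then a
    Hungarian bijection on the negative log posterior is solved per frame.  The
    previous frame's bijection is kept unless the optimum beats it by more than
    ``hysteresis`` nats — near-tied alternatives would otherwise make the
    alignment oscillate frame to frame, while a genuine role hand-off (posterior
    mass shifting to another state) clears the margin within a few frames.
    """
    if model.dynamic_role_model is None:
        raise ValueError("fit the dynamic role model first")
    ids = play.defender_ids
    T = play.n_frames
    gammas = np.empty((len(ids), T, N_ROLES))
    for i, eid in enumerate(ids):
        t = play.tracks[eid]
        gammas[i] = roles_mod.state_posteriors(
            model.dynamic_role_model, np.column_stack([t.x, t.y]))
    logg = np.log(np.maximum(gammas, 1e-12))
    out = np.empty((T, N_ROLES), dtype=int)
    # seed the sequence with the snap-position (static) assignment — reliable at
    # the snap — and let the HMM hand roles off as the play develops; this
    # relies on seeded dynamic models keeping the static role indexation
    if model.static_role_model is not None:
        static_map = roles_mod.assign_roles_static(model.static_role_model, play)
        prev_cols = np.array([static_map.mapping[eid] for eid in ids])
    else:
        prev_cols = None
    idx = np.arange(N_ROLES)
    for t in range(T):
        C = -logg[:, t, :]
        cols, opt = roles_mod.hungarian_assign(C)
        if prev_cols is not None and C[idx, prev_cols].sum() - opt < hysteresis:
            cols = prev_cols
        prev_cols = cols
        inv = np.empty(N_ROLES, dtype=int)
        inv[cols] = np.arange(N_ROLES)
        out[t] = [ids[inv[r]] for r in range(N_ROLES)]
    return out


def make_dynamic_windows(model: GhostModel, plays: list[Play]) -> list[TrainingWindow]:
    """Training windows under HMM role alignment, split at role hand-offs.

    The per-frame bijection is computed once per play; every standard window is
    then cut at the frames where the bijection changes, and each piece is built
    under its own constant role assignment.  A play whose defenders exchange
    tasks mid-play therefore contributes coherent (no identity teleports)
    windows on both sides of the switch — the point of the coordinated
    (cross-update) variant.  Pieces shorter than 2 frames are dropped.
    """
    cfg = model.config
    windows: list[TrainingWindow] = []
    for p in plays:
        seq = frame_assignment_sequence(model, p)
        changes = [t for t in range(1, len(seq))
                   if not np.array_equal(seq[t], seq[t - 1])]
        # one full-play tensor per distinct bijection segment
        seg_starts = [0] + changes
        tensors_by_start = {}
        for s0 in seg_starts:
            a = roles_mod.RoleAssignment(
                p.key, {int(e): r for r, e in enumerate(seq[s0])}, 0.0)
            tensors_by_start[s0] = build_play_tensor(p, a, model.offense_role_model)
        for s, e in window_bounds(p.n_frames, cfg.window_len, cfg.window_stride):
            cuts = [s] + [c for c in changes if s < c < e] + [e]
            for a0, b0 in zip(cuts[:-1], cuts[1:]):
                if b0 - a0 < 2:
                    continue
                seg = max(x for x in seg_starts if x <= a0)
                pt = tensors_by_start[seg]
                windows.append(TrainingWindow(
                    p.key, a0, b0, pt.features[a0:b0 - 1].copy(),
                    np.diff(pt.defender_pos[a0:b0], axis=0),
                    pt.defender_pos[a0:b0].copy()))
    return windows


def validation_rollout_mae(model: GhostModel, plays: list[Play],
                           assignments: dict | None = None) -> float:
    """Mean Euclidean rollout error (yards) over defenders, frames and plays."""
    tensors = model.tensors(plays, assignments)
    ghosts = batch_rollout(model, tensors)
    return float(np.mean([np.linalg.norm(g - pt.defender_pos, axis=2).mean()
                          for g, pt in zip(ghosts, tensors)]))


def joint_rollout_error_profiles(model: GhostModel, plays: list[Play],
                                 assignments: dict | None = None) -> np.ndarray:
    """Per-role error curves, (7, T_max) yards, from the full-team joint rollout
    (all seven policies imputing their own positions)."""
    tensors = model.tensors(plays, assignments)
    T_max = max(pt.features.shape[0] for pt in tensors)
    acc = np.zeros((N_ROLES, T_max))
    cnt = np.zeros((N_ROLES, T_max))
    ghosts = batch_rollout(model, tensors)
    for g, pt in zip(ghosts, tensors):
        err = np.linalg.norm(g - pt.defender_pos, axis=2)  # (T, 7)
        acc[:, :err.shape[0]] += err.T
        cnt[:, :err.shape[0]] += 1
    return acc / np.maximum(cnt, 1)


def single_role_error_profiles(model: GhostModel, plays: list[Play],
                               assignments: dict | None = None) -> np.ndarray:
    """Per-role single-policy rollout error curves, (7, T_max) yards.

    Each role is rolled out alone (all other defenders observed), mirroring the
    per-role model-error view; plays shorter than T_max contribute to the frames
    they cover.
    """
    tensors = model.tensors(plays, assignments)
    T_max = max(pt.features.shape[0] for pt in tensors)
    acc = np.zeros((N_ROLES, T_max))
    cnt = np.zeros((N_ROLES, T_max))
    for r in range(N_ROLES):
        ghosts = batch_rollout(model, tensors, roles_to_impute=[r])
        for g, pt in zip(ghosts, tensors):
            err = np.linalg.norm(g[:, r] - pt.defender_pos[:, r], axis=1)
            acc[r, :len(err)] += err
            cnt[r, :len(err)] += 1
    return acc / np.maximum(cnt, 1)


def train_policies_on_windows(model: GhostModel, windows: list[TrainingWindow],
                              seed: int, use_dagger: bool = True) -> GhostModel:
    """One policy-optimization pass (pretrain, then optionally per-role DAgger)
    on a fixed set of role-assigned windows."""
    model.init_policies()
    pretrain_policies(model, windows, seed=seed)
    if use_dagger:
        for r in range(N_ROLES):
            dagger_train_single(model, r, windows, seed=seed + r)
    return model


def alternate_optimize(model: GhostModel, train_plays: list[Play],
                       val_plays: list[Play], seed: int | None = None,
                       use_dagger: bool = True) -> GhostModel:
    """Cross-update loop: train policies with roles fixed, then refit the HMM and
    re-assign roles per window with policies fixed; stop when validation rollout
    MAE fails to improve by more than the tolerance over a full cycle.  Returns
    the model state with the best validation MAE seen."""
    cfg = model.config
    seed = cfg.seed if seed is None else seed
    if model.static_role_model is None:
        model.fit_role_models(train_plays, seed)

    model.assignment_mode = "static"
    windows = make_training_windows(model.tensors(train_plays),
                                    cfg.window_len, cfg.window_stride)
    best_mae = np.inf
    best_state = None  # (policies, mode, dynamic role model) as one unit
    history = []
    for cycle in range(cfg.alternate_max_cycles):
        train_policies_on_windows(model, windows, seed=seed + 1000 * cycle,
                                  use_dagger=use_dagger)
        mae = validation_rollout_mae(model, val_plays)
        history.append(mae)
        if mae < best_mae - cfg.alternate_tol:
            best_mae = mae
            best_state = ([p.clone() for p in model.policies],
                          model.assignment_mode, model.dynamic_role_model)
        elif cycle > 0:
            break  # no improvement over a full cycle
        if cycle < cfg.alternate_max_cycles - 1:
            # role-model refit with policies fixed (cross-update): emission
            # states seeded from role-conditional moments under the current
            # alignment, then refined by one Baum–Welch pass
            mu, sig = role_conditional_moments(windows)
            model.dynamic_role_model = roles_mod.fit_dynamic_role_model(
                train_plays, N_ROLES, seed=seed + cycle, max_iter=1,
                init_means=mu, init_covs=sig)
            model.assignment_mode = "dynamic"
            windows = make_dynamic_windows(model, train_plays)
    if best_state is not None:
        model.policies, model.assignment_mode, model.dynamic_role_model = (
            best_state[0], best_state[1], best_state[2])
    model.manifest["alternate_history"] = history
    model.manifest["alternate_best_mae"] = float(best_mae)
    return model
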