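"""Synthetic play generator in the Big Data Bowl tracking dialect.

Generates pass plays with 7 defenders, 6 offensive players (QB + 5 receivers) and a
ball at 10 Hz: route-running receivers, a scripted reactive defense (first-order
pursuit), snap→pass windows of roughly 2–8 s with a mean of about 3.6 s, and a known
logistic ground truth for the pass-completion probability.  The scripted defense is
deliberately simple — each defender moves a fixed fraction of the way toward its
current target every frame — so that the expert behavior is learnable by a small
recurrent policy and every closed-form property (geometric gap decay, collocation at
gain 1) is checkable exactly at zero noise.

All geometry is produced in the normalized frame (scrimmage line at y' = 0, offense
advancing toward negative y') and converted to raw field coordinates for the CSV
dialect, so generated plays exercise the full read → filter → normalize pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .tracking import (
    BALL_ID, FIELD_LENGTH, FIELD_WIDTH, Play, PlayCollection, PlayMeta, Track,
    _inverse_transform, write_tracking,
)

MAX_SPEED_YDS = 11.0          # physical cap on any per-second displacement
_MAX_STEP = MAX_SPEED_YDS / 10.0

ROUTE_NAMES = ("go", "hitch", "crossing", "flat")


@dataclass
class RouteTemplate:
    """A named receiver route: waypoints relative to the receiver's start.

    Offsets are in normalized coordinates (negative y' = downfield); ``speed`` is
    the target running speed in yards/s, capped at 11.
    """

    name: str
    offsets: list[tuple[float, float]]
    speed: float = 7.0

    def waypoints(self, start: np.ndarray, toward_center: float) -> np.ndarray:
        """Absolute waypoints; lateral offsets are signed toward the field center."""
        pts = []
        for dx, dy in self.offsets:
            pts.append([start[0] + dx * toward_center, start[1] + dy])
        pts = np.asarray(pts)
        pts[:, 0] = np.clip(pts[:, 0], 1.0, FIELD_WIDTH - 1.0)
        return pts


def route_library() -> dict[str, RouteTemplate]:
    return {
        "go": RouteTemplate("go", [(0.0, -28.0)], speed=8.5),
        "hitch": RouteTemplate("hitch", [(0.0, -8.0), (0.0, -7.0)], speed=7.0),
        "crossing": RouteTemplate("crossing", [(16.0, -9.0)], speed=7.5),
        "flat": RouteTemplate("flat", [(9.0, -2.0)], speed=6.5),
    }


@dataclass
class CoverageScript:
    """Scripted defensive behavior for one play.

    ``man``: defenders 0–4 pursue their assigned receivers with gain ``g`` (the
    fraction of the current gap closed per frame), defender 5 rushes the QB and
    defender 6 plays a deep safety shadowing the deepest receiver.  ``zone``:
    each defender holds an anchor and engages the nearest receiver within its
    radius.  ``sigma`` is i.i.d. Gaussian reaction noise in yards/frame.
    """

    type: str = "man"                      # man | zone
    assignment: dict[int, int] = field(default_factory=dict)  # defender -> receiver
    gain: float = 0.3
    sigma: float = 0.2
    rusher_gain: float = 0.12
    safety_gain: float = 0.12
    anchors: np.ndarray | None = None      # zone: (7, 2)
    radius: float = 8.0

    def __post_init__(self):
        if not (0.0 < self.gain <= 1.0):
            raise ValueError("pursuit gain must lie in (0, 1]")
        if self.sigma < 0:
            raise ValueError("reaction noise sigma must be >= 0")


@dataclass
class GroundTruthCompletion:
    """Known logistic completion model over interpretable formation geometry.

    Features (yards, computed at the pass_forward frame in the normalized frame):
    openness of the most-open receiver (distance to its nearest defender), QB
    pressure (distance from QB to the nearest defender) and depth of the most-open
    receiver beyond the scrimmage line.  The probability is the standard logistic
    sigmoid of their weighted sum.
    """

    w_openness: float = 2.5
    w_pressure: float = 0.6
    w_depth: float = -0.12
    openness_ref: float = 2.0
    pressure_ref: float = 1.0
    depth_ref: float = 14.0
    bias: float = 1.6

    def features(self, receivers: np.ndarray, defenders: np.ndarray,
                 qb: np.ndarray) -> tuple[float, float, float]:
        d2 = np.linalg.norm(receivers[:, None, :] - defenders[None, :, :], axis=2)
        nearest = d2.min(axis=1)
        best = int(np.argmax(nearest))
        openness = float(nearest[best])
        pressure = float(np.linalg.norm(defenders - qb, axis=1).min())
        depth = float(max(0.0, -receivers[best, 1]))
        return openness, pressure, depth

    def probability(self, receivers: np.ndarray, defenders: np.ndarray,
                    qb: np.ndarray) -> float:
        openness, pressure, depth = self.features(receivers, defenders, qb)
        logit = (self.w_openness * (openness - self.openness_ref)
                 + self.w_pressure * (pressure - self.pressure_ref)
                 + self.w_depth * (depth - self.depth_ref)
                 + self.bias)
        return float(expit(logit))


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    Snap→pass durations are 2 s plus a truncated-exponential tail chosen so the
    mean duration is ≈3.6 s; pursuit gains are resampled per play over
    ``gain_range`` so formations separate by different amounts, which is what
    gives the completion ground truth its dynamic range.
    """

    coverage: str = "man"
    sigma: float = 0.2
    gain_range: tuple[float, float] = (0.15, 0.5)
    duration_range_s: tuple[float, float] = (2.0, 8.0)
    duration_tail_scale_s: float = 1.8
    fixed_duration_s: float | None = None
    n_pre_snap: int = 5
    n_post_pass: int = 3
    routes: tuple[str, ...] | None = None      # None -> sampled per receiver
    route_speed_scale: float = 1.0             # 0 freezes receivers (scripted tests)
    truth: GroundTruthCompletion = field(default_factory=GroundTruthCompletion)

    def __post_init__(self):
        if self.coverage not in ("man", "zone"):
            raise ValueError(f"unknown coverage type {self.coverage!r}")
        if not (self.gain_range[0] > 0 and self.gain_range[1] <= 1.0):
            raise ValueError("gain_range must lie within (0, 1]")


@dataclass
class PlayScript:
    """Everything needed to re-simulate one play deterministically."""

    seed: int
    config: SynthConfig
    coverage: CoverageScript
    n_window: int
    receiver_starts: np.ndarray        # (5, 2) normalized
    receiver_waypoints: list[np.ndarray]
    receiver_speeds: np.ndarray
    defender_starts: np.ndarray        # (7, 2)
    qb_start: np.ndarray
    play_direction: str
    los_x: float
    down: int
    yards_to_go: float
    week: int
    game_id: int
    play_id: int
    switch: tuple[int, int, int] | None = None   # (defender_a, defender_b, frame offset)
    role_sequence: np.ndarray | None = None      # (T, 7) ground-truth role per frame


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sample_duration_frames(cfg: SynthConfig, rng: np.random.Generator) -> int:
    if cfg.fixed_duration_s is not None:
        return int(round(cfg.fixed_duration_s * 10))
    lo, hi = cfg.duration_range_s
    span = hi - lo
    scale = cfg.duration_tail_scale_s
    # exact truncated exponential on [0, span] via inverse CDF
    u = rng.random()
    tail = -scale * np.log1p(-u * (1.0 - np.exp(-span / scale)))
    return int(round((lo + tail) * 10))


def sample_play_script(config: SynthConfig, seed: int) -> PlayScript:
    rng = np.random.default_rng(seed)
    n_window = _sample_duration_frames(config, rng)

    center = FIELD_WIDTH / 2.0
    # five canonical receiver alignments (wide-left .. wide-right) with jitter,
    # as in real formations; keeps snap positions clusterable into stable roles
    slots = np.array([6.0, 16.0, center, FIELD_WIDTH - 16.0, FIELD_WIDTH - 6.0])
    rx = np.sort(np.clip(slots + rng.normal(0.0, 1.5, size=5),
                         2.0, FIELD_WIDTH - 2.0))
    receiver_starts = np.column_stack([rx, rng.uniform(0.5, 1.5, size=5)])
    qb_start = np.array([center + rng.uniform(-2, 2), 5.0 + rng.uniform(-0.5, 1.0)])

    lib = route_library()
    names = (config.routes if config.routes is not None
             else rng.choice(ROUTE_NAMES, size=5))
    waypoints, speeds = [], []
    for i, name in enumerate(names):
        tpl = lib[str(name)]
        toward = 1.0 if receiver_starts[i, 0] < center else -1.0
        waypoints.append(tpl.waypoints(receiver_starts[i], toward))
        speeds.append(tpl.speed * config.route_speed_scale
                      * rng.uniform(0.9, 1.1))
    gain = float(rng.uniform(*config.gain_range))
    if config.coverage == "man":
        coverage = CoverageScript(
            type="man", assignment={j: j for j in range(5)},
            gain=gain, sigma=config.sigma,
            rusher_gain=0.4 * gain, safety_gain=0.4 * gain)
        # man defenders 5 yd off their receivers, an edge rusher on the line to
        # the QB's right, and a deep middle safety: separable snap clusters
        defender_starts = np.column_stack([
            np.concatenate([receiver_starts[:, 0] + rng.uniform(-0.8, 0.8, 5),
                            [qb_start[0] + rng.uniform(3.0, 5.0),
                             center + rng.uniform(-2, 2)]]),
            np.concatenate([rng.uniform(-5.5, -4.0, 5),
                            [rng.uniform(-1.5, -0.8), rng.uniform(-13.0, -11.0)]]),
        ])
    else:
        anchors = np.column_stack([
            np.linspace(6, FIELD_WIDTH - 6, 7),
            np.array([-4, -7, -4, -10, -4, -7, -4.0]),
        ])
        coverage = CoverageScript(type="zone", gain=gain, sigma=config.sigma,
                                  anchors=anchors)
        defender_starts = anchors + rng.normal(0, 1.0, size=(7, 2))

    direction = "right" if rng.random() < 0.5 else "left"
    los_x = float(rng.uniform(35.0, 80.0))
    down = int(rng.choice([1, 2, 3, 4], p=[0.45, 0.30, 0.20, 0.05]))
    yards_to_go = 10.0 if down == 1 else float(rng.integers(1, 16))
    week = int(rng.integers(1, 18))
    return PlayScript(
        seed=seed, config=config, coverage=coverage, n_window=n_window,
        receiver_starts=receiver_starts, receiver_waypoints=waypoints,
        receiver_speeds=np.asarray(speeds), defender_starts=defender_starts,
        qb_start=qb_start, play_direction=direction, los_x=los_x,
        down=down, yards_to_go=yards_to_go, week=week,
        game_id=2019090000 + seed // 1000, play_id=seed % 1000 + 1,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def pursuit_step(pos: np.ndarray, target: np.ndarray, gain: float,
                 noise: np.ndarray | float = 0.0,
                 max_step: float = _MAX_STEP) -> np.ndarray:
    """One first-order pursuit update: close ``gain`` of the gap, capped at max speed."""
    step = gain * (target - pos) + noise
    norm = np.linalg.norm(step)
    if norm > max_step:
        step = step * (max_step / norm)
    return pos + step


def _receiver_positions(script: PlayScript, n_steps: int) -> np.ndarray:
    """(n_steps+1, 5, 2) receiver trajectory from snap, waypoint-following."""
    pos = script.receiver_starts.copy()
    way_idx = np.zeros(5, dtype=int)
    out = [pos.copy()]
    for _ in range(n_steps):
        for i in range(5):
            wps = script.receiver_waypoints[i]
            k = min(way_idx[i], len(wps) - 1)
            target = wps[k]
            delta = target - pos[i]
            dist = np.linalg.norm(delta)
            step = min(script.receiver_speeds[i] / 10.0, _MAX_STEP)
            if dist <= step:
                pos[i] = target.copy()
                if way_idx[i] < len(wps) - 1:
                    way_idx[i] += 1
            elif dist > 0:
                pos[i] = pos[i] + delta / dist * step
        out.append(pos.copy())
    return np.asarray(out)


def simulate_script(script: PlayScript) -> dict[str, np.ndarray]:
    """Run the scripted play; returns normalized-frame trajectories over the full
    pre-snap + window + post-pass grid, plus the ground-truth role sequence."""
    cfg = script.config
    cov = script.coverage
    rng = np.random.default_rng(script.seed + 987654321)
    n_win = script.n_window                       # snap..pass has n_win+1 frames
    receivers = _receiver_positions(script, n_win + cfg.n_post_pass)

    qb = [script.qb_start.copy()]
    for t in range(n_win + cfg.n_post_pass):
        nxt = qb[-1] + np.array([rng.normal(0, 0.05), 0.06 if qb[-1][1] < 7.5 else 0.0])
        qb.append(nxt)
    qb = np.asarray(qb)

    assignment = dict(cov.assignment)

    def _current_roles() -> np.ndarray:
        roles = np.arange(7)
        for j, r in assignment.items():
            roles[j] = r
        return roles

    if script.switch is not None and script.switch[2] == 0:
        a, b, _ = script.switch
        if a in assignment and b in assignment:
            assignment[a], assignment[b] = assignment[b], assignment[a]
    defenders = [script.defender_starts.copy()]
    role_seq = [_current_roles()]
    for t in range(n_win + cfg.n_post_pass):
        if script.switch is not None and t == script.switch[2] and t > 0:
            a, b, _ = script.switch
            if a in assignment and b in assignment:
                assignment[a], assignment[b] = assignment[b], assignment[a]
        cur = defenders[-1]
        nxt = cur.copy()
        noise = rng.normal(0.0, cov.sigma, size=(7, 2))
        if cov.type == "man":
            for j in range(5):
                target = receivers[t, assignment[j]]
                nxt[j] = pursuit_step(cur[j], target, cov.gain, noise[j])
            nxt[5] = pursuit_step(cur[5], qb[t], cov.rusher_gain, noise[5])
            # deep safety shadows the receiver centroid from behind (smooth target)
            shadow = receivers[t].mean(axis=0) + np.array([0.0, -6.0])
            nxt[6] = pursuit_step(cur[6], shadow, cov.safety_gain, noise[6])
        else:
            for j in range(7):
                d = np.linalg.norm(receivers[t] - cur[j], axis=1)
                k = int(np.argmin(d))
                target = receivers[t, k] if d[k] <= cov.radius else cov.anchors[j]
                nxt[j] = pursuit_step(cur[j], target, cov.gain, noise[j])
        defenders.append(nxt)
        role_seq.append(_current_roles())
    defenders = np.asarray(defenders)
    script.role_sequence = np.asarray(role_seq)[: n_win + 1]

    # ball: held by QB until the pass, then flies toward the most-open receiver
    ball = qb.copy()
    truth = cfg.truth
    rec_pass, def_pass, qb_pass = receivers[n_win], defenders[n_win], qb[n_win]
    d2 = np.linalg.norm(rec_pass[:, None, :] - def_pass[None, :, :], axis=2)
    target_rec = int(np.argmax(d2.min(axis=1)))
    for k in range(1, cfg.n_post_pass + 1):
        frac = k / max(cfg.n_post_pass, 1)
        ball[n_win + k] = qb_pass + frac * (receivers[n_win + k, target_rec] - qb_pass)

    return {
        "receivers": receivers, "qb": qb, "defenders": defenders, "ball": ball,
        "truth_probability": truth.probability(rec_pass, def_pass, qb_pass),
    }


# ---------------------------------------------------------------------------
# play assembly in the CSV dialect's raw frame
# ---------------------------------------------------------------------------

_DEF_POSITIONS = ["CB", "CB", "CB", "LB", "LB", "DE", "FS"]

RECEIVER_ID_BASE = 100
DEFENDER_ID_BASE = 200
QB_ENTITY_ID = 199


def _heading_degrees(xy: np.ndarray) -> np.ndarray:
    d = np.diff(xy, axis=0, prepend=xy[:1])
    ang = (np.degrees(np.arctan2(d[:, 0], -d[:, 1]))) % 360.0
    return ang


def script_to_play(script: PlayScript, sim: dict, outcome: str | None) -> Play:
    """Assemble a raw-frame :class:`Play` (dialect coordinates) from a simulation."""
    cfg = script.config
    n_pre, n_post = cfg.n_pre_snap, cfg.n_post_pass
    n_win = script.n_window
    n_total = n_pre + n_win + 1 + n_post
    frame_ids = np.arange(1, n_total + 1)
    snap_frame = n_pre + 1
    pass_frame = n_pre + 1 + n_win

    def full_track(sim_xy: np.ndarray) -> np.ndarray:
        pre = np.repeat(sim_xy[:1], n_pre, axis=0)
        return np.vstack([pre, sim_xy])

    entities: dict[int, tuple[str, str, np.ndarray]] = {}
    for i in range(5):
        entities[RECEIVER_ID_BASE + i] = ("offense", "WR", full_track(sim["receivers"][:, i]))
    entities[QB_ENTITY_ID] = ("offense", "QB", full_track(sim["qb"]))
    for j in range(7):
        entities[DEFENDER_ID_BASE + j] = ("defense", _DEF_POSITIONS[j],
                                          full_track(sim["defenders"][:, j]))
    entities[BALL_ID] = ("ball", "", full_track(sim["ball"]))

    tracks: dict[int, Track] = {}
    for eid, (team, pos_label, xy_norm) in entities.items():
        x, y = _inverse_transform(script.play_direction, script.los_x,
                                  xy_norm[:, 0], xy_norm[:, 1])
        disp = np.linalg.norm(np.diff(xy_norm, axis=0, prepend=xy_norm[:1]), axis=1)
        s = disp * 10.0
        o = _heading_degrees(xy_norm)
        tracks[eid] = Track(eid, team, pos_label, x, y, s, o)

    los = script.los_x
    afp = (FIELD_LENGTH - 10.0 - los) if script.play_direction == "right" else (los - 10.0)
    meta = PlayMeta(
        down=script.down, yards_to_go=script.yards_to_go,
        line_of_scrimmage_x=los, absolute_field_position=afp,
        play_direction=script.play_direction,  # type: ignore[arg-type]
        pass_outcome=outcome, week=script.week,
    )
    events = {"ball_snap": int(snap_frame), "pass_forward": int(pass_frame)}
    if outcome is not None:
        events["pass_outcome_caught" if outcome == "complete"
               else "pass_outcome_incomplete"] = int(frame_ids[-1])
    return Play(script.play_id, script.game_id, frame_ids, tracks, meta, events,
                normalized=False, script=script)


def generate_play(config: SynthConfig, seed: int) -> tuple[Play, float]:
    """Generate one play; returns (raw-frame play, ground-truth completion prob).

    The pass outcome stored in the play metadata is drawn Bernoulli from the
    ground-truth probability with a seed-derived stream, so the same seed yields
    a byte-identical play.
    """
    script = sample_play_script(config, seed)
    sim = simulate_script(script)
    p = sim["truth_probability"]
    label_rng = np.random.default_rng(seed + 555000111)
    outcome = "complete" if label_rng.random() < p else "incomplete"
    play = script_to_play(script, sim, outcome)
    return play, p


def generate_dataset(n_plays: int, config: SynthConfig | None = None,
                     seed: int = 0) -> tuple[PlayCollection, np.ndarray, np.ndarray]:
    """Generate ``n_plays`` plays.

    Returns ``(collection, labels, truth_probabilities)`` where labels are the
    realized Bernoulli outcomes (1 = complete) and truth probabilities are the
    generator's per-play completion probabilities (for calibration tests).
    """
    if n_plays < 1:
        raise ValueError("n_plays must be >= 1")
    config = config or SynthConfig()
    plays, labels, probs = [], [], []
    for k in range(n_plays):
        play, p = generate_play(config, seed * 1_000_003 % (2**31) + k)
        plays.append(play)
        labels.append(1 if play.meta.pass_outcome == "complete" else 0)
        probs.append(p)
    return PlayCollection(plays=plays), np.asarray(labels), np.asarray(probs)


def inject_role_switch(play: Play, t_switch: int,
                       pair: tuple[int, int] = (0, 1)) -> Play:
    """Re-simulate a generated play with two man defenders exchanging assignments
    at frame offset ``t_switch`` (frames after the snap).

    The ground-truth role sequence is recorded on the returned play's script.
    ``t_switch = 0`` switches at the snap (equivalent to a relabeled assignment).
    """
    if play.script is None:
        raise ValueError("inject_role_switch requires a generator-produced play")
    script: PlayScript = play.script
    if not (0 <= t_switch <= script.n_window):
        raise ValueError(f"t_switch {t_switch} outside the snap→pass window "
                         f"[0, {script.n_window}]")
    new_script = dataclasses.replace(script, switch=(pair[0], pair[1], int(t_switch)))
    sim = simulate_script(new_script)
    return script_to_play(new_script, sim, play.meta.pass_outcome)


def write_dataset(collection: PlayCollection, truth_probs: np.ndarray,
                  out_dir: str | Path) -> None:
    """Write the dialect CSVs plus a ``truth.json`` with role sequences and
    ground-truth completion probabilities."""
    import json

    out_dir = Path(out_dir)
    write_tracking(collection, out_dir)
    truth = {}
    for play, p in zip(collection, truth_probs):
        entry = {"truth_probability": float(p)}
        if play.script is not None and play.script.role_sequence is not None:
            entry["role_sequence"] = play.script.role_sequence.tolist()
        truth[f"{play.game_id}_{play.play_id}"] = entry
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
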