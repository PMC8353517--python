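"""Reading, validation, filtering, normalization and windowing of football tracking data.

The supported dialect is the NFL Big Data Bowl 2021 CSV layout: one tracking row per
entity and frame with columns ``x, y, s, o, event, nflId, frameId, playId, gameId,
team, position, playDirection`` sampled at 10 Hz, plus a ``plays.csv`` with per-play
metadata (down, distance, line of scrimmage, possession team, pass result).

Coordinates are in yards: ``0 <= x <= 120`` along the field (including both 10-yard
end zones) and ``0 <= y <= 53.3`` across it.  All modelling downstream happens in a
normalized frame in which the line of scrimmage is the x'-axis (``y' = 0``), the
offense's backfield is at positive y' and the offense advances toward negative y'.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

FIELD_LENGTH = 120.0
FIELD_WIDTH = 53.3
FRAME_RATE_HZ = 10.0
BALL_ID = 0

#: canonical roster sizes after filtering
N_DEFENDERS = 7
N_OFFENSE = 6  # QB + 5 receivers

TRACKING_COLUMNS = [
    "x", "y", "s", "o", "event", "nflId", "frameId",
    "playId", "gameId", "team", "position", "playDirection",
]


@dataclass
class PlayMeta:
    """Game-state metadata for one play.

    ``line_of_scrimmage_x`` is in raw field coordinates (yards from the back of the
    left end zone); ``absolute_field_position`` is the distance in yards from the
    line of scrimmage to the goal line the offense is attacking.
    """

    down: int
    yards_to_go: float
    line_of_scrimmage_x: float
    absolute_field_position: float
    play_direction: Literal["left", "right"]
    pass_outcome: str | None  # complete | incomplete | intercepted | None
    week: int = 1
    is_sack: bool = False
    has_handoff: bool = False


@dataclass
class Track:
    """Per-entity synchronized coordinate/speed/orientation sequences."""

    entity_id: int
    team: Literal["defense", "offense", "ball"]
    position: str  # listed position label (QB, WR, CB, ...), "" for the ball
    x: np.ndarray
    y: np.ndarray
    s: np.ndarray
    o: np.ndarray

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class Play:
    """A single play: time-aligned entity tracks, events and metadata.

    ``frame_ids`` is the shared time grid (10 Hz frame numbers); ``events`` maps
    event names (``ball_snap``, ``pass_forward``, ...) to frame ids on that grid.
    Entities missing from a frame carry NaN in their track (a gap).
    """

    play_id: int
    game_id: int
    frame_ids: np.ndarray
    tracks: dict[int, Track]
    meta: PlayMeta
    events: dict[str, int]
    normalized: bool = False
    script: object | None = None  # synthetic provenance (coverage script), if any

    # --- roster helpers -------------------------------------------------
    @property
    def key(self) -> tuple[int, int]:
        return (self.game_id, self.play_id)

    @property
    def week(self) -> int:
        return self.meta.week

    def entity_ids(self, team: str) -> list[int]:
        return sorted(t.entity_id for t in self.tracks.values() if t.team == team)

    @property
    def defender_ids(self) -> list[int]:
        return self.entity_ids("defense")

    @property
    def offense_ids(self) -> list[int]:
        return self.entity_ids("offense")

    @property
    def qb_id(self) -> int:
        qbs = [t.entity_id for t in self.tracks.values()
               if t.team == "offense" and t.position == "QB"]
        if len(qbs) != 1:
            raise ValueError(f"play {self.key}: expected exactly one QB, got {len(qbs)}")
        return qbs[0]

    @property
    def receiver_ids(self) -> list[int]:
        return [i for i in self.offense_ids if i != self.qb_id]

    @property
    def ball(self) -> Track:
        return self.tracks[BALL_ID]

    def frame_index(self, frame_id: int) -> int:
        idx = np.searchsorted(self.frame_ids, frame_id)
        if idx >= len(self.frame_ids) or self.frame_ids[idx] != frame_id:
            raise KeyError(f"frame {frame_id} not on play {self.key} time grid")
        return int(idx)

    def positions_at(self, frame_id: int, entity_ids: Iterable[int]) -> np.ndarray:
        """(n, 2) array of entity positions at one frame."""
        i = self.frame_index(frame_id)
        return np.array([[self.tracks[e].x[i], self.tracks[e].y[i]] for e in entity_ids])

    @property
    def n_frames(self) -> int:
        return len(self.frame_ids)

    def duration_s(self) -> float:
        return (self.frame_ids[-1] - self.frame_ids[0]) / FRAME_RATE_HZ


@dataclass
class PlayCollection:
    """An ordered set of plays with optional split labels and filter diagnostics."""

    plays: list[Play]
    split_labels: dict[tuple[int, int], str] = field(default_factory=dict)
    split_mode: str | None = None
    split_seed: int | None = None
    filter_report: dict | None = None
    diagnostics: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.plays)

    def __iter__(self):
        return iter(self.plays)

    def subset(self, label: str) -> list[Play]:
        return [p for p in self.plays if self.split_labels.get(p.key) == label]


# ---------------------------------------------------------------------------
# reading / writing the CSV dialect
# ---------------------------------------------------------------------------

_PASS_RESULT_MAP = {"C": "complete", "I": "incomplete", "IN": "intercepted"}


def _week_from_path(path: str | Path) -> int | None:
    import re

    m = re.search(r"week(\d+)", Path(path).name)
    return int(m.group(1)) if m else None


def read_tracking(csv_paths: Iterable[str | Path],
                  plays_meta_path: str | Path) -> PlayCollection:
    """Load tracking CSVs plus play metadata into a :class:`PlayCollection`.

    Entities are time-aligned on ``frameId``; an entity missing from a frame gets
    NaN coordinates (a gap).  Rows with unparseable or out-of-bounds coordinates
    are rejected with row-level diagnostics.  Plays lacking a ``ball_snap`` event
    are retained but flagged unusable in the diagnostics (``filter_plays`` drops
    them); plays lacking ``pass_forward`` are retained and marked no-pass.
    """
    meta_df = pd.read_csv(plays_meta_path)
    meta_by_key: dict[tuple[int, int], pd.Series] = {
        (int(r.gameId), int(r.playId)): r for r in meta_df.itertuples()
    }

    plays: list[Play] = []
    diagnostics: list[str] = []
    for path in csv_paths:
        df = pd.read_csv(path)
        missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        file_week = _week_from_path(path)

        # row-level validation
        bad = (
            df["x"].isna() | df["y"].isna()
            | (df["x"] < 0) | (df["x"] > FIELD_LENGTH)
            | (df["y"] < 0) | (df["y"] > FIELD_WIDTH)
        )
        if bad.any():
            for i in df.index[bad][:50]:
                diagnostics.append(
                    f"{Path(path).name}:row {i}: malformed coordinates "
                    f"(x={df.at[i, 'x']}, y={df.at[i, 'y']}) — rejected"
                )
            df = df[~bad]

        for (game_id, play_id), g in df.groupby(["gameId", "playId"], sort=True):
            key = (int(game_id), int(play_id))
            meta_row = meta_by_key.get(key)
            if meta_row is None:
                diagnostics.append(f"play {key}: no metadata row — skipped")
                continue
            play = _build_play(key, g, meta_row, file_week, diagnostics)
            if play is not None:
                plays.append(play)

    return PlayCollection(plays=plays, diagnostics=diagnostics)


def _build_play(key, g: pd.DataFrame, meta_row, file_week, diagnostics) -> Play | None:
    game_id, play_id = key
    frame_ids = np.sort(g["frameId"].unique()).astype(int)
    n = len(frame_ids)
    pos_of_frame = {f: i for i, f in enumerate(frame_ids)}

    possession = getattr(meta_row, "possessionTeam", None)
    direction = str(g["playDirection"].iloc[0])

    tracks: dict[int, Track] = {}
    events: dict[str, int] = {}
    for nfl_id, eg in g.groupby(g["nflId"].fillna(BALL_ID).astype(int)):
        team_raw = str(eg["team"].iloc[0])
        if team_raw == "football":
            team = "ball"
        elif possession is not None and team_raw == str(possession):
            team = "offense"
        else:
            team = "defense"
        x = np.full(n, np.nan)
        y = np.full(n, np.nan)
        s = np.full(n, np.nan)
        o = np.full(n, np.nan)
        idx = eg["frameId"].map(pos_of_frame).to_numpy()
        x[idx] = eg["x"].to_numpy()
        y[idx] = eg["y"].to_numpy()
        s[idx] = eg["s"].to_numpy()
        o[idx] = eg["o"].to_numpy()
        pos_label = eg["position"].iloc[0]
        pos_label = "" if pd.isna(pos_label) else str(pos_label)
        tracks[int(nfl_id)] = Track(int(nfl_id), team, pos_label, x, y, s, o)
        for ev, fr in zip(eg["event"], eg["frameId"]):
            if isinstance(ev, str) and ev not in ("", "None"):
                events.setdefault(ev, int(fr))

    week = file_week if file_week is not None else int(getattr(meta_row, "week", 1))
    pass_result = getattr(meta_row, "passResult", None)
    pass_result = None if pd.isna(pass_result) else str(pass_result)
    los = float(meta_row.absoluteYardlineNumber)
    afp = (FIELD_LENGTH - 10.0 - los) if direction == "right" else (los - 10.0)
    meta = PlayMeta(
        down=int(meta_row.down),
        yards_to_go=float(meta_row.yardsToGo),
        line_of_scrimmage_x=los,
        absolute_field_position=afp,
        play_direction=direction,  # type: ignore[arg-type]
        pass_outcome=_PASS_RESULT_MAP.get(pass_result or "", None),
        week=week,
        is_sack=(pass_result == "S") or ("qb_sack" in events),
        has_handoff=("handoff" in events),
    )
    if "ball_snap" not in events:
        diagnostics.append(f"play {key}: no ball_snap event — unusable")
    elif "pass_forward" not in events:
        diagnostics.append(f"play {key}: no pass_forward event — marked no-pass")
    return Play(play_id, game_id, frame_ids, tracks, meta, events)


def write_tracking(collection: PlayCollection, out_dir: str | Path) -> list[Path]:
    """Write a collection back out in the Big Data Bowl dialect.

    Produces one ``weekN.csv`` per week present plus a ``plays.csv``; this is the
    exact inverse of :func:`read_tracking` for gap-free plays (round-trip safe).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows_by_week: dict[int, list[dict]] = {}
    meta_rows = []
    for play in collection:
        if play.normalized:
            raise ValueError("write_tracking expects raw-frame plays; denormalize first")
        ev_by_frame = {fr: ev for ev, fr in sorted(play.events.items(), key=lambda kv: kv[1])}
        for track in play.tracks.values():
            team = ("football" if track.team == "ball"
                    else "OFF" if track.team == "offense" else "DEF")
            for i, fr in enumerate(play.frame_ids):
                if np.isnan(track.x[i]):
                    continue
                rows_by_week.setdefault(play.week, []).append({
                    "x": track.x[i], "y": track.y[i], "s": track.s[i], "o": track.o[i],
                    "event": ev_by_frame.get(int(fr), "None"),
                    "nflId": track.entity_id, "frameId": int(fr),
                    "playId": play.play_id, "gameId": play.game_id,
                    "team": team, "position": track.position or "",
                    "playDirection": play.meta.play_direction,
                })
        outcome_to_result = {v: k for k, v in _PASS_RESULT_MAP.items()}
        result = outcome_to_result.get(play.meta.pass_outcome or "", "")
        if play.meta.is_sack:
            result = "S"
        meta_rows.append({
            "gameId": play.game_id, "playId": play.play_id, "week": play.week,
            "down": play.meta.down, "yardsToGo": play.meta.yards_to_go,
            "absoluteYardlineNumber": play.meta.line_of_scrimmage_x,
            "possessionTeam": "OFF", "passResult": result,
        })
    written = []
    for week, rows in sorted(rows_by_week.items()):
        path = out_dir / f"week{week}.csv"
        pd.DataFrame(rows, columns=TRACKING_COLUMNS).to_csv(
            path, index=False, float_format="%.4f")
        written.append(path)
    meta_path = out_dir / "plays.csv"
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False, float_format="%.2f")
    written.append(meta_path)
    return written


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _gap_free_in_window(play: Play) -> bool:
    try:
        lo = play.frame_index(play.events["ball_snap"])
        hi = play.frame_index(play.events["pass_forward"])
    except KeyError:
        return False
    for t in play.tracks.values():
        if np.isnan(t.x[lo:hi + 1]).any() or np.isnan(t.y[lo:hi + 1]).any():
            return False
    return True


def filter_plays(collection: PlayCollection) -> PlayCollection:
    """Keep only modellable pass plays.

    Retained plays have exactly 7 tracked defenders and 6 tracked offensive players
    (one of them a QB), both a ``ball_snap`` and a later ``pass_forward`` event, no
    sack, no handoff, and no frame gaps for any rostered entity inside the
    snap→pass window.  Idempotent; the returned collection carries a
    ``filter_report`` with before/after counts and per-reason tallies.
    """
    kept: list[Play] = []
    reasons: dict[str, int] = {}

    def reject(reason: str) -> None:
        reasons[reason] = reasons.get(reason, 0) + 1

    for play in collection:
        ev = play.events
        if "ball_snap" not in ev:
            reject("no_ball_snap")
        elif "pass_forward" not in ev:
            reject("no_pass_forward")
        elif ev["pass_forward"] <= ev["ball_snap"]:
            reject("pass_before_snap")
        elif play.meta.is_sack:
            reject("sack")
        elif play.meta.has_handoff:
            reject("handoff")
        elif len(play.defender_ids) != N_DEFENDERS or len(play.offense_ids) != N_OFFENSE:
            reject("roster_not_7_6")
        elif sum(1 for t in play.tracks.values()
                 if t.team == "offense" and t.position == "QB") != 1:
            reject("no_unique_qb")
        elif BALL_ID not in play.tracks:
            reject("no_ball_track")
        elif not _gap_free_in_window(play):
            reject("frame_gaps")
        else:
            kept.append(play)

    report = {"before": len(collection.plays), "after": len(kept), "rejected": reasons}
    labels = {p.key: collection.split_labels[p.key]
              for p in kept if p.key in collection.split_labels}
    return PlayCollection(plays=kept, split_labels=labels,
                          split_mode=collection.split_mode,
                          split_seed=collection.split_seed,
                          filter_report=report,
                          diagnostics=list(collection.diagnostics))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _transform(direction: str, los: float, x: np.ndarray, y: np.ndarray):
    """Raw field frame -> normalized frame (rigid).

    right-directed play:  x' = y,          y' = los − x
    left-directed play:   x' = 53.3 − y,   y' = x − los

    Both put the line of scrimmage on y' = 0 with the offense backfield at
    positive y' (offense advances toward negative y'), and the left-play branch
    reflects so that the offense's own right sideline is always at x' = 0.
    """
    if direction == "right":
        return y.copy(), los - x
    return FIELD_WIDTH - y, x - los


def _inverse_transform(direction: str, los: float, xp: np.ndarray, yp: np.ndarray):
    if direction == "right":
        return los - yp, xp.copy()
    return yp + los, FIELD_WIDTH - xp


def normalize_play(play: Play) -> Play:
    """Return the play in the normalized (scrimmage-aligned) frame.

    The transform is rigid, so all pairwise distances and speeds are preserved;
    :func:`denormalize_play` inverts it exactly.  Orientation angles are carried
    through unchanged (they are not used by any downstream model).
    """
    if play.normalized:
        return play
    if play.meta.line_of_scrimmage_x is None or play.meta.play_direction not in ("left", "right"):
        raise ValueError(f"play {play.key}: missing scrimmage metadata, cannot normalize")
    new_tracks = {}
    for eid, t in play.tracks.items():
        xp, yp = _transform(play.meta.play_direction, play.meta.line_of_scrimmage_x, t.x, t.y)
        new_tracks[eid] = Track(eid, t.team, t.position, xp, yp, t.s.copy(), t.o.copy())
    return replace(play, tracks=new_tracks, normalized=True)


def denormalize_play(play: Play) -> Play:
    """Inverse of :func:`normalize_play` (exact up to floating-point round-off)."""
    if not play.normalized:
        return play
    new_tracks = {}
    for eid, t in play.tracks.items():
        x, y = _inverse_transform(play.meta.play_direction, play.meta.line_of_scrimmage_x,
                                  t.x, t.y)
        new_tracks[eid] = Track(eid, t.team, t.position, x, y, t.s.copy(), t.o.copy())
    return replace(play, tracks=new_tracks, normalized=False)


def mirror_play(play: Play) -> Play:
    """The same play run toward the other end zone (180° field rotation).

    Maps x → 120 − x, y → 53.3 − y, flips the play direction and moves the line
    of scrimmage accordingly.  ``normalize_play`` maps a play and its mirror to
    identical normalized coordinates.
    """
    if play.normalized:
        raise ValueError("mirror_play operates on raw-frame plays")
    new_tracks = {}
    for eid, t in play.tracks.items():
        new_tracks[eid] = Track(eid, t.team, t.position,
                                FIELD_LENGTH - t.x, FIELD_WIDTH - t.y,
                                t.s.copy(), t.o.copy())
    new_dir = "left" if play.meta.play_direction == "right" else "right"
    new_meta = replace(play.meta, play_direction=new_dir,
                       line_of_scrimmage_x=FIELD_LENGTH - play.meta.line_of_scrimmage_x)
    return replace(play, tracks=new_tracks, meta=new_meta)


# ---------------------------------------------------------------------------
# windowing and splitting
# ---------------------------------------------------------------------------

def clip_to_pass_window(play: Play) -> Play:
    """Restrict a play to the inclusive [ball_snap, pass_forward] frame window."""
    ev = play.events
    if "ball_snap" not in ev or "pass_forward" not in ev:
        raise ValueError(f"play {play.key}: needs both ball_snap and pass_forward events")
    if ev["pass_forward"] < ev["ball_snap"]:
        raise ValueError(f"play {play.key}: pass_forward precedes ball_snap (corrupt play)")
    lo = play.frame_index(ev["ball_snap"])
    hi = play.frame_index(ev["pass_forward"])
    sl = slice(lo, hi + 1)
    new_tracks = {
        eid: Track(eid, t.team, t.position, t.x[sl], t.y[sl], t.s[sl], t.o[sl])
        for eid, t in play.tracks.items()
    }
    frame_ids = play.frame_ids[sl]
    events = {e: f for e, f in play.events.items()
              if frame_ids[0] <= f <= frame_ids[-1]}
    return replace(play, tracks=new_tracks, frame_ids=frame_ids, events=events)


def split_collection(collection: PlayCollection, mode: str = "by_week",
                     seed: int | None = None) -> PlayCollection:
    """Label plays train/validation/test.

    ``by_week``: weeks 1–14 → train (with a 1-in-8 validation carve-out, seeded),
    weeks 15–17 → test.  ``random_70_30``: seeded 70/30 train/test partition with
    the same validation carve-out from the train side.
    """
    labels: dict[tuple[int, int], str] = {}
    rng = np.random.default_rng(seed if seed is not None else 0)
    if mode == "by_week":
        for p in collection:
            if p.week >= 15:
                labels[p.key] = "test"
            else:
                labels[p.key] = "validation" if rng.random() < 0.125 else "train"
    elif mode == "random_70_30":
        keys = [p.key for p in collection]
        order = rng.permutation(len(keys))
        n_test = round(0.3 * len(keys))
        test_set = {keys[i] for i in order[:n_test]}
        for p in collection:
            if p.key in test_set:
                labels[p.key] = "test"
            else:
                labels[p.key] = "validation" if rng.random() < 0.125 else "train"
    else:
        raise ValueError(f"unknown split mode: {mode!r}")
    return replace(collection, split_labels=labels, split_mode=mode, split_seed=seed)


def write_manifest(collection: PlayCollection, path: str | Path) -> None:
    """JSON manifest of play ids, split labels and filter disposition."""
    data = {
        "split_mode": collection.split_mode,
        "split_seed": collection.split_seed,
        "filter_report": collection.filter_report,
        "plays": [
            {"game_id": p.game_id, "play_id": p.play_id, "week": p.week,
             "split": collection.split_labels.get(p.key)}
            for p in collection
        ],
    }
    Path(path).write_text(json.dumps(data, indent=2))
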