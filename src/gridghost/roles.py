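"""Unsupervised tactical role alignment for tracked players.

Listed positions (CB, FS, ...) do not identify what a defender actually does on a
given play — cornerbacks swap sides, safeties rotate down.  To give every slot of a
learned feature vector a stable meaning, players are mapped to latent *roles*:

* **static** alignment fits a Gaussian mixture to snap-frame positions (in the
  normalized scrimmage frame) and assigns each play's defenders to mixture
  components with the Hungarian algorithm, one component per defender;
* **dynamic** alignment fits a hidden Markov model with Gaussian emissions to
  per-frame position sequences, so a play can be re-assigned window by window as
  tasks change mid-play (the "cross-update" used in alternating optimization).

Role indices are canonicalized by sorting component means left-to-right along x'
(ties by y'), so role 0 is always the offense's right-most deep slot, independent of
the random initialization of a refit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from hmmlearn.hmm import GaussianHMM
from hmmlearn.base import ConvergenceMonitor
from scipy.optimize import linear_sum_assignment
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

from .tracking import Play

_REG_COVAR = 1e-6  # diagonal regularization against singular covariances


@dataclass
class StaticRoleModel:
    """Gaussian mixture over snap positions, one component per role."""

    n_roles: int
    means: np.ndarray        # (n_roles, 2)
    covariances: np.ndarray  # (n_roles, 2, 2)
    weights: np.ndarray      # (n_roles,)
    log_likelihoods: np.ndarray  # per-EM-iteration mean log-likelihood

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "kind": "static", "n_roles": self.n_roles,
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "weights": self.weights.tolist(),
            "log_likelihoods": self.log_likelihoods.tolist(),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StaticRoleModel":
        d = json.loads(Path(path).read_text())
        return cls(d["n_roles"], np.array(d["means"]), np.array(d["covariances"]),
                   np.array(d["weights"]), np.array(d["log_likelihoods"]))


@dataclass
class DynamicRoleModel:
    """Hidden Markov model with Gaussian emissions over per-frame positions."""

    n_states: int
    transition: np.ndarray      # (n_states, n_states), row-stochastic
    emission_means: np.ndarray  # (n_states, 2)
    emission_covs: np.ndarray   # (n_states, 2, 2)
    initial: np.ndarray         # (n_states,)
    log_likelihoods: np.ndarray

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "kind": "dynamic", "n_states": self.n_states,
            "transition": self.transition.tolist(),
            "emission_means": self.emission_means.tolist(),
            "emission_covs": self.emission_covs.tolist(),
            "initial": self.initial.tolist(),
            "log_likelihoods": self.log_likelihoods.tolist(),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DynamicRoleModel":
        d = json.loads(Path(path).read_text())
        return cls(d["n_states"], np.array(d["transition"]),
                   np.array(d["emission_means"]), np.array(d["emission_covs"]),
                   np.array(d["initial"]), np.array(d["log_likelihoods"]))


@dataclass
class RoleAssignment:
    """A per-play (or per-window) bijection from players to roles."""

    play_key: tuple[int, int]
    mapping: dict[int, int]   # entity_id -> role index
    cost: float
    posteriors: np.ndarray | None = None  # (n_players, n_states) state posteriors

    def role_of(self, entity_id: int) -> int:
        return self.mapping[entity_id]

    def entity_for_role(self, role: int) -> int:
        for eid, r in self.mapping.items():
            if r == role:
                return eid
        raise KeyError(role)

    @property
    def role_order(self) -> list[int]:
        """Entity ids ordered by role index 0..n-1."""
        return [self.entity_for_role(r) for r in sorted(self.mapping.values())]


# ---------------------------------------------------------------------------
# snap-position extraction
# ---------------------------------------------------------------------------

def snap_positions(play: Play, team: str = "defense",
                   exclude_qb: bool = False) -> tuple[list[int], np.ndarray]:
    """(entity_ids, (n, 2) positions) at the ball_snap frame of a normalized play."""
    if not play.normalized:
        raise ValueError(f"play {play.key} must be normalized for role alignment")
    ids = play.entity_ids(team)
    if exclude_qb and team == "offense":
        ids = [i for i in ids if i != play.qb_id]
    return ids, play.positions_at(play.events["ball_snap"], ids)


# ---------------------------------------------------------------------------
# static model: EM-fitted Gaussian mixture, stepped to expose the LL sequence
# ---------------------------------------------------------------------------

def _canonical_order(means: np.ndarray) -> np.ndarray:
    return np.lexsort((means[:, 1], means[:, 0]))


def fit_static_role_model(plays: list[Play], n_roles: int = 7, seed: int = 0,
                          team: str = "defense", max_iter: int = 200,
                          tol: float = 1e-4) -> StaticRoleModel:
    """EM-fit a Gaussian mixture to snap-frame positions of ``team``.

    EM is stepped one iteration at a time so the recorded per-iteration mean
    log-likelihood sequence is available (it is non-decreasing, an EM guarantee
    the test suite asserts).  The fit is reproducible for a fixed seed.
    """
    if len(plays) < n_roles:
        raise ValueError(f"need at least {n_roles} plays, got {len(plays)}")
    pts = np.vstack([snap_positions(p, team, exclude_qb=True)[1] for p in plays])
    gmm = GaussianMixture(n_components=n_roles, covariance_type="full",
                          reg_covar=_REG_COVAR, random_state=seed,
                          max_iter=1, warm_start=True, init_params="kmeans",
                          tol=0.0)
    lls: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # single-step fits flag non-convergence
            gmm.fit(pts)
        ll = float(gmm.score(pts))
        lls.append(ll)
        if ll - prev < tol and len(lls) > 1:
            break
        prev = ll
    order = _canonical_order(gmm.means_)
    return StaticRoleModel(
        n_roles=n_roles,
        means=gmm.means_[order],
        covariances=gmm.covariances_[order],
        weights=gmm.weights_[order],
        log_likelihoods=np.asarray(lls),
    )


def hungarian_assign(cost: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimum-cost bijection rows→columns of a square cost matrix."""
    rows, cols = linear_sum_assignment(cost)
    return cols, float(cost[rows, cols].sum())


def assign_roles_static(model: StaticRoleModel, play: Play,
                        team: str = "defense") -> RoleAssignment:
    """Hungarian assignment of players to roles at the snap frame.

    Cost entry (i, j) is the negative log density of player i's snap position
    under role j's Gaussian; the returned bijection minimizes the total cost.
    """
    ids, pts = snap_positions(play, team, exclude_qb=True)
    if len(ids) != model.n_roles:
        raise ValueError(f"play {play.key}: {len(ids)} players vs {model.n_roles} roles")
    cost = np.empty((len(ids), model.n_roles))
    for j in range(model.n_roles):
        cov = model.covariances[j]
        if np.linalg.det(cov) <= 0:
            raise ValueError(f"role {j}: singular covariance, density degenerate")
        cost[:, j] = -multivariate_normal.logpdf(pts, model.means[j], cov)
    cols, total = hungarian_assign(cost)
    return RoleAssignment(play.key, {ids[i]: int(cols[i]) for i in range(len(ids))},
                          total)


# ---------------------------------------------------------------------------
# dynamic model: Baum–Welch HMM over per-frame position sequences
# ---------------------------------------------------------------------------

class _HistoryMonitor(ConvergenceMonitor):
    """Convergence monitor that keeps the full log-likelihood history."""

    def __init__(self, tol, n_iter, verbose):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)


def _defender_sequences(plays: list[Play]) -> tuple[np.ndarray, list[int]]:
    seqs, lengths = [], []
    for p in plays:
        if not p.normalized:
            raise ValueError(f"play {p.key} must be normalized")
        for eid in p.defender_ids:
            t = p.tracks[eid]
            if len(t) < 2:
                import warnings

                warnings.warn(f"play {p.key} entity {eid}: sequence shorter than "
                              "2 frames, excluded from HMM fit")
                continue
            seqs.append(np.column_stack([t.x, t.y]))
            lengths.append(len(t))
    return np.vstack(seqs), lengths


def fit_dynamic_role_model(plays: list[Play], n_states: int = 7, seed: int = 0,
                           max_iter: int = 50, tol: float = 1e-3,
                           init_means: np.ndarray | None = None,
                           init_covs: np.ndarray | None = None) -> DynamicRoleModel:
    """Baum–Welch fit of a Gaussian-emission HMM to defender (x', y') sequences.

    Emission features are positions only; one observation sequence per defender
    per play.  ``init_means``/``init_covs`` seed the emission Gaussians — in the
    alternating cross-update these are the role-conditional moments under the
    current role assignment, which anchors states to tactical roles; without
    them the default k-means initialization regularly lands several states on
    one crowded region.  The per-iteration log-likelihood history is recorded
    (monotone non-decreasing up to the library's floating-point slack).
    """
    X, lengths = _defender_sequences(plays)
    hmm = GaussianHMM(n_components=n_states, covariance_type="full",
                      n_iter=max_iter, tol=tol, random_state=seed,
                      min_covar=_REG_COVAR)
    if init_means is not None:
        if init_means.shape != (n_states, 2):
            raise ValueError("init_means must be (n_states, 2)")
        hmm.init_params = "st"
        hmm.means_ = np.asarray(init_means, dtype=float)
        if init_covs is not None:
            hmm.covars_ = np.asarray(init_covs, dtype=float)
        else:
            # broad, elongated along y' (routes run downfield): every state has
            # posterior mass from the first E-step
            hmm.covars_ = np.tile(np.diag([9.0, 100.0]), (n_states, 1, 1))
    hmm.monitor_ = _HistoryMonitor(hmm.tol, hmm.n_iter, hmm.verbose)
    hmm.fit(X, lengths)
    # seeded fits keep the seed indexation (state j stays role j); unseeded
    # fits are canonicalized left-to-right for stable role indices
    order = (np.arange(n_states) if init_means is not None
             else _canonical_order(hmm.means_))
    inv = np.empty_like(order)
    inv[order] = np.arange(n_states)
    return DynamicRoleModel(
        n_states=n_states,
        transition=hmm.transmat_[np.ix_(order, order)],
        emission_means=hmm.means_[order],
        emission_covs=hmm.covars_[order],
        initial=hmm.startprob_[order],
        log_likelihoods=np.asarray(hmm.monitor_.full_history),
    )


def emission_log_density(model: DynamicRoleModel, pts: np.ndarray) -> np.ndarray:
    """(T, n_states) log emission densities for a position sequence."""
    out = np.empty((len(pts), model.n_states))
    for j in range(model.n_states):
        cov = model.emission_covs[j]
        if np.linalg.det(cov) <= 0:
            raise ValueError(f"state {j}: singular emission covariance")
        out[:, j] = multivariate_normal.logpdf(pts, model.emission_means[j], cov)
    return out


def state_posteriors(model: DynamicRoleModel, pts: np.ndarray) -> np.ndarray:
    """Forward–backward state posteriors for one observation sequence."""
    hmm = GaussianHMM(n_components=model.n_states, covariance_type="full")
    hmm.startprob_ = model.initial
    hmm.transmat_ = model.transition
    hmm.means_ = model.emission_means
    hmm.covars_ = model.emission_covs
    return hmm.predict_proba(pts)


def viterbi_states(model: DynamicRoleModel, pts: np.ndarray) -> np.ndarray:
    """Most-likely state sequence for one position sequence (Viterbi decode)."""
    hmm = GaussianHMM(n_components=model.n_states, covariance_type="full")
    hmm.startprob_ = model.initial
    hmm.transmat_ = model.transition
    hmm.means_ = model.emission_means
    hmm.covars_ = model.emission_covs
    return hmm.predict(pts)


def assign_roles_dynamic(model: DynamicRoleModel, play: Play,
                         frame_slice: slice | None = None) -> RoleAssignment:
    """Hungarian role assignment for one play window under the HMM.

    Cost entry (i, j) is the negative total log emission density of defender i's
    windowed trajectory under state j; the Hungarian bijection minimizes the sum
    (equal to the brute-force minimum over all 7! permutations).  State
    posteriors per defender are attached for inspection.
    """
    if not play.normalized:
        raise ValueError(f"play {play.key} must be normalized")
    ids = play.defender_ids
    sl = frame_slice if frame_slice is not None else slice(None)
    cost = np.empty((len(ids), model.n_states))
    post = np.empty((len(ids), model.n_states))
    for i, eid in enumerate(ids):
        t = play.tracks[eid]
        pts = np.column_stack([t.x[sl], t.y[sl]])
        logd = emission_log_density(model, pts)
        cost[i] = -logd.sum(axis=0)
        post[i] = state_posteriors(model, pts).mean(axis=0)
    cols, total = hungarian_assign(cost)
    return RoleAssignment(play.key, {ids[i]: int(cols[i]) for i in range(len(ids))},
                          total, posteriors=post)
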