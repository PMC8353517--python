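# Methods

## Problem

From the snap to the quarterback's forward pass, a defense reacts to what the
offense shows. `gridghost` simulates that reaction: given the offensive
trajectories, the ball and the game state, it synthesizes *ghost* trajectories
for the seven defenders that represent average defensive behavior, and scores
both the observed and the ghost defense with a formation-level pass-completion
probability model. The completion model acts as a tactical third-party judge:
two defenses that reach different positions may still concede the same
completion probability, and that is the comparison that matters.

## Coordinate frame

All modelling happens in a scrimmage-aligned frame. For a right-directed play
`(x, y) → (x', y') = (y, LOS − x)`; for a left-directed play
`(x', y') = (53.3 − y, x − LOS)`. The line of scrimmage becomes the x'-axis
(`y' = 0`), the offensive backfield sits at positive y', the offense advances
toward negative y', and left-directed plays are reflected so the offense's own
right sideline is always at `x' = 0`. Both branches are rigid maps, so
distances and speeds are preserved and the transform inverts exactly. A play
and its 180°-rotated twin (same play run at the other end zone) normalize to
identical coordinates. Units are yards throughout — the tracking dialect's
field is 120 × 53.3 in yard units and we keep it that way.

## Role alignment

Feature-vector slots must mean the same thing on every play, but listed
positions do not provide that (cornerbacks swap sides; safeties rotate down).

**Static alignment.** A Gaussian mixture with one component per role is fitted
by EM to snap-frame positions. EM is stepped one iteration at a time through
scikit-learn's `GaussianMixture` with `warm_start`, which exposes the full
per-iteration log-likelihood sequence; the test suite asserts it is
non-decreasing. Per play, defenders are matched to components by the Hungarian
algorithm on cost `−log N(position | role)`. Role indices are canonicalized by
sorting component means along x' (ties by y'), so role 0 is a stable,
interpretable slot across refits. Offensive receivers are aligned with the
same machinery (5 roles; the QB is identified by listed position and kept
fixed).

**Dynamic alignment.** A hidden Markov model with Gaussian emissions over
per-frame `(x', y)'` positions, fitted by Baum–Welch (hmmlearn) with one
observation sequence per defender per play. Velocity, distance to the QB and
the ball position are deliberately not part of the emission space. Unseeded
fits initialize with k-means and are canonicalized like the static model.
Inside the alternating loop the emissions are instead seeded with the
role-conditional position moments under the current alignment and refined by a
single Baum–Welch pass: free-running EM prefers splitting dense position
regions over keeping one state per tactical role, which destroys the state ↔
role correspondence the cross-update depends on. Seeded fits keep the seed
indexation (state *j* stays role *j*).

Per-window assignment solves the Hungarian problem on the summed emission
log-densities of each defender's windowed trajectory (exactly the brute-force
permutation optimum; verified against it for all 7! permutations).
For the alternating loop a finer alignment is used: forward–backward state
posteriors are computed over each defender's whole trajectory, a Hungarian
bijection on the negative log posterior is solved per frame, and the previous
frame's bijection is kept unless the new optimum beats it by 5 nats. The
hysteresis suppresses oscillation between near-tied bijections while a genuine
role hand-off (posterior mass moving decisively to another state) flips within
a few frames. The sequence is initialized from the snap-frame static
assignment, which is reliable before anyone has moved.

## Pass-completion model

The pass is a single binary outcome for the whole formation — caught (1)
versus incomplete or intercepted (0) — with

P(y = 1 | X) = 1 / (1 + e^(−f(X)))  and equivalently  logit P = f(X),

evaluated at the pass-release frame. X concatenates, in order: five receiver
blocks (receiver x', y', speed; then for each of its two nearest defenders at
that frame — nearer first, distance ties broken by ascending entity id — the
defender's absolute position, position relative to the receiver, and speed),
a QB block (position, speed; no self-distances), and a metadata block
(distance to the attacked goal line, down, yards to go). 71 features total.
Defenders may appear in several receiver blocks; orientation is not used.

Two backends realize f: a feed-forward network (64, 64, 32 fully-connected
layers, Adam, learning rate 2·10⁻³, batch size 1024; scikit-learn
`MLPClassifier` driven by an explicit `partial_fit` epoch loop) and LightGBM
gradient-boosted trees (max depth 10, 60 leaves, learning rate 0.03). The
epoch loop exists so that **receiver-permutation augmentation** can resample
an independent random permutation of the five receiver blocks for every
training row in every epoch; the tree backend instead materializes eight
permuted copies of the training set. scikit-learn's MLP has no batch
normalization or dropout, so inputs are standardized instead and early
stopping (validation log-loss, patience 10, max 200 epochs) provides the
regularization; that is this package's design choice for the network
internals. `raw_score` re-implements the network's forward pass from the
fitted weight matrices so the logit/probability round trip is checked against
an independent code path, and the trees report their native raw score.
Accuracy is thresholded at 0.5; ROC/AUROC use the full threshold sweep with
trapezoidal integration and are verified against a pairwise-concordance
brute force. The baseline is the all-catch classifier.

## Ghost policies

Each of the seven defensive roles has its own recurrent policy: a stacked
two-layer LSTM (128 units each by default) over the full per-frame game state —
7 defender positions in role order, 5 receivers in role order, QB, ball, then
yards-to-go, down and field position (31 inputs) — with a linear head emitting
the role's next-step displacement (Δx', Δy') in yards per frame. Displacement
outputs keep regression targets bounded by the physical speed cap wherever the
play happens on the field. Inputs are divided by 10 yards for conditioning.

torch is not a dependency: the LSTM is implemented directly in numpy
(forward, full backpropagation through time, Adam), and the analytic gradients
are verified against central finite differences in the test suite. Hidden
state is reset at window boundaries during training and at the snap during
rollout. Variable-length windows are zero-padded per batch with a loss mask.

**Training phases.**

1. *Pretraining*: teacher-forced least-squares one-step prediction; every
   input is observed data.
2. *Single-policy DAgger*: one role at a time is rolled out within each
   training window, its own position inputs replaced by its integrated
   predictions while everything else stays observed. Each visited state is
   paired with the expert correction — the displacement from the predicted
   position toward the next observed position, capped at the 11 yd/s physical
   limit (there is no omniscient oracle; this is the standard imitation
   surrogate, and the cap keeps corrective targets physical). Visited
   windows are aggregated (the aggregate never shrinks), the optimizer
   moments are reset, and the policy is refitted on the aggregate; following
   the original dataset-aggregation algorithm, the iterate with the best
   validation closed-loop error is the one kept.
3. *Joint training*: all seven roles impute their own predictions
   simultaneously (offense and ball observed), with the same aggregation,
   refitting and best-iterate rule applied jointly.

Windows are 25 frames with stride 15 (overlap 10); the trailing remainder is
kept as a shorter window.

**Alternating (cross-update) optimization.** Cycle 0 trains policies under the
static assignment. Each further cycle refits the dynamic role model with
policies fixed (emissions seeded from role-conditional moments as above),
recomputes the per-frame alignment, cuts every training window at the frames
where the bijection changes so each piece has a constant, coherent role
assignment with no identity teleports, and retrains the policies from scratch
on the re-aligned windows. The loop stops when validation rollout MAE fails to
improve by the tolerance over a full cycle and returns the best-validation
state — policies, assignment mode and the matching role model restored
together, since policies are only meaningful under the alignment they were
trained with.

## Synthetic data

The generator emulates the tracking dialect end to end: plays are simulated in
the normalized frame, converted to raw field coordinates, and written as
`weekN.csv` + `plays.csv`, so every consumer exercises the same read → filter
→ normalize → clip pipeline as real data.

* **Formation**: five receivers at canonical alignments (wide left … wide
  right, jittered), QB in the pocket; defense = five man defenders 4–5.5 yd
  off their receivers, an edge rusher on the line, a deep middle safety.
  Canonical slots matter: they make snap formations clusterable into stable
  roles, which real formations are and uniform-random ones are not.
* **Routes**: go, hitch, crossing, flat — waypoint-following at capped speed
  (≤ 11 yd/s).
* **Defense**: first-order pursuit — each defender closes a fixed fraction
  *g* of the gap to its target per frame (man defenders → assigned receiver,
  rusher → QB, safety → receiver centroid shadowed from 6 yd behind), plus
  i.i.d. Gaussian reaction noise σ and the speed cap. At σ = 0 the dynamics
  have exact closed forms (collocation at g = 1, geometric gap decay at
  g = 0.5) used as oracles. The expert is deliberately simple enough for a
  small recurrent policy to learn on a CPU in minutes.
* **Durations**: snap→pass window = 2 s + a truncated-exponential tail
  (scale 1.8 s, truncated at 6 s), giving the 2–8 s range with mean ≈ 3.6 s.
* **Ground-truth completion**: a logistic model over interpretable geometry at
  the pass frame — openness of the most-open receiver (distance to nearest
  defender), QB pressure (distance to nearest defender), and depth of the
  most-open receiver. Reference points sit at the feature means of the
  default conditions; the openness weight (2.5/yd) dominates so that at low
  noise the Bayes AUROC of the truth is ≈ 0.92–0.95, i.e. the label actually
  is recoverable, and the bias puts the completion rate near 0.55. Pursuit
  gains are resampled per play over (0.15, 0.5), which is what gives openness
  its dynamic range.
* **Role switches**: `inject_role_switch` re-simulates a play with two man
  defenders exchanging assignments at a chosen frame (0 = a cross-matchup
  from the snap); the true role sequence is recorded for recovery tests.

## Study conditions and problem sizes

The reproduction studies (`gridghost.studies`, driven by both
`tests/test_acceptance.py` and `scripts/acceptance.py`) fix these sizes as
their conditions: 1,000 plays for duration statistics; 5,000 low-noise
(σ = 0.05) passes for completion recovery and the order-invariance pairing;
500 formations for static role recovery; 200 man-coverage plays (fixed
g = 0.3, 6 s windows, σ = 0.2) for the imitation comparison, with
hidden size 32 and a 5 × 10-epoch DAgger budget mirrored by equal extra
teacher-forced epochs in the pretrain-only arm; 100 plays (σ = 0.05, 5 s,
all-hitch routes, a switch or cross-matchup in every play) for the
coordination comparison at 60 pretrain epochs and two cycles per arm. The
hitch-only routes in the coordination fixture are deliberate: pursuit tasks
then stay inside their spatial role regions, so the only alignment events are
the injected switches — with deep routes, defenders legitimately traverse
other roles' regions and a position-only role model cannot distinguish
travel from hand-off.

Of the paired comparisons, the coordination one is the least robust: the
cross-update cycle beats the same-seed static retrain in most but not all
draws at this scale, because a single policy-training run's validation MAE
varies by a few tenths of a yard and the alignment benefit is of the same
order. The studies fix the seed along with the other conditions, so their
outcome is reproducible; across arbitrary seeds the ordering can flip, and
the acceptance report simply states both arms' errors.

## Numerical choices

* Covariances regularized by 10⁻⁶ on the diagonal; singular covariances in
  assignment costs raise instead of silently degenerating.
* Nearest-defender and canonical-order ties break by ascending entity id /
  lexicographic mean, for determinism.
* The LSTM forget-gate bias initializes at 1; the output head initializes
  near zero so untrained ghosts stand still rather than fly off.
* Every stochastic component (generator, initializations, batch shuffling,
  permutation augmentation, splits) draws from `numpy.random.default_rng`
  with an explicit seed; CSVs are written with fixed float formatting, so
  equal seeds give byte-identical files.
* Zero-variance correlation inputs yield a flagged `None`, not an exception.

## What the synthetic results do and do not show

Passing studies demonstrate that the machinery is correct and that each
mechanism delivers its intended effect under conditions where the truth is
known: the completion model recovers a known logistic ground truth, augmented
training is measurably more order-invariant, dataset aggregation beats pure
teacher forcing on long rollouts, and coordinated re-alignment beats static
assignment when tasks genuinely hand over mid-play. They do not certify
real-NFL numbers: real defensive behavior is multi-modal, scheme-dependent and
far richer than first-order pursuit, real formations are more varied than five
canonical slots, and real labels carry noise sources (drops, throwaways,
penalties) the generator omits. The dataset-count checks against the real
2019 season run only when the public Big Data Bowl 2021 download is present
under `data/big-data-bowl-2021`.

## Known limitations

* The numpy LSTM is CPU-bound; season-scale training is supported in
  principle but slow (hidden size and epoch counts are configurable).
* Position-only dynamic roles cannot separate co-located tasks (a deep-zone
  safety and a man defender chasing a deep route occupy the same region).
* The completion model extends the pass-frame encoding to every frame for the
  probability-over-time curves; early-play frames are out of its training
  distribution and those curves are qualitative.
* Post-catch movement, QB decision-making and offense ghosting are out of
  scope.
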