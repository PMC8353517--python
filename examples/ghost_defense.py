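"""Train ghost policies on scripted man coverage and roll out a defense.

Small-scale version of the imitation pipeline: teacher-forced pretraining plus
dataset-aggregation (DAgger) refinement for every role, then an autoregressive
rollout of all seven ghosts on a held-out play.
"""

import numpy as np

from gridghost import evaluation, ghosting, synth, tracking

cfg = synth.SynthConfig(sigma=0.2, fixed_duration_s=4.0, gain_range=(0.3, 0.3))
coll, _, _ = synth.generate_dataset(60, cfg, seed=9)
plays = [tracking.clip_to_pass_window(tracking.normalize_play(p))
         for p in tracking.filter_plays(coll)]
train, held_out = plays[:50], plays[50:]

gcfg = ghosting.GhostConfig(hidden_size=24, pretrain_epochs=60,
                            dagger_iters=3, dagger_refit_epochs=8, seed=0)
model = ghosting.GhostModel(gcfg)
model.fit_role_models(train)
windows = ghosting.make_training_windows(model.tensors(train))
print(f"{len(train)} plays → {len(windows)} training windows "
      f"(25 frames, stride 15)")

ghosting.pretrain_policies(model, windows)
for role in range(ghosting.N_ROLES):
    ghosting.dagger_train_single(model, role, windows)
print("pretraining + per-role DAgger done")

play = held_out[0]
assignment = model.assign_static(play)
tensor = ghosting.build_play_tensor(play, assignment, model.offense_role_model)
ghost = ghosting.rollout(model, play, assignment)
profile = evaluation.rollout_mae(tensor.defender_pos, ghost)
for t in (10, 20, min(30, len(profile.per_timestep_mae) - 1)):
    print(f"  ghost error at {t / 10:.0f} s: "
          f"{profile.per_timestep_mae[t]:.2f} yards")
print(f"overall rollout MAE {profile.overall_mae:.2f} yards over "
      f"{play.n_frames} frames")
# Errors around a yard or two mean the ghosts run recognizably the same
# coverage as the scripted defense they imitate; a naive (non-DAgger) policy
# drifts by roughly the width of the field's numbers instead.
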