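"""Judge ghost defenses with the completion model (the third-party metric).

Trains a completion classifier and a small ghost model, substitutes ghost
trajectories for the observed defenders on held-out plays, and correlates the
completion probabilities the classifier assigns to the two defenses.
"""

from gridghost import completion, evaluation, ghosting, synth, tracking

# completion classifier on generic plays
coll, labels, _ = synth.generate_dataset(1200, seed=31)
cplays = [tracking.clip_to_pass_window(tracking.normalize_play(p))
          for p in tracking.filter_plays(coll)]
clf = completion.train_classifier(
    completion.design_matrix(cplays), labels,
    completion.ClassifierConfig(backend="gbt", augment=True, seed=0))

# ghost model on scripted man coverage
mcfg = synth.SynthConfig(sigma=0.2, fixed_duration_s=4.0, gain_range=(0.3, 0.3))
mcoll, _, _ = synth.generate_dataset(60, mcfg, seed=13)
mplays = [tracking.clip_to_pass_window(tracking.normalize_play(p))
          for p in tracking.filter_plays(mcoll)]
train, held_out = mplays[:48], mplays[48:]
model = ghosting.GhostModel(ghosting.GhostConfig(hidden_size=24,
                                                 pretrain_epochs=60,
                                                 dagger_iters=3,
                                                 dagger_refit_epochs=8, seed=0))
model.fit_role_models(train)
windows = ghosting.make_training_windows(model.tensors(train))
ghosting.pretrain_policies(model, windows)
for role in range(ghosting.N_ROLES):
    ghosting.dagger_train_single(model, role, windows)

ghosts = [ghosting.ghost_play(model, p) for p in held_out]
cmp_ = evaluation.compare_completion(held_out, ghosts, clf)
print(f"completion probability, observed defense: "
      f"mean {cmp_.true_probs.mean():.3f}")
print(f"completion probability, ghost defense:    "
      f"mean {cmp_.ghost_probs.mean():.3f}")
print(f"Pearson r across {len(held_out)} plays: {cmp_.pearson_r}")
# A positive correlation says the ghosts concede easy and hard completions on
# the same plays the real defense would — agreement in tactical effect even
# where the exact trajectories differ.  The ghost mean sits above the observed
# mean because the generator's completion ground truth is steep in receiver
# openness: every yard of imitation error reads as extra separation, so
# lightly trained ghosts are judged more permissive than the scripted defense.
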