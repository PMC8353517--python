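"""Align defenders to tactical roles, independent of listed position.

Fits a Gaussian mixture to snap formations, assigns each play's defenders to
roles with the Hungarian algorithm, then fits the Gaussian-emission HMM used
for dynamic (window-level) re-alignment.
"""

import numpy as np

from gridghost import roles, synth, tracking

coll, _, _ = synth.generate_dataset(80, seed=3)
plays = [tracking.clip_to_pass_window(tracking.normalize_play(p))
         for p in tracking.filter_plays(coll)]

static = roles.fit_static_role_model(plays, n_roles=7, seed=0)
print("static role means (x' across field, y' depth behind scrimmage):")
for r, (mx, my) in enumerate(static.means):
    print(f"  role {r}: ({mx:5.1f}, {my:6.1f})")
print(f"EM iterations {len(static.log_likelihoods)}, "
      f"log-likelihood monotone: "
      f"{bool(np.all(np.diff(static.log_likelihoods) >= -1e-9))}")

a = roles.assign_roles_static(static, plays[0])
print(f"play {plays[0].key}: defender→role bijection {a.mapping} "
      f"(total cost {a.cost:.1f})")

dynamic = roles.fit_dynamic_role_model(plays[:30], n_states=7, seed=0,
                                       max_iter=10)
d = roles.assign_roles_dynamic(dynamic, plays[0])
print(f"dynamic (trajectory-level) assignment: {d.mapping}")
# Roles are sorted left-to-right across the field, so role 0 is always the
# defender covering the offense's right sideline regardless of which tracked
# player fills it on a given play.
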