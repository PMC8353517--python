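import numpy as np
import pytest

from gridghost import synth, tracking


@pytest.fixture(scope="session")
def small_collection():
    """30 default-condition plays with labels and truth probabilities."""
    coll, labels, probs = synth.generate_dataset(30, seed=11)
    return coll, labels, probs


@pytest.fixture(scope="session")
def norm_plays(small_collection):
    """Filtered, normalized, snap→pass-clipped plays."""
    coll, _, _ = small_collection
    filtered = tracking.filter_plays(coll)
    return [tracking.clip_to_pass_window(tracking.normalize_play(p))
            for p in filtered]


@pytest.fixture(scope="session")
def man_fixture_plays():
    """Scripted man-coverage fixture: fixed pursuit gain, fixed 4 s windows."""
    cfg = synth.SynthConfig(sigma=0.1, fixed_duration_s=4.0,
                            gain_range=(0.3, 0.3))
    coll, _, _ = synth.generate_dataset(40, cfg, seed=21)
    filtered = tracking.filter_plays(coll)
    return [tracking.clip_to_pass_window(tracking.normalize_play(p))
            for p in filtered]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
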