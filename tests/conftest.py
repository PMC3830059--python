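import numpy as np
import pytest

import p3attn as pa


@pytest.fixture(scope="session")
def montage():
    return pa.make_montage()


@pytest.fixture(scope="session")
def times():
    return pa.default_times_ms()


@pytest.fixture(scope="session")
def healthy_small(montage):
    """One simulated healthy subject at reduced trial counts (fast)."""
    prof = pa.builtin_profiles()["HEALTHY"]
    prof.n_trials = {"explicit_target": 80, "implicit_target": 80,
                     "distractor": 120}
    return pa.simulate_epochs(prof, montage, rng=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
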