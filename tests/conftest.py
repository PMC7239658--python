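import numpy as np
import pytest

import wtanet as w


@pytest.fixture(scope="session")
def full_cfg():
    """Default full circuit, two channels."""
    return w.default_config(2)


@pytest.fixture(scope="session")
def full_net(full_cfg):
    return w.build_network(full_cfg)


@pytest.fixture(scope="session")
def full_net6():
    return w.build_network(w.default_config(6))


@pytest.fixture(scope="session")
def bare_cfg():
    """All motifs disabled: independent feedforward chains."""
    return w.default_config(
        2, motifs=w.MotifFlags(False, False, False, False)
    )


@pytest.fixture(scope="session")
def bare_net(bare_cfg):
    return w.build_network(bare_cfg)


@pytest.fixture
def crp_grid():
    return np.arange(2.0, 16.1, 1.0)


def make_crp(norm_A, comps, means, sds, n_trials=10):
    """Hand-constructed CRP for estimator unit tests."""
    return w.CRPCurve(
        norm_A=float(norm_A),
        competitor_norms=np.asarray(comps, dtype=float),
        mean_response=np.asarray(means, dtype=float),
        sd_response=np.asarray(sds, dtype=float),
        n_trials=n_trials,
        channel_probed=0,
    )
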