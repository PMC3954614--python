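import numpy as np
import pytest

import chokinet as ck


@pytest.fixture(scope="session")
def net():
    return ck.build_canonical_network()


@pytest.fixture(scope="session")
def base_params():
    return ck.ParameterSet.canonical_defaults()


@pytest.fixture(scope="session")
def parental_params(base_params):
    return ck.make_clone(ck.CLONES["parental"], base_params)


@pytest.fixture(scope="session")
def parental_truth(net, parental_params):
    """Noise-free parental reference culture (observations + trajectory)."""
    return ck.generate_experiment(ck.CLONES["parental"],
                                  noise=ck.NoiseModel(cv=0.0, seed=0),
                                  net=net)


@pytest.fixture(scope="session")
def parental_noisy(net):
    """Duplicate-flask parental culture at 5% CV."""
    return ck.generate_experiment(ck.CLONES["parental"],
                                  noise=ck.NoiseModel(cv=0.05, seed=42),
                                  net=net)


@pytest.fixture(scope="session")
def high_truth(net):
    """Noise-free induced high-producer culture."""
    return ck.generate_experiment(ck.CLONES["high"],
                                  ck.CultureSchedule(induced=True),
                                  ck.NoiseModel(cv=0.0, seed=0), net=net)


@pytest.fixture(scope="session")
def reference_state():
    return ck.StateVector()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
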