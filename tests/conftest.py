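import numpy as np
import pytest

from hesdyn import LatticeSpec, ModelParams, SimConfig, build_lattice


@pytest.fixture(scope="session")
def params():
    """Reference kinetic parameters (mid-range LI threshold)."""
    return ModelParams(p0_li=4000.0)


@pytest.fixture(scope="session")
def column26():
    return LatticeSpec(26, 1)


@pytest.fixture(scope="session")
def column26_map(column26):
    return build_lattice(column26)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_sim():
    """A small stochastic run shared by analysis tests."""
    from hesdyn import simulate

    traj = simulate(
        ModelParams(p0_li=4000.0),
        LatticeSpec(26, 1),
        SimConfig(duration_h=60.0, seed=7),
        eps_ratio=1.5,
    )
    return traj
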