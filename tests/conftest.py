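import numpy as np
import pytest

import lencom as lc


def make_toy3(tau_on: bool = True, other: float = 5e7, n_l: int = 16):
    """A 3-species forage/mesopredator/top-predator food chain.

    Hand-picked life histories spanning the size spectrum (Linf 20, 50,
    120 cm), hockey-stick recruitment scaled to asymptotic weight, a
    constant residual mortality, and a strictly lower-triangular
    predation topology (bigger eats smaller).
    """
    linf = np.array([20.0, 50.0, 120.0])
    w_inf = 0.008 * linf**3
    species = lc.SpeciesTable(
        names=["prey", "meso", "top"],
        linf=linf,
        lmat=np.array([11.0, 27.0, 65.0]),
        w_a=np.full(3, 0.008),
        w_b=np.full(3, 3.0),
        k=np.array([1.0, 0.45, 0.2]),
        rec_fun=["hockey-stick"] * 3,
        rec_a=10.0 / w_inf,
        rec_b=1e3 * w_inf,
        m1_fun=["constant"] * 3,
        m1_rate=np.full(3, 0.5),
    )
    tau = (
        np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0]])
        if tau_on
        else np.zeros((3, 3))
    )
    return lc.build_community(
        species, tau=tau, pred=lc.PredationParams(other=other), n_l=n_l
    )


@pytest.fixture(scope="session")
def toy3():
    """3-species community with predation links."""
    return make_toy3(tau_on=True)


@pytest.fixture(scope="session")
def toy3_nopred():
    """Same community, all predation links switched off."""
    return make_toy3(tau_on=False)


@pytest.fixture(scope="session")
def community():
    """The default synthetic 21-species community with its 4 fleets."""
    fx = lc.generate_fixture(lc.FixtureSpec(seed=1))
    return lc.build_community(fx.species, tau=fx.tau, gears=fx.gears, pred=fx.pred)


@pytest.fixture(scope="session")
def community_state0(community):
    """Burnt-in initial state of the 21-species community."""
    return lc.get_N0(community, burn_years=10)
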