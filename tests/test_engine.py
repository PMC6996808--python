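import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import lencom as lc
from lencom import (
    CommunityState,
    EffortSchedule,
    calc_F,
    calc_M2,
    get_N0,
    growth_step,
    mortality_step,
    recruitment,
    run,
    seed_state,
)
from lencom.engine import calc_ration

from conftest import make_toy3


# ----------------------------------------------------------------------
# recruitment functions


@pytest.mark.parametrize(
    "fun,a,b,ssb,expected",
    [
        ("hockey-stick", 2.0, 10.0, 5.0, 10.0),
        ("hockey-stick", 2.0, 10.0, 50.0, 20.0),     # plateau a*b
        ("ricker", 1.0, 0.1, 10.0, 10.0 * np.exp(-1.0)),
        ("beverton-holt", 2.0, 0.5, 10.0, 20.0 / 6.0),
        ("linear", 3.0, 0.0, 7.0, 21.0),
        ("constant", 5.0, 0.0, 123.0, 5.0),
    ],
)
def test_recruitment_families(fun, a, b, ssb, expected):
    assert recruitment(ssb, fun, a, b) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("fun", ["hockey-stick", "ricker", "beverton-holt", "linear"])
def test_no_spawners_no_recruits(fun):
    assert recruitment(0.0, fun, 2.0, 1.0) == 0.0


def test_recruitment_rejects_negative_ssb_and_unknown_family():
    with pytest.raises(ValueError):
        recruitment(-1.0, "linear", 1.0, 0.0)
    with pytest.raises(ValueError):
        recruitment(1.0, "cushing", 1.0, 0.0)


# ----------------------------------------------------------------------
# mortality


def test_mortality_survival_value():
    N = np.array([[100.0]])
    F = np.array([[[0.5]]])
    survivors, catch_n = mortality_step(
        N, np.array([[0.2]]), np.array([[0.3]]), F, dt=0.1
    )
    assert survivors[0, 0] == pytest.approx(100.0 * np.exp(-0.1), rel=1e-12)
    # fished share of deaths is F/Z = 0.5
    assert catch_n[0, 0, 0] == pytest.approx(0.5 * (100.0 - survivors[0, 0]))


def test_zero_total_mortality_changes_nothing():
    N = np.array([[10.0, 3.0]])
    survivors, catch_n = mortality_step(
        N, np.zeros((1, 2)), np.zeros((1, 2)), np.zeros((1, 2, 2)), dt=0.1
    )
    np.testing.assert_array_equal(survivors, N)
    assert catch_n.sum() == 0.0


@settings(max_examples=50, deadline=None)
@given(
    N=arrays(float, (4, 3), elements=st.floats(0.0, 1e6)),
    M1=arrays(float, (4, 3), elements=st.floats(0.0, 2.0)),
    M2=arrays(float, (4, 3), elements=st.floats(0.0, 2.0)),
    F=arrays(float, (4, 3, 2), elements=st.floats(0.0, 2.0)),
)
def test_death_accounting_is_exact(N, M1, M2, F):
    """Deaths equal the natural share plus catches (Baranov partition)."""
    survivors, catch_n = mortality_step(N, M1, M2, F, dt=0.1)
    assert np.all(survivors >= 0)
    deaths = N - survivors
    Z = M1 + M2 + F.sum(axis=2)
    with np.errstate(invalid="ignore"):
        natural = np.where(Z > 0, (M1 + M2) / Z, 0.0) * deaths
    np.testing.assert_allclose(
        deaths, natural + catch_n.sum(axis=2), rtol=1e-10, atol=1e-10
    )


# ----------------------------------------------------------------------
# growth


def test_growth_moves_expected_proportion():
    N = np.array([[10.0], [0.0]])
    phi = np.array([[0.3], [0.0]])
    out = growth_step(N, phi)
    np.testing.assert_allclose(out[:, 0], [7.0, 3.0])


def test_growth_identity_when_phi_zero():
    N = np.arange(8.0).reshape(4, 2)
    np.testing.assert_array_equal(growth_step(N, np.zeros((4, 2))), N)


@settings(max_examples=50, deadline=None)
@given(
    N=arrays(float, (5, 2), elements=st.floats(0.0, 1e6)),
    phi=arrays(float, (5, 2), elements=st.floats(0.0, 1.0)),
)
def test_growth_conserves_totals_with_closed_top(N, phi):
    phi = phi.copy()
    phi[-1] = 0.0
    out = growth_step(N, phi)
    np.testing.assert_allclose(out.sum(axis=0), N.sum(axis=0), rtol=1e-10)
    assert np.all(out >= 0)


# ----------------------------------------------------------------------
# predation mortality


def brute_force_M2(N, params):
    """Naive quadruple loop over (pred sp, pred class, prey sp, prey class)."""
    n_l, n_s = N.shape
    w = params.w
    ration = calc_ration(params)
    M2 = np.zeros((n_l, n_s))
    for m in range(n_s):
        for n in range(n_l):
            avail = params.pred.other
            for ip in range(n_s):
                for jp in range(n_l):
                    avail += params.suit[m, n, ip, jp] * N[jp, ip] * w[jp, ip]
            if avail <= 0:
                continue
            for i in range(n_s):
                for j in range(n_l):
                    M2[j, i] += (
                        ration[n, m] * N[n, m] * params.suit[m, n, i, j] / avail
                    )
    return M2 / params.dt


@pytest.fixture(scope="module")
def toy2():
    """2-species, 3-class community for the brute-force oracle."""
    sp = lc.SpeciesTable(
        names=["a", "b"], linf=np.array([25.0, 60.0]), lmat=np.array([12.0, 30.0]),
        w_a=np.full(2, 0.01), w_b=np.full(2, 3.0), k=np.array([0.9, 0.4]),
        rec_fun=["hockey-stick"] * 2, rec_a=np.array([1.0, 1.0]),
        rec_b=np.array([1e4, 1e5]),
    )
    return lc.build_community(
        sp, tau=np.array([[1.0, 0.0], [1.0, 1.0]]),
        pred=lc.PredationParams(other=1e4), n_l=3,
    )


def test_m2_matches_brute_force_quadruple_sum(toy2, toy3):
    rng = np.random.default_rng(42)
    for params in (toy2, toy3):
        N = rng.uniform(0.0, 1e5, size=(params.n_l, params.n_s))
        fast = calc_M2(N, params)
        slow = brute_force_M2(N, params)
        np.testing.assert_allclose(fast, slow, rtol=1e-10, atol=1e-13)


def test_m2_zero_without_links_or_predators(toy2, toy3_nopred):
    N = np.full((toy3_nopred.n_l, 3), 1e4)
    assert np.all(calc_M2(N, toy3_nopred) == 0.0)
    assert np.all(calc_M2(np.zeros((toy2.n_l, 2)), toy2) == 0.0)


def test_m2_vanishes_as_other_food_dominates(toy2):
    from dataclasses import replace

    N = np.full((3, 2), 1e4)
    base = calc_M2(N, toy2).max()
    previous = base
    for other in (1e6, 1e8, 1e10):
        params = replace(toy2, pred=replace(toy2.pred, other=other))
        current = calc_M2(N, params).max()
        assert current < previous
        previous = current
    assert previous < 1e-3 * base


def test_m2_guards_zero_available_food(toy2):
    from dataclasses import replace

    params = replace(toy2, pred=replace(toy2.pred, other=0.0))
    # predators present but nothing edible and no other food
    N = np.zeros((3, 2))
    N[2, 1] = 1e4   # only the top class of the larger species
    M2 = calc_M2(N, params)
    assert np.all(np.isfinite(M2)) and np.all(M2 >= 0)


# ----------------------------------------------------------------------
# fishing mortality


def test_calc_F_examples():
    Q = np.zeros((1, 1, 2))
    Q[0, 0] = [0.4, 0.2]
    assert calc_F(Q, np.array([0.5, 1.0]))[0, 0] == pytest.approx(0.4)
    assert np.all(calc_F(Q, np.zeros(2)) == 0.0)
    with pytest.raises(ValueError):
        calc_F(Q, np.array([-0.1, 0.0]))
    with pytest.raises(ValueError):
        calc_F(Q, np.zeros(3))


def test_unit_effort_means_unit_F_on_most_selected_class(community):
    F = calc_F(community.Q, np.full(community.n_gears, 0.25))
    assert F.max() == pytest.approx(0.25, abs=1e-12)


# ----------------------------------------------------------------------
# the run loop


def test_zero_years_returns_empty_series(toy3):
    out = run(toy3, seed_state(toy3), years=0)
    assert out.steps == 0 and out.years == 0


def test_run_rejects_mismatched_effort(toy3):
    state = seed_state(toy3)
    with pytest.raises(ValueError, match="effort schedule covers"):
        run(toy3, state, years=3, effort=np.zeros((2, 0)))


def test_state_is_constant_when_all_processes_are_null():
    sp = lc.SpeciesTable(
        names=["s"], linf=np.array([50.0]), lmat=np.array([25.0]),
        w_a=np.array([0.01]), w_b=np.array([3.0]), k=np.array([1e-9]),
        rec_fun=["linear"], rec_a=np.array([2.0]), rec_b=np.array([0.0]),
        kappa=np.array([100.0]),  # ogive numerically 0 below maturity
        m1_fun=["constant"], m1_rate=np.array([0.0]),
    )
    from dataclasses import replace

    params = lc.build_community(sp, tau=np.zeros((1, 1)), n_l=4)
    params = replace(params, phi=np.zeros_like(params.phi))  # freeze growth
    # put the fish below maturity so SSB = 0 and recruitment is zero
    N0 = np.zeros((4, 1))
    N0[0, 0] = 7.0
    out = run(params, CommunityState(N0), years=3)
    np.testing.assert_allclose(out.N, np.broadcast_to(N0, out.N.shape))


def test_one_year_equals_ten_hand_chained_steps(toy3):
    """The run loop is exactly recruitment + 10x (mortality, growth)."""
    params = toy3
    state0 = get_N0(params, burn_years=2)
    effort = EffortSchedule(np.full((1, 0), 0.0)[:, :0], ())
    effort = np.zeros((1, params.n_gears))
    out = run(params, state0, years=1, effort=effort)

    # manual chain with the public pieces
    N = state0.N.copy()
    ssb = (N * params.w * params.mature).sum(axis=0)
    R = np.array([
        recruitment(ssb[i], params.species.rec_fun[i],
                    params.species.rec_a[i], params.species.rec_b[i])
        for i in range(params.n_s)
    ])
    for s in range(params.steps_per_year):
        if s == 0:
            N[0] += R
        M2 = calc_M2(N, params)
        N, _ = mortality_step(
            N, params.M1, M2, np.zeros((params.n_l, params.n_s, 0)), params.dt
        )
        N = growth_step(N, params.phi)
    np.testing.assert_allclose(out.N[-1], N, rtol=1e-12, atol=0)
    np.testing.assert_allclose(out.R[0], R, rtol=1e-12)


def test_catch_zero_where_effort_zero(toy3, community, community_state0):
    out = run(community, community_state0, years=2)
    assert out.Catch.sum() == 0.0
    assert np.all(out.N >= 0)


def test_more_effort_never_more_fish_without_predation(toy3_nopred):
    """With no predation links, raising one gear's effort cannot raise
    any species' end-of-run numbers (no predation-release feedback)."""
    params = toy3_nopred.with_gears(lc.per_species_gears(toy3_nopred))
    state0 = get_N0(params, burn_years=5)
    totals = []
    for e in (0.0, 0.5, 1.0):
        effort = np.zeros((5, params.n_gears))
        effort[:, 1] = e
        out = run(params, state0, years=5, effort=effort)
        totals.append(out.N[-1].sum(axis=0))
    for lo, hi in zip(totals[1:], totals[:-1]):
        assert np.all(lo <= hi + 1e-9)


# ----------------------------------------------------------------------
# initialisation


def test_get_n0_zero_burn_is_the_raw_seed(toy3):
    np.testing.assert_array_equal(
        get_N0(toy3, burn_years=0).N, seed_state(toy3).N
    )
    with pytest.raises(ValueError):
        get_N0(toy3, burn_years=-1)


def test_burn_in_reaches_quasi_equilibrium(community):
    """A second 10-year unfished burn changes every species' SSB < 1%."""
    first = get_N0(community, burn_years=10)
    second = run(community, first, years=10)
    ssb1 = (first.N * community.w * community.mature).sum(axis=0)
    ssb2 = (second.N[-1] * community.w * community.mature).sum(axis=0)
    assert np.all(ssb1 > 0)
    assert np.max(np.abs(ssb2 / ssb1 - 1.0)) < 0.01
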