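"""Passage-time machinery: closed forms, iteration, refuge algebra, solvers."""

import math

import numpy as np
import pytest

from btrefuge import (
    NEVER,
    GenotypeFitness,
    HDRScenario,
    PassageQuery,
    expected_pace,
    lambda_factor,
    min_refuge_for_passage,
    passage_time,
    passage_time_basic_hdr,
    passage_time_epsilon,
    passage_time_general,
    passage_time_iterative,
    refuge_threshold,
)


def odds(q):
    return q / (1 - q)


def scenario_for(omega, f=0.0, h=0.0, g=0.0, u_rr=1.0, v_rr=1.0):
    return HDRScenario(
        omega=omega, f_assort=f,
        fitness=GenotypeFitness.from_dominance(h=h, g=g, u_rr=u_rr, v_rr=v_rr),
    )


# ---------------------------------------------------------------- closed forms

def test_basic_hdr_formula_direct_arithmetic():
    q0, qk, omega = 0.01, 0.02, 0.5
    y0, yk = odds(q0), odds(qk)
    expected = (0.5 / 0.5) * (1 / y0 - 1 / yk + math.log(yk / y0))
    assert passage_time_basic_hdr(q0, qk, omega) == pytest.approx(expected, rel=1e-14)


def test_basic_hdr_no_selection_never_reaches():
    assert passage_time_basic_hdr(1e-4, 0.1, 0.0) == NEVER


def test_basic_hdr_matches_iteration_at_low_odds():
    """Continuous approximation within 2% of the exact iterate for y0 < 0.01."""
    for omega, q0, qk in [(0.8, 1e-4, 0.1), (0.5, 1e-3, 0.05), (0.7, 1e-4, 0.02)]:
        closed = passage_time_basic_hdr(q0, qk, omega)
        exact = passage_time_iterative(q0, qk, scenario_for(omega))
        assert closed == pytest.approx(exact, rel=0.02)


def test_epsilon_form_continuous_with_basic_at_tiny_epsilon():
    base = passage_time_basic_hdr(1e-4, 0.1, 0.8)
    near = passage_time_epsilon(1e-4, 0.1, 0.8, f_assort=0.0, h=1e-8)
    assert near == pytest.approx(base, rel=1e-3)
    assert passage_time_epsilon(1e-4, 0.1, 0.8) == base  # exact zero delegates


def test_epsilon_form_reproduces_collapse_anchor():
    """F=h=0.025 at omega=0.8 collapses ~2500 generations to ~30."""
    t_eps = passage_time_epsilon(1e-4, 0.1, 0.8, 0.025, 0.025)
    assert t_eps == pytest.approx(30.0, rel=0.10)
    assert passage_time_basic_hdr(1e-4, 0.1, 0.8) / t_eps > 80


def test_epsilon_form_tracks_iteration_at_moderate_pace():
    """Within 10% of the exact iterate when the rare-allele pace is small.

    The continuous form undershoots the discrete recursion by roughly
    (1/2)*ln(yk/y0) generations, so the 10% band is asserted on its
    validity domain: pace omega*eps/(1-omega) <= 0.05, q0 << qk.
    """
    rng = np.random.default_rng(20)
    checked = 0
    while checked < 60:
        omega = rng.uniform(0.5, 0.85)
        eps = 10 ** rng.uniform(-2.7, -1.3)
        if omega * eps / (1 - omega) > 0.05:
            continue
        qk = rng.uniform(0.02, 0.1)
        q0 = qk * 10 ** rng.uniform(-3, -1.7)
        checked += 1
        closed = passage_time_epsilon(q0, qk, omega, 0.0, eps)
        exact = passage_time_iterative(q0, qk, scenario_for(omega, h=eps))
        assert closed == pytest.approx(exact, rel=0.10)


def test_general_form_reduces_when_chi_zero():
    sc = scenario_for(0.8, h=0.05)  # no cost => chi irrelevant
    expected = (0.2 / (0.8 * 0.05 * 1.0)) * math.log(odds(0.1) / odds(1e-3))
    assert passage_time_general(1e-3, 0.1, sc) == pytest.approx(expected, rel=1e-12)


def test_general_form_high_dose_worked_example():
    """h=0.05 with a recessive-ish 25% cost: ~40 generations at 26% refuge."""
    sc = scenario_for(1 - 0.26, h=0.05, g=0.1, u_rr=0.75)
    assert passage_time_general(0.001, 0.1, sc) == pytest.approx(40.0, rel=0.02)


def test_general_form_never_when_denominator_nonpositive():
    sc = scenario_for(0.05, h=0.01, g=0.5, u_rr=0.6)  # 95% refuge, strong cost
    assert passage_time_general(1e-4, 0.1, sc) == NEVER


def test_general_form_upper_bounds_iteration_at_moderate_pace():
    """T^k* freezes the pace at its rare-allele value, hence overestimates
    the passage time; verified for rare-allele pace <= 0.08."""
    rng = np.random.default_rng(21)
    checked = 0
    while checked < 60:
        omega = rng.uniform(0.4, 0.85)
        h = 10 ** rng.uniform(-3, -1.3)
        f = 10 ** rng.uniform(-3, -1.6)
        g = rng.uniform(0.0, 0.4)
        u_rr = rng.uniform(0.6, 1.0)
        v_rr = rng.uniform(0.6, 1.0)
        sc = scenario_for(omega, f=f, h=h, g=g, u_rr=u_rr, v_rr=v_rr)
        pace = expected_pace(sc)
        if not 0.0 < pace <= 0.08:
            continue
        checked += 1
        t_star = passage_time_general(1e-4, 0.1, sc)
        t_exact = passage_time_iterative(1e-4, 0.1, sc)
        assert t_star >= t_exact


# ------------------------------------------------------------------ iteration

def test_iterative_one_step_crossing():
    sc = scenario_for(0.9, h=0.5)  # strong selection
    assert passage_time_iterative(0.0999, 0.1, sc) == 1.0


def test_iterative_counts_generations_below_threshold(basic_hdr):
    t = passage_time_iterative(1e-4, 0.1, basic_hdr)
    # every generation strictly below the threshold is counted
    from btrefuge import iterate_trajectory
    traj = iterate_trajectory(1e-4, basic_hdr, qk=0.1, max_generations=10_000)
    assert t == len(traj) - 1
    assert traj.q_series[-1] >= 0.1 > traj.q_series[-2]


def test_iterative_never_reaches_in_protected_regime():
    sc = scenario_for(0.05, h=0.01, g=0.5, u_rr=0.6)
    assert passage_time_iterative(1e-4, 0.1, sc) == NEVER


def test_iterative_rejects_bad_bounds():
    with pytest.raises(ValueError):
        passage_time_iterative(0.2, 0.1, HDRScenario(omega=0.8))


def test_passage_query_dispatch(epsilon_scenario):
    for method in ("iterative", "basic_hdr", "epsilon", "general"):
        t = passage_time(PassageQuery(scenario=epsilon_scenario, q0=1e-4, qk=0.1,
                                      method=method))
        assert t > 0


# ------------------------------------------------------------- monotonicities

def test_passage_time_monotonicity_grids():
    """More refuge -> longer; larger eps -> shorter; larger q0 -> shorter;
    larger qk -> longer. Checked on the exact iterate and the closed forms."""
    refuges = [0.1, 0.2, 0.3, 0.4]
    ts = [passage_time_iterative(1e-4, 0.1, scenario_for(1 - r, h=0.02)) for r in refuges]
    assert ts == sorted(ts) and len(set(ts)) == len(ts)

    epss = [0.01, 0.02, 0.05, 0.1]
    ts = [passage_time_epsilon(1e-4, 0.1, 0.8, 0.0, e) for e in epss]
    assert ts == sorted(ts, reverse=True)

    q0s = [1e-5, 1e-4, 1e-3, 1e-2]
    ts = [passage_time_epsilon(q, 0.1, 0.8, 0.0, 0.02) for q in q0s]
    assert ts == sorted(ts, reverse=True)

    qks = [0.02, 0.05, 0.1, 0.2]
    ts = [passage_time_basic_hdr(1e-4, qk, 0.8) for qk in qks]
    assert ts == sorted(ts)


def test_refuge_odds_prefactor_linearity():
    """All closed forms scale exactly with the refuge odds (1-omega)/omega:
    5% vs 20% refuge changes passage time by the factor 0.25/(0.05/0.95)."""
    ratio = (0.20 / 0.80) / (0.05 / 0.95)
    t20 = passage_time_epsilon(1e-4, 0.1, 0.80, 0.0, 0.05)
    t05 = passage_time_epsilon(1e-4, 0.1, 0.95, 0.0, 0.05)
    assert t20 / t05 == pytest.approx(ratio, rel=1e-12)
    assert ratio == pytest.approx(4.75, abs=0.01)


# -------------------------------------------------------------- refuge algebra

@pytest.mark.parametrize(
    "eps, chi, v_rr, u_rr, expected",
    [
        (0.05, 0.05, 1.0, 0.0, 0.5),   # symmetric terms
        (0.05, 9 * 0.05, 1.0, 0.0, 0.1),
        (0.05, 4 * 0.05, 1.0, 0.0, 0.2),
        (0.02, 0.3, 0.9, 0.75, 0.018 / (0.018 + 0.075)),
    ],
)
def test_refuge_threshold_values(eps, chi, v_rr, u_rr, expected):
    assert refuge_threshold(eps, chi, v_rr, u_rr) == pytest.approx(expected, rel=1e-12)


def test_refuge_threshold_undefined_when_both_terms_zero():
    with pytest.raises(ValueError):
        refuge_threshold(0.0, 0.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        refuge_threshold(0.0, 0.5, 1.0, 1.0)  # chi*(1-u_rr)=0 too


def test_threshold_sign_consistency():
    """Just above the protective refuge fraction resistance declines as q->0;
    just below, it grows."""
    cases = [
        dict(f=0.02, h=0.03, g=0.3, u_rr=0.7, v_rr=0.9),
        dict(f=0.0, h=0.05, g=0.5, u_rr=0.5, v_rr=0.6),
    ]
    for c in cases:
        fit = GenotypeFitness.from_dominance(h=c["h"], g=c["g"],
                                             u_rr=c["u_rr"], v_rr=c["v_rr"])
        probe = HDRScenario(omega=0.5, f_assort=c["f"], fitness=fit)
        thr = refuge_threshold(probe.epsilon, probe.chi, c["v_rr"], c["u_rr"])
        above = HDRScenario(omega=1 - 1.01 * thr, f_assort=c["f"], fitness=fit)
        below = HDRScenario(omega=1 - 0.99 * thr, f_assort=c["f"], fitness=fit)
        assert lambda_factor(1e-8, above) < 0
        assert lambda_factor(1e-8, below) > 0


# ------------------------------------------------------------ minimal refuge

def test_min_refuge_solver_bracketing():
    fit = GenotypeFitness.from_dominance(h=0.05, g=0.1, u_rr=0.75)
    refuge = min_refuge_for_passage(40, fit, 0.0, 0.001, 0.1, method="general")
    delta = 1e-4
    lo = scenario_for(1 - (refuge - delta), h=0.05, g=0.1, u_rr=0.75)
    hi = scenario_for(1 - (refuge + delta), h=0.05, g=0.1, u_rr=0.75)
    assert passage_time_general(0.001, 0.1, lo) < 40 <= passage_time_general(0.001, 0.1, hi)


def test_min_refuge_monotone_in_target():
    fit = GenotypeFitness.from_dominance(h=0.05, g=0.1, u_rr=0.75)
    refs = [min_refuge_for_passage(t, fit, 0.0, 0.001, 0.1, method="general")
            for t in (10, 20, 40, 60)]
    assert refs == sorted(refs)


def test_min_refuge_tiny_target_needs_almost_none():
    fit = GenotypeFitness.from_dominance(h=0.05)
    assert min_refuge_for_passage(1e-6, fit, 0.0, 0.001, 0.1) == pytest.approx(0.0, abs=1e-5)


def test_min_refuge_rejects_nonpositive_target():
    fit = GenotypeFitness.from_dominance(h=0.05)
    with pytest.raises(ValueError):
        min_refuge_for_passage(0, fit, 0.0, 0.001, 0.1)


def test_min_refuge_iterative_agrees_with_general_direction():
    """The iterate runs a touch slower than the closed form, so it needs no
    more refuge than the general-form answer plus a small margin."""
    fit = GenotypeFitness.from_dominance(h=0.05, g=0.1, u_rr=0.75)
    r_gen = min_refuge_for_passage(40, fit, 0.0, 0.001, 0.1, method="general")
    r_it = min_refuge_for_passage(40, fit, 0.0, 0.001, 0.1, method="iterative")
    assert r_it <= r_gen + 0.05
    assert r_gen > 0.25
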