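"""Passage time to a critical resistance-allele frequency.

The passage time ``T^k`` is the number of generations the resistance
allele spends below a critical frequency ``q_k`` (0.1 by default), a
proxy for the time until the Bt crop loses containment of the pest.  It
can be computed exactly by iterating the discrete recursion, or
approximated in closed form by integrating the continuous analogue
``dy/dt = Lambda(y) * y`` on the odds scale ``y = q/(1-q)``.

Three closed forms are provided, from most to least restrictive:

* :func:`passage_time_basic_hdr` — the idealised model (recessive
  resistance, random mating, no cost, complete resistance, lethal Bt for
  susceptibles), where ``Lambda = [omega/(1-omega)] * q`` and

  ``T = [(1-omega)/omega] * [1/y0 - 1/yk + ln(yk/y0)]``.

* :func:`passage_time_epsilon` — deviation ``epsilon = F + h - F*h > 0``
  with no cost and complete resistance.  Integrating
  ``dy/dt = [omega/(1-omega)] * y*(y+epsilon)/(1+y)`` by partial
  fractions gives

  ``T = [(1-omega)/omega] * (1/epsilon)
        * [ln(yk/y0) + (epsilon-1) * ln((epsilon+yk)/(epsilon+y0))]``.

  The ``1/y0`` term of the basic model disappears: even a small epsilon
  collapses passage times by orders of magnitude when ``epsilon >> q0``.

* :func:`passage_time_general` — arbitrary cost and incomplete
  resistance, small-``y0`` limit (reference survivals ``u_ss = 1``,
  ``v_ss = 0``):

  ``T = (1-omega) / [omega*eps*v_rr - (1-omega)*chi*(1-u_rr)] * ln(yk/y0)``.

  This freezes the pace at its rare-allele value, so it is an upper
  bound on the true (iterated) passage time; it is a good estimate
  whenever it is short (below ~100 generations).

A management-side inversion is also provided: the minimal refuge
fraction guaranteeing that resistance never increases
(:func:`refuge_threshold`), and the minimal refuge achieving a target
passage time (:func:`min_refuge_for_passage`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

from .selection import GenotypeFitness, HDRScenario, lambda_factor, step

__all__ = [
    "NEVER",
    "PassageQuery",
    "passage_time_iterative",
    "passage_time_basic_hdr",
    "passage_time_epsilon",
    "passage_time_general",
    "passage_time",
    "refuge_threshold",
    "min_refuge_for_passage",
]

#: Distinguished result meaning the threshold is never reached (a desired
#: management regime, not an error).
NEVER = math.inf

PassageMethod = Literal["iterative", "basic_hdr", "epsilon", "general"]

# epsilon below this is numerically indistinguishable from the basic model
_EPS_TINY = 1e-12


def _odds(q: float) -> float:
    return q / (1.0 - q)


def _check_bounds(q0: float, qk: float) -> tuple[float, float]:
    q0, qk = float(q0), float(qk)
    if not (0.0 < q0 < qk < 1.0):
        raise ValueError(f"require 0 < q0 < qk < 1, got q0={q0!r}, qk={qk!r}")
    return q0, qk


@dataclass(frozen=True)
class PassageQuery:
    """A passage-time question: scenario, start, threshold, method."""

    scenario: HDRScenario
    q0: float
    qk: float = 0.1
    method: PassageMethod = "iterative"

    def __post_init__(self) -> None:
        _check_bounds(self.q0, self.qk)


def passage_time_iterative(
    q0: float,
    qk: float,
    scenario: HDRScenario,
    *,
    max_generations: int = 1_000_000,
) -> float:
    """Exact passage time by iterating the discrete recursion.

    Returns the integer count of generations with ``q < qk`` (the index of
    the first generation at or above the threshold).  Returns :data:`NEVER`
    when the trajectory is non-increasing or stalls below the threshold
    (e.g. refuge above the protective threshold, or an interior
    equilibrium): that regime is a management success, not an error.
    """
    q0, qk = _check_bounds(q0, qk)
    q = q0
    for t in range(max_generations + 1):
        if q >= qk:
            return float(t)
        q_next = step(q, scenario)
        if q_next <= q or (q_next - q) < 1e-16 * q:
            return NEVER
        q = q_next
    return NEVER


def passage_time_basic_hdr(q0: float, qk: float, omega: float) -> float:
    """Closed-form passage time for the idealised high-dose/refuge model.

    Assumes recessive resistance and random mating (``epsilon = 0``), no
    fitness cost, complete resistance and a lethal Bt crop for SS and RS.
    ``omega = 0`` (no Bt crop, hence no selection) returns :data:`NEVER`.
    """
    q0, qk = _check_bounds(q0, qk)
    if not (0.0 <= omega <= 1.0):
        raise ValueError(f"omega must lie in [0, 1], got {omega!r}")
    if omega == 0.0:
        return NEVER
    y0, yk = _odds(q0), _odds(qk)
    return ((1.0 - omega) / omega) * (1.0 / y0 - 1.0 / yk + math.log(yk / y0))


def passage_time_epsilon(
    q0: float,
    qk: float,
    omega: float,
    f_assort: float = 0.0,
    h: float = 0.0,
) -> float:
    """Closed-form passage time under deviation ``epsilon = F + h - F*h``.

    Assumes no fitness cost and complete resistance.  Exact integral of
    the continuous approximation (partial fractions on
    ``(1+y) / (y*(y+epsilon))``), continuous with the basic model as
    ``epsilon -> 0``; that limit (and exact zero) delegates to
    :func:`passage_time_basic_hdr`.
    """
    q0, qk = _check_bounds(q0, qk)
    eps = f_assort + h - f_assort * h
    if not (0.0 <= eps <= 1.0):
        raise ValueError(f"epsilon must lie in [0, 1], got {eps!r}")
    if eps < _EPS_TINY:
        return passage_time_basic_hdr(q0, qk, omega)
    if omega == 0.0:
        return NEVER
    y0, yk = _odds(q0), _odds(qk)
    bracket = math.log(yk / y0) + (eps - 1.0) * math.log((eps + yk) / (eps + y0))
    return ((1.0 - omega) / omega) * bracket / eps


def passage_time_general(q0: float, qk: float, scenario: HDRScenario) -> float:
    """Small-``y0`` closed-form passage time for the general model.

    ``T = (1-omega) / [omega*eps*v_rr - (1-omega)*chi*(1-u_rr)] * ln(yk/y0)``
    with reference survivals ``u_ss = 1`` and ``v_ss = 0``.  The
    denominator is the rare-allele pace of resistance evolution; when it
    is non-positive the resistance allele does not increase and
    :data:`NEVER` is returned.  Because the pace only accelerates as ``q``
    grows, the value is an upper bound on the iterated passage time.
    """
    q0, qk = _check_bounds(q0, qk)
    fit = scenario.fitness
    denom = (
        scenario.omega * scenario.epsilon * fit.v_rr
        - (1.0 - scenario.omega) * scenario.chi * (1.0 - fit.u_rr)
    )
    if denom <= 0.0:
        return NEVER
    return (1.0 - scenario.omega) / denom * math.log(_odds(qk) / _odds(q0))


def passage_time(query: PassageQuery, *, max_generations: int = 1_000_000) -> float:
    """Dispatch a :class:`PassageQuery` to the requested method."""
    sc = query.scenario
    if query.method == "iterative":
        return passage_time_iterative(
            query.q0, query.qk, sc, max_generations=max_generations
        )
    if query.method == "basic_hdr":
        return passage_time_basic_hdr(query.q0, query.qk, sc.omega)
    if query.method == "epsilon":
        return passage_time_epsilon(
            query.q0, query.qk, sc.omega, sc.f_assort, sc.fitness.h
        )
    if query.method == "general":
        return passage_time_general(query.q0, query.qk, sc)
    raise ValueError(f"unknown passage-time method {query.method!r}")


def refuge_threshold(
    epsilon: float, chi: float, v_rr: float, u_rr: float
) -> float:
    """Minimal refuge fraction preventing any increase of resistance.

    In the rare-allele limit the odds growth rate changes sign at the
    refuge fraction ``eps*v_rr / (eps*v_rr + chi*(1 - u_rr))``: strictly
    more refuge than this makes resistance decline.  Requires at least one
    of the Bt-side deviation term ``eps*v_rr`` and the refuge-side cost
    term ``chi*(1 - u_rr)`` to be positive, otherwise the threshold is
    undefined (selection vanishes as ``q -> 0``).
    """
    bt_term = epsilon * v_rr
    cost_term = chi * (1.0 - u_rr)
    if bt_term < 0 or cost_term < 0:
        raise ValueError("epsilon*v_rr and chi*(1-u_rr) must be non-negative")
    if bt_term + cost_term == 0.0:
        raise ValueError(
            "refuge threshold undefined: both the deviation term eps*v_rr "
            "and the cost term chi*(1-u_rr) are zero"
        )
    return bt_term / (bt_term + cost_term)


def min_refuge_for_passage(
    target_generations: float,
    fitness: GenotypeFitness,
    f_assort: float,
    q0: float,
    qk: float,
    *,
    method: PassageMethod = "general",
    tol: float = 1e-6,
    max_generations: int = 1_000_000,
) -> Optional[float]:
    """Smallest refuge fraction whose passage time reaches the target.

    Passage time increases monotonically with refuge, so the minimal
    refuge is found by bisection on ``1 - omega`` over ``[1e-6, 1-1e-6]``
    to absolute tolerance ``tol``.  Returns ``None`` when even a refuge
    fraction of ``1 - 1e-6`` cannot achieve the target (unreachable).
    """
    if target_generations <= 0:
        raise ValueError("target_generations must be positive")
    _check_bounds(q0, qk)

    def t_of(refuge: float) -> float:
        sc = HDRScenario(omega=1.0 - refuge, f_assort=f_assort, fitness=fitness)
        return passage_time(
            PassageQuery(scenario=sc, q0=q0, qk=qk, method=method),
            max_generations=max_generations,
        )

    lo, hi = 1e-6, 1.0 - 1e-6
    if t_of(hi) < target_generations:
        return None
    if t_of(lo) >= target_generations:
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if t_of(mid) >= target_generations:
            hi = mid
        else:
            lo = mid
    return hi
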