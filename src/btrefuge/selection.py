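"""Single-locus viability selection across a Bt/refuge crop mosaic.

The model tracks a biallelic resistance locus in an infinite, discretely
reproducing pest population.  A fraction ``omega`` of the host-plant
landscape expresses a Bt toxin; the remaining fraction ``1 - omega`` is
toxin-free refuge.  Each genotype has a survival probability on each crop
type, and larvae are assumed to be distributed over crop types at random,
so the landscape-level fitness of a genotype is the ``omega``-weighted
mean of its two survivals.

Departures from Hardy-Weinberg genotype proportions caused by assortative
mating (mating to type, or limited pre-mating dispersal between Bt and
refuge blocks) are captured by a fixation-index coefficient ``F`` applied
afresh every generation: the frequency of resistant homozygotes is
``q**2 + p*q*F`` rather than ``q**2``, and heterozygotes are depleted by
the factor ``1 - F``.

The generation cycle is: zygotes at the F-adjusted genotype proportions
-> viability selection by the landscape-weighted fitnesses -> allele
frequencies among the survivors become the next generation's ``q``.  The
model is deterministic (no drift, no mutation): the whole dynamics reduce
to an exact one-dimensional recursion in ``q``, which this module
implements and which serves as the brute-force oracle for every
closed-form approximation built on top of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "FIXATION_CEIL",
    "FIXATION_FLOOR",
    "ExtinctionError",
    "GenotypeFitness",
    "HDRScenario",
    "AlleleState",
    "Trajectory",
    "genotype_frequencies",
    "landscape_fitness",
    "average_allelic_fitness",
    "mean_fitness",
    "lambda_factor",
    "step",
    "iterate_trajectory",
]

#: q at or above this value is treated as fixation of the resistance allele.
FIXATION_CEIL = 1.0 - 1e-12
#: q at or below this value is treated as loss of the resistance allele.
FIXATION_FLOOR = 1e-300


class ExtinctionError(RuntimeError):
    """Mean fitness is exactly zero: every genotype dies and the allele
    frequency of the next generation is undefined."""


def _check_unit(name: str, value: float, *, closed: bool = True) -> float:
    value = float(value)
    if not math.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class GenotypeFitness:
    """Survival probabilities of the three genotypes on each crop type.

    ``u_*`` are survivals on refuge (non-Bt) plants, ``v_*`` on Bt plants.
    The default table is the idealised high-dose/refuge reference: fully
    susceptible SS/RS on Bt plants, complete resistance of RR, no fitness
    cost on refuge.

    Parameters
    ----------
    u_ss, u_rs, u_rr :
        Refuge survival of SS, RS, RR.  A fitness cost of resistance means
        ``u_ss > u_rr``.
    v_ss, v_rs, v_rr :
        Bt-crop survival of SS, RS, RR.  Incomplete resistance means
        ``v_rr`` below the refuge survival of susceptibles.
    """

    u_ss: float = 1.0
    u_rs: float = 1.0
    u_rr: float = 1.0
    v_ss: float = 0.0
    v_rs: float = 0.0
    v_rr: float = 1.0

    def __post_init__(self) -> None:
        for name in ("u_ss", "u_rs", "u_rr", "v_ss", "v_rs", "v_rr"):
            _check_unit(name, getattr(self, name))
        if self.u_ss < self.u_rr:
            raise ValueError(
                "u_ss < u_rr: the fitness cost of resistance on refuge "
                "plants must be non-negative"
            )
        if self.v_rr < self.v_ss:
            raise ValueError(
                "v_rr < v_ss: resistance must not be deleterious on Bt plants"
            )

    @classmethod
    def from_dominance(
        cls,
        h: float = 0.0,
        g: float = 0.0,
        *,
        u_ss: float = 1.0,
        u_rr: float = 1.0,
        v_ss: float = 0.0,
        v_rr: float = 1.0,
    ) -> "GenotypeFitness":
        """Build the six-survival table from the reduced parameterisation.

        ``h`` is the dominance of resistance on Bt plants (0 recessive,
        1 dominant): ``v_rs = v_ss + h*(v_rr - v_ss)``.  ``g`` is the
        dominance of the fitness cost on refuge plants, the fraction of
        the homozygote cost expressed in the heterozygote:
        ``u_rs = u_ss - g*(u_ss - u_rr)``, so ``g = 0`` means a fully
        recessive cost (RS pays none of it) and ``g = 1`` a dominant one.
        This is the convention under which the composite refuge-side
        deviation works out to ``chi = F + g - F*g``.
        """
        h = _check_unit("h", h)
        g = _check_unit("g", g)
        return cls(
            u_ss=u_ss,
            u_rs=u_ss - g * (u_ss - u_rr),
            u_rr=u_rr,
            v_ss=v_ss,
            v_rs=v_ss + h * (v_rr - v_ss),
            v_rr=v_rr,
        )

    @property
    def h(self) -> float:
        """Dominance of resistance on Bt plants implied by the table
        (0 when RR and SS survive equally, so the interpolation is moot)."""
        span = self.v_rr - self.v_ss
        return (self.v_rs - self.v_ss) / span if span > 0 else 0.0

    @property
    def g(self) -> float:
        """Dominance of the refuge fitness cost implied by the table."""
        span = self.u_ss - self.u_rr
        return (self.u_ss - self.u_rs) / span if span > 0 else 0.0

    @property
    def cost(self) -> float:
        """Fitness cost of resistance on refuge plants, ``u_ss - u_rr``."""
        return self.u_ss - self.u_rr


@dataclass(frozen=True)
class HDRScenario:
    """A full high-dose/refuge landscape: crop split, mating system, fitnesses.

    Parameters
    ----------
    omega :
        Fraction of the landscape planted to the Bt crop, in ``[0, 1]``.
        ``omega == 1`` (no refuge at all) is accepted so that the textbook
        pure-viability-selection limit is expressible; :attr:`is_pure_bt`
        flags it.
    f_assort :
        Assortative-mating / fixation-index coefficient ``F``.
    fitness :
        The genotype survival table.

    Two composite deviation parameters are derived: ``epsilon = F + h - F*h``
    summarises everything that lets resistance leak through the Bt crop
    (heterozygote survival and homozygote excess), while ``chi = F + g - F*g``
    summarises how effectively the refuge fitness cost is expressed.
    """

    omega: float
    f_assort: float = 0.0
    fitness: GenotypeFitness = field(default_factory=GenotypeFitness)

    def __post_init__(self) -> None:
        _check_unit("omega", self.omega)
        _check_unit("f_assort", self.f_assort)

    @property
    def is_pure_bt(self) -> bool:
        return self.omega >= 1.0

    @property
    def refuge(self) -> float:
        """Refuge fraction ``1 - omega``."""
        return 1.0 - self.omega

    @property
    def epsilon(self) -> float:
        """Composite Bt-side deviation ``F + h - F*h``; 0 only for strictly
        recessive resistance under random mating."""
        f, h = self.f_assort, self.fitness.h
        return f + h - f * h

    @property
    def chi(self) -> float:
        """Composite refuge-side cost expression ``F + g - F*g``."""
        f, g = self.f_assort, self.fitness.g
        return f + g - f * g


@dataclass(frozen=True)
class AlleleState:
    """Resistance-allele frequency with its odds transform.

    ``y = q / (1 - q)`` linearises the low-frequency growth equations, so
    both scales are exposed.  Only strictly polymorphic states (0 < q < 1)
    are representable; fixation is handled by the iteration machinery.
    """

    q: float

    def __post_init__(self) -> None:
        q = float(self.q)
        if not (0.0 < q < 1.0):
            raise ValueError(f"allele frequency q must lie in (0, 1), got {q!r}")

    @property
    def p(self) -> float:
        return 1.0 - self.q

    @property
    def y(self) -> float:
        return self.q / (1.0 - self.q)

    @classmethod
    def from_odds(cls, y: float) -> "AlleleState":
        if y <= 0:
            raise ValueError("odds y must be positive")
        return cls(y / (1.0 + y))


def _q_of(state: Union[float, AlleleState]) -> float:
    return state.q if isinstance(state, AlleleState) else float(state)


def genotype_frequencies(
    state: Union[float, AlleleState], f_assort: float
) -> tuple[float, float, float]:
    """Zygote genotype frequencies (RR, RS, SS) under partial assortment.

    With fixation index ``F`` the proportions are ``q**2 + p*q*F``,
    ``2*p*q*(1 - F)`` and ``p**2 + p*q*F``; ``F = 0`` recovers
    Hardy-Weinberg and ``F = 1`` leaves only homozygotes at the allele
    frequencies.
    """
    q = _q_of(state)
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q must lie in [0, 1], got {q!r}")
    f = _check_unit("f_assort", f_assort)
    p = 1.0 - q
    return (q * q + p * q * f, 2.0 * p * q * (1.0 - f), p * p + p * q * f)


def landscape_fitness(
    fitness: GenotypeFitness, omega: float
) -> tuple[float, float, float]:
    """Landscape-weighted genotype fitnesses (W_RR, W_RS, W_SS).

    Each is the ``omega``-weighted mean of the genotype's Bt and refuge
    survival, which assumes larvae land on crop types at random.
    """
    w = _check_unit("omega", omega)
    r = 1.0 - w
    return (
        r * fitness.u_rr + w * fitness.v_rr,
        r * fitness.u_rs + w * fitness.v_rs,
        r * fitness.u_ss + w * fitness.v_ss,
    )


def average_allelic_fitness(
    state: Union[float, AlleleState], scenario: HDRScenario
) -> tuple[float, float]:
    """Landscape-weighted average allelic fitnesses ``(W~_R, W~_S)``.

    On each crop type the average fitness of an allele is the weighted mean
    of the fitnesses of the genotypes it finds itself in, with the weights
    set by the F-adjusted genotype proportions: an R allele sits in an RR
    genotype with probability ``q + p*F`` and in an RS genotype with
    probability ``p*(1 - F)``.  The two crop-type values are then blended
    with weights ``omega`` / ``1 - omega``.  This shortcut is exactly
    equivalent to full genotype bookkeeping (see the test suite's oracle).
    """
    q = _q_of(state)
    p = 1.0 - q
    f = scenario.f_assort
    fit = scenario.fitness
    u_s = (p + q * f) * fit.u_ss + q * (1.0 - f) * fit.u_rs
    u_r = (q + p * f) * fit.u_rr + p * (1.0 - f) * fit.u_rs
    v_s = (p + q * f) * fit.v_ss + q * (1.0 - f) * fit.v_rs
    v_r = (q + p * f) * fit.v_rr + p * (1.0 - f) * fit.v_rs
    w, r = scenario.omega, 1.0 - scenario.omega
    return (r * u_r + w * v_r, r * u_s + w * v_s)


def mean_fitness(state: Union[float, AlleleState], scenario: HDRScenario) -> float:
    """Population mean fitness ``W_bar = q*W~_R + p*W~_S``."""
    q = _q_of(state)
    w_r, w_s = average_allelic_fitness(q, scenario)
    return q * w_r + (1.0 - q) * w_s


def lambda_factor(state: Union[float, AlleleState], scenario: HDRScenario) -> float:
    """Per-generation relative growth rate of the odds ``y = q/p``.

    ``Lambda = W~_R / W~_S - 1`` so that ``delta_y = Lambda * y`` exactly.
    Positive values mean resistance is spreading.  In the idealised
    high-dose/refuge limit (recessive resistance, random mating, no cost,
    complete resistance, lethal Bt crop for susceptibles) this reduces to
    ``q * omega / (1 - omega)``.

    Returns ``inf`` when every copy of the susceptible allele dies
    (``W~_S == 0``): the caller decides how to treat divergent growth.
    """
    q = _q_of(state)
    w_r, w_s = average_allelic_fitness(q, scenario)
    if w_s == 0.0:
        return math.inf
    return w_r / w_s - 1.0


def step(state: Union[float, AlleleState], scenario: HDRScenario) -> float:
    """Advance the exact recursion by one generation and return ``q'``.

    ``q' = q * W~_R / W_bar``; the sign of the change equals the sign of
    ``W~_R - W~_S``.  The result is clamped to the open interval
    ``[FIXATION_FLOOR, FIXATION_CEIL]`` so the odds transform stays finite;
    :func:`iterate_trajectory` turns a clamped value into a termination
    event.

    Raises
    ------
    ExtinctionError
        If mean fitness is zero (all genotypes die).
    """
    q = _q_of(state)
    w_r, w_s = average_allelic_fitness(q, scenario)
    w_bar = q * w_r + (1.0 - q) * w_s
    if w_bar <= 0.0:
        raise ExtinctionError(
            "mean fitness is zero: no genotype survives under this scenario"
        )
    q_next = q * w_r / w_bar
    return min(max(q_next, FIXATION_FLOOR), FIXATION_CEIL)


@dataclass(frozen=True)
class Trajectory:
    """A per-generation allele-frequency series from the exact recursion."""

    q_series: np.ndarray
    terminated_reason: str  # reached_threshold | max_generations | fixation_floor

    @property
    def generations(self) -> np.ndarray:
        return np.arange(len(self.q_series))

    @property
    def q_final(self) -> float:
        return float(self.q_series[-1])

    def __len__(self) -> int:
        return len(self.q_series)


def iterate_trajectory(
    q0: float,
    scenario: HDRScenario,
    *,
    qk: Optional[float] = None,
    max_generations: int = 10_000,
) -> Trajectory:
    """Iterate the exact recursion from ``q0``, recording every generation.

    Stops at the first generation with ``q >= qk`` (``reached_threshold``),
    when the frequency leaves the polymorphic interval (``fixation_floor``),
    or after ``max_generations`` steps (``max_generations``).
    """
    q0 = float(q0)
    if not (0.0 < q0 < 1.0):
        raise ValueError(f"q0 must lie in (0, 1), got {q0!r}")
    series = [q0]
    reason = None
    while reason is None:
        q = series[-1]
        if qk is not None and q >= qk:
            reason = "reached_threshold"
            break
        if len(series) > max_generations:
            reason = "max_generations"
            break
        q_next = step(q, scenario)
        series.append(q_next)
        if q_next >= FIXATION_CEIL or q_next <= FIXATION_FLOOR:
            reason = "fixation_floor"
    return Trajectory(q_series=np.asarray(series, dtype=float), terminated_reason=reason)
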