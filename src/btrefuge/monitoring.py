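"""Empirical estimators of the pace of resistance evolution.

Field monitoring programs typically yield two allele-frequency
measurements: an initial frequency ``q0`` and a later frequency ``qj``
observed ``Tj`` generations apart.  On the odds scale ``y = q/(1-q)``
the deterministic model predicts near-exponential growth while the
allele is rare, so the log odds-ratio per generation

    ``xi* = ln(yj / y0) / Tj``

is a standardised pace of resistance evolution that needs no knowledge
of the underlying parameters (refuge fraction, dominance, mating
system, fitness cost).  Its model-side counterpart is

    ``xi = [omega*eps*v_rr - (1-omega)*chi*(1-u_rr)] / (1-omega)``,

and the projected passage time to a critical frequency ``qk`` is
``Tk* = ln(yk / y0) / xi*`` — an upper-bound first approximation,
adequate whenever it is short (under ~100 generations).

The module also implements the survey-table workflow: parsing delimited
monitoring records with the field conventions used in published
compilations (censored frequencies written ``>0.1``, bounded elapsed
times written ``<30``, missing initial frequencies assumed at 0.001 and
flagged), and converting per-generation projections to calendar years
via the midpoint of the species' generations-per-year range.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .selection import HDRScenario

__all__ = [
    "ASSUMED_Q0",
    "SurveyRecord",
    "PaceEstimate",
    "pace_xi_star",
    "expected_pace",
    "project_passage",
    "analyze_survey_table",
    "read_survey_table",
    "estimates_to_frame",
]

#: Default initial frequency assumed when a survey reports none.
ASSUMED_Q0 = 0.001

_SURVEY_COLUMNS = ("species", "crop", "toxin", "country", "gen_per_year", "q0", "qj", "Tj")


def _odds(q: float) -> float:
    if not (0.0 < q < 1.0):
        raise ValueError(f"frequency must lie in (0, 1), got {q!r}")
    return q / (1.0 - q)


def pace_xi_star(q0: float, qj: float, t_j: float) -> float:
    """Empirical pace of resistance evolution from two frequency surveys.

    ``xi* = ln(yj / y0) / Tj`` on the odds scale.  A non-positive value
    (``qj <= q0``) is returned as-is with a warning: the allele is not
    spreading, so downstream projections are undefined.
    """
    if t_j <= 0:
        raise ValueError(f"elapsed generations Tj must be positive, got {t_j!r}")
    xi = math.log(_odds(qj) / _odds(q0)) / t_j
    if xi <= 0:
        warnings.warn(
            "observed frequency did not increase (qj <= q0): the pace is "
            "non-positive and projections are undefined",
            stacklevel=2,
        )
    return xi


def expected_pace(scenario: HDRScenario) -> float:
    """Model-side pace of resistance evolution for a parameterised scenario.

    ``xi = [omega*eps*v_rr - (1-omega)*chi*(1-u_rr)] / (1-omega)``, the
    rare-allele odds growth rate of the general model (reference survivals
    ``u_ss = 1``, ``v_ss = 0``).  Multiplying its inverse by
    ``ln(yk/y0)`` reproduces the general closed-form passage time.
    """
    if scenario.is_pure_bt:
        raise ValueError("expected pace is undefined without any refuge (omega = 1)")
    fit = scenario.fitness
    return (
        scenario.omega * scenario.epsilon * fit.v_rr
        - (1.0 - scenario.omega) * scenario.chi * (1.0 - fit.u_rr)
    ) / (1.0 - scenario.omega)


def project_passage(xi_star: float, q0: float, qk: float = 0.1) -> Optional[float]:
    """Projected generations until ``q`` first reaches ``qk``.

    ``Tk* = ln(yk / y0) / xi*``.  Returns ``None`` when the pace is not
    positive (no projection is defined for a non-spreading allele).
    """
    if q0 >= qk:
        raise ValueError(f"require q0 < qk, got q0={q0!r}, qk={qk!r}")
    if xi_star <= 0:
        return None
    return math.log(_odds(qk) / _odds(q0)) / xi_star


@dataclass(frozen=True)
class SurveyRecord:
    """One resistance-monitoring observation.

    ``qj_censored`` marks frequencies reported only as exceeding a bound
    (e.g. ``>0.1``); ``t_j_is_upper_bound`` marks elapsed times reported
    as ``<N`` generations.  ``q0`` is ``None`` when the survey provides no
    initial-frequency estimate.
    """

    species: str
    crop: str
    toxin: str
    country: str
    gen_per_year_low: float
    gen_per_year_high: float
    q0: Optional[float]
    qj: float
    qj_censored: bool
    t_j: float
    t_j_is_upper_bound: bool

    def __post_init__(self) -> None:
        if self.q0 is not None and not (0.0 < self.q0 < 1.0):
            raise ValueError(f"q0 must lie in (0, 1), got {self.q0!r}")
        if not (0.0 < self.qj <= 1.0):
            raise ValueError(f"qj must lie in (0, 1], got {self.qj!r}")
        if self.t_j <= 0:
            raise ValueError(f"Tj must be positive, got {self.t_j!r}")
        if self.gen_per_year_low > self.gen_per_year_high:
            raise ValueError("gen_per_year_low must not exceed gen_per_year_high")

    @property
    def gen_per_year_mid(self) -> float:
        return 0.5 * (self.gen_per_year_low + self.gen_per_year_high)


@dataclass(frozen=True)
class PaceEstimate:
    """Pace and passage-time projection derived from one survey record."""

    record: SurveyRecord
    q0_used: float
    q0_assumed: bool
    xi_star: float
    xi_is_lower_bound: bool
    t_k_star: Optional[float]
    years_to_qk: Optional[float]


def analyze_survey_table(
    records: Sequence[SurveyRecord], qk: float = 0.1
) -> list[PaceEstimate]:
    """Estimate pace and projected passage time for each survey record.

    Censoring rules:

    * missing ``q0`` — assume :data:`ASSUMED_Q0` and flag the estimate;
    * censored ``qj`` (reported only as exceeding its value) — ``xi*`` is
      computed at the bound and reported as a lower bound on the pace
      (a bounded ``Tj`` likewise keeps the estimate a lower bound);
    * any observed ``qj`` at or above ``qk`` — no passage-time projection
      (the threshold was already crossed within the survey window).

    Calendar years use the midpoint of the generations-per-year range.
    """
    out = []
    for rec in records:
        q0_assumed = rec.q0 is None
        q0_used = ASSUMED_Q0 if q0_assumed else rec.q0
        xi = pace_xi_star(q0_used, rec.qj, rec.t_j)
        lower_bound = rec.qj_censored
        if rec.qj_censored or rec.qj >= qk:
            t_k: Optional[float] = None
            years: Optional[float] = None
        else:
            t_k = project_passage(xi, q0_used, qk)
            years = None if t_k is None else t_k / rec.gen_per_year_mid
        out.append(
            PaceEstimate(
                record=rec,
                q0_used=q0_used,
                q0_assumed=q0_assumed,
                xi_star=xi,
                xi_is_lower_bound=lower_bound,
                t_k_star=t_k,
                years_to_qk=years,
            )
        )
    return out


_BOUND_RE = re.compile(r"^\s*([<>])\s*([0-9.eE+-]+)\s*$")


def _parse_bounded(text: str, field: str) -> tuple[float, Optional[str]]:
    """Parse '0.018', '>0.1' or '<30' into (value, bound-direction)."""
    m = _BOUND_RE.match(text)
    if m:
        return float(m.group(2)), m.group(1)
    try:
        return float(text), None
    except ValueError as exc:
        raise ValueError(f"cannot parse {field}={text!r}") from exc


def _parse_gen_range(text: str) -> tuple[float, float]:
    parts = re.split(r"[-–]", text.strip())
    if len(parts) == 1:
        v = float(parts[0])
        return v, v
    if len(parts) == 2:
        return float(parts[0]), float(parts[1])
    raise ValueError(f"cannot parse gen_per_year={text!r}")


def parse_survey_row(row: dict) -> SurveyRecord:
    """Build a :class:`SurveyRecord` from one row of string-valued fields."""
    missing = [c for c in _SURVEY_COLUMNS if c not in row]
    if missing:
        raise ValueError(f"missing columns: {', '.join(missing)}")
    lo, hi = _parse_gen_range(str(row["gen_per_year"]))
    q0_text = str(row["q0"]).strip() if row["q0"] is not None else ""
    if q0_text in ("", "a", "na", "NA", "nan", "None"):
        q0: Optional[float] = None
    else:
        q0 = float(q0_text)
    qj, qj_bound = _parse_bounded(str(row["qj"]), "qj")
    if qj_bound == "<":
        raise ValueError("an upper-bounded qj cannot bound the pace from below")
    tj, tj_bound = _parse_bounded(str(row["Tj"]), "Tj")
    if tj_bound == ">":
        raise ValueError("a lower-bounded Tj cannot bound the pace from below")
    return SurveyRecord(
        species=str(row["species"]),
        crop=str(row["crop"]),
        toxin=str(row["toxin"]),
        country=str(row["country"]),
        gen_per_year_low=lo,
        gen_per_year_high=hi,
        q0=q0,
        qj=qj,
        qj_censored=qj_bound == ">",
        t_j=tj,
        t_j_is_upper_bound=tj_bound == "<",
    )


def read_survey_table(
    path: Union[str, Path], *, sep: str = "\t"
) -> tuple[list[SurveyRecord], list[tuple[int, str]]]:
    """Read a delimited survey table; malformed rows go to a rejects list.

    Returns ``(records, rejects)`` where each reject is a ``(line_number,
    message)`` pair (line numbers count the header as line 1).
    """
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _SURVEY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"survey table lacks columns: {', '.join(missing)}")
    records: list[SurveyRecord] = []
    rejects: list[tuple[int, str]] = []
    for i, row in frame.iterrows():
        line_no = int(i) + 2  # header is line 1
        try:
            records.append(parse_survey_row(row.to_dict()))
        except (ValueError, TypeError) as exc:
            rejects.append((line_no, str(exc)))
    return records, rejects


def estimates_to_frame(estimates: Sequence[PaceEstimate]) -> pd.DataFrame:
    """Flatten pace estimates into a tidy DataFrame for reporting."""
    rows = []
    for est in estimates:
        rec = est.record
        rows.append(
            {
                "species": rec.species,
                "crop": rec.crop,
                "toxin": rec.toxin,
                "country": rec.country,
                "gen_per_year": rec.gen_per_year_mid,
                "q0": est.q0_used,
                "q0_assumed": est.q0_assumed,
                "qj": rec.qj,
                "qj_censored": rec.qj_censored,
                "Tj": rec.t_j,
                "xi_star": est.xi_star,
                "xi_is_lower_bound": est.xi_is_lower_bound,
                "Tk_star": est.t_k_star,
                "years_to_qk": est.years_to_qk,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "crop", "toxin", "country", "gen_per_year", "q0",
            "q0_assumed", "qj", "qj_censored", "Tj", "xi_star",
            "xi_is_lower_bound", "Tk_star", "years_to_qk",
        ],
    )
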