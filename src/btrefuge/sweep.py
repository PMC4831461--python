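"""Parameter sweeps and report serialisation.

A sweep evaluates one output quantity (a passage-time method, the
expected pace, or the protective refuge threshold) over the Cartesian
product of one or more parameter grids laid over a baseline scenario.
Errors in individual cells are recorded in-row so a sweep never dies
half way.  Reports are TSV (default) or JSON with a comment header
carrying the package version, a hash of the generating configuration
and a timestamp; the body is byte-reproducible for identical inputs.
"""

from __future__ import annotations

import hashlib
import io
import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import __version__
from .config import ScenarioConfig, scenario_from_dict
from .monitoring import expected_pace
from .passage import PassageQuery, passage_time, refuge_threshold
from .selection import GenotypeFitness, HDRScenario

__all__ = ["GridSpec", "SweepSpec", "run_sweep", "report", "config_hash"]

_SCENARIO_FIELDS = ("omega", "F", "h", "g", "u_ss", "u_rr", "v_ss", "v_rr", "q0", "qk")

_QUANTITIES = (
    "passage_iterative",
    "passage_basic_hdr",
    "passage_epsilon",
    "passage_general",
    "expected_pace",
    "refuge_threshold",
)


@dataclass(frozen=True)
class GridSpec:
    """One axis of a sweep: evenly spaced values on a linear or log scale."""

    start: float
    stop: float
    count: int
    scale: str = "linear"

    def values(self) -> np.ndarray:
        if self.count < 1:
            raise ValueError("grid count must be >= 1")
        if self.scale == "linear":
            return np.linspace(self.start, self.stop, self.count)
        if self.scale == "log":
            if self.start <= 0 or self.stop <= 0:
                raise ValueError("log grids require positive endpoints")
            return np.geomspace(self.start, self.stop, self.count)
        raise ValueError(f"unknown grid scale {self.scale!r}")


@dataclass(frozen=True)
class SweepSpec:
    """Baseline scenario, grids to vary, and the quantity to evaluate."""

    base: ScenarioConfig
    grids: dict[str, GridSpec]
    quantity: str = "passage_general"

    def __post_init__(self) -> None:
        if not self.grids:
            raise ValueError("sweep needs at least one grid")
        bad = set(self.grids) - set(_SCENARIO_FIELDS)
        if bad:
            raise ValueError(
                f"cannot sweep over {sorted(bad)}; "
                f"valid fields: {', '.join(_SCENARIO_FIELDS)}"
            )
        if self.quantity not in _QUANTITIES:
            raise ValueError(
                f"unknown quantity {self.quantity!r}; "
                f"valid: {', '.join(_QUANTITIES)}"
            )


def _base_dict(cfg: ScenarioConfig) -> dict:
    fit = cfg.scenario.fitness
    return {
        "omega": cfg.scenario.omega,
        "F": cfg.scenario.f_assort,
        "h": fit.h,
        "g": fit.g,
        "u_ss": fit.u_ss,
        "u_rr": fit.u_rr,
        "v_ss": fit.v_ss,
        "v_rr": fit.v_rr,
        "q0": cfg.q0,
        "qk": cfg.qk,
        "max_generations": cfg.max_generations,
    }


def _evaluate(quantity: str, params: dict) -> float:
    fitness = GenotypeFitness.from_dominance(
        h=params["h"], g=params["g"],
        u_ss=params["u_ss"], u_rr=params["u_rr"],
        v_ss=params["v_ss"], v_rr=params["v_rr"],
    )
    scenario = HDRScenario(
        omega=params["omega"], f_assort=params["F"], fitness=fitness
    )
    if quantity == "expected_pace":
        return expected_pace(scenario)
    if quantity == "refuge_threshold":
        return refuge_threshold(
            scenario.epsilon, scenario.chi, fitness.v_rr, fitness.u_rr
        )
    method = quantity.removeprefix("passage_")
    return passage_time(
        PassageQuery(
            scenario=scenario, q0=params["q0"], qk=params["qk"], method=method
        ),
        max_generations=params["max_generations"],
    )


def run_sweep(spec: SweepSpec) -> list[dict]:
    """Evaluate the quantity on the Cartesian product of the grids.

    Row order is deterministic (last grid varies fastest, in insertion
    order of ``spec.grids``).  A failing cell gets ``value=None`` and the
    error message in its ``error`` column; the sweep continues.
    """
    names = list(spec.grids)
    axes = [spec.grids[n].values() for n in names]
    base = _base_dict(spec.base)
    rows: list[dict] = []
    for combo in _cartesian(axes):
        params = dict(base)
        params.update({n: float(v) for n, v in zip(names, combo)})
        row = {n: float(params[n]) for n in names}
        try:
            row["value"] = _evaluate(spec.quantity, params)
            row["error"] = ""
        except Exception as exc:  # cell-local failure, recorded in-row
            row["value"] = None
            row["error"] = str(exc)
        rows.append(row)
    return rows


def _cartesian(axes: Sequence[np.ndarray]):
    if not axes:
        yield ()
        return
    for head in axes[0]:
        for tail in _cartesian(axes[1:]):
            yield (head, *tail)


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if math.isinf(value):
            return "Inf" if value > 0 else "-Inf"
        if math.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def report(
    rows: Sequence[dict],
    fmt: str = "tsv",
    out: Optional[Union[str, Path, io.TextIOBase]] = None,
    *,
    config: Optional[dict] = None,
    timestamp: bool = True,
) -> str:
    """Serialise result rows to TSV or JSON with a provenance header.

    TSV floats carry 6 significant digits; infinite passage times render
    as ``Inf`` and missing values as ``NA``.  JSON keeps full precision so
    that ``json.loads`` round-trips the rows.  The comment header (TSV) /
    metadata object (JSON) records the package version, a hash of the
    generating config and, unless ``timestamp=False``, the UTC time.
    """
    meta = {"version": __version__}
    if config is not None:
        meta["config_hash"] = config_hash(config)
    if timestamp:
        meta["generated"] = datetime.now(timezone.utc).isoformat(timespec="seconds")

    if fmt == "json":
        def _jsonable(v):
            if isinstance(v, float) and (math.isnan(v) or math.isinf(v)):
                return None if math.isnan(v) else ("Inf" if v > 0 else "-Inf")
            return v
        payload = {
            "metadata": meta,
            "rows": [{k: _jsonable(v) for k, v in r.items()} for r in rows],
        }
        text = json.dumps(payload, indent=2) + "\n"
    elif fmt == "tsv":
        lines = [f"# {k}: {v}" for k, v in meta.items()]
        if rows:
            cols = list(rows[0].keys())
            lines.append("\t".join(cols))
            for r in rows:
                lines.append("\t".join(_fmt(r.get(c)) for c in cols))
        text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown report format {fmt!r}")

    if out is not None:
        if isinstance(out, (str, Path)):
            Path(out).write_text(text)
        else:
            out.write(text)
    return text
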