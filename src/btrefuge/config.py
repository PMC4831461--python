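"""Scenario configuration files.

A scenario is a flat JSON object.  Two mutually exclusive fitness
parameterisations are accepted: the reduced form via dominance
coefficients (``h`` for resistance on Bt plants, ``g`` for the cost on
refuge plants) or the explicit heterozygote survivals (``v_rs``,
``u_rs``).  Remaining keys: ``omega``, ``F``, the homozygote survivals,
``q0``, ``qk`` and ``max_generations``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from .selection import GenotypeFitness, HDRScenario

__all__ = ["ScenarioConfig", "ConfigError", "load_scenario", "scenario_from_dict"]

_REDUCED_KEYS = {"h", "g"}
_EXPLICIT_KEYS = {"u_rs", "v_rs"}
_KNOWN_KEYS = {
    "omega", "F", "u_ss", "u_rr", "v_ss", "v_rr",
    "q0", "qk", "max_generations",
} | _REDUCED_KEYS | _EXPLICIT_KEYS

_DEFAULTS = {
    "F": 0.0,
    "u_ss": 1.0,
    "u_rr": 1.0,
    "v_ss": 0.0,
    "v_rr": 1.0,
    "q0": 1e-4,
    "qk": 0.1,
    "max_generations": 1_000_000,
}


class ConfigError(ValueError):
    """A scenario config failed validation; the message names the key."""


@dataclass(frozen=True)
class ScenarioConfig:
    """A validated scenario plus the passage-time question attached to it."""

    scenario: HDRScenario
    q0: float
    qk: float
    max_generations: int
    pure_bt_warning: bool = False
    source: str = "<dict>"


def scenario_from_dict(raw: dict, *, source: str = "<dict>") -> ScenarioConfig:
    """Validate a flat key/value mapping into a :class:`ScenarioConfig`."""
    if not isinstance(raw, dict):
        raise ConfigError(f"{source}: scenario config must be a JSON object")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"{source}: unknown keys: {', '.join(sorted(unknown))}")
    if "omega" not in raw:
        raise ConfigError(f"{source}: required key 'omega' is missing")
    reduced = _REDUCED_KEYS & set(raw)
    explicit = _EXPLICIT_KEYS & set(raw)
    if reduced and explicit:
        raise ConfigError(
            f"{source}: keys {sorted(reduced)} (reduced dominance form) and "
            f"{sorted(explicit)} (explicit heterozygote form) are mutually exclusive"
        )

    cfg = dict(_DEFAULTS)
    cfg.update(raw)
    try:
        if explicit:
            fitness = GenotypeFitness(
                u_ss=cfg["u_ss"],
                u_rs=cfg.get("u_rs", cfg["u_rr"]),
                u_rr=cfg["u_rr"],
                v_ss=cfg["v_ss"],
                v_rs=cfg.get("v_rs", cfg["v_ss"]),
                v_rr=cfg["v_rr"],
            )
        else:
            fitness = GenotypeFitness.from_dominance(
                h=cfg.get("h", 0.0),
                g=cfg.get("g", 0.0),
                u_ss=cfg["u_ss"],
                u_rr=cfg["u_rr"],
                v_ss=cfg["v_ss"],
                v_rr=cfg["v_rr"],
            )
        scenario = HDRScenario(
            omega=cfg["omega"], f_assort=cfg["F"], fitness=fitness
        )
    except ValueError as exc:
        raise ConfigError(f"{source}: {exc}") from exc

    q0, qk = float(cfg["q0"]), float(cfg["qk"])
    if not (0.0 < q0 < 1.0):
        raise ConfigError(f"{source}: q0 must lie in (0, 1), got {q0!r}")
    if not (q0 < qk < 1.0):
        raise ConfigError(f"{source}: qk must lie in (q0, 1), got {qk!r}")
    max_gen = int(cfg["max_generations"])
    if max_gen <= 0:
        raise ConfigError(f"{source}: max_generations must be positive")

    return ScenarioConfig(
        scenario=scenario,
        q0=q0,
        qk=qk,
        max_generations=max_gen,
        pure_bt_warning=scenario.is_pure_bt,
        source=source,
    )


def load_scenario(path: Union[str, Path]) -> ScenarioConfig:
    """Load and validate a scenario JSON file."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    return scenario_from_dict(raw, source=str(path))
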