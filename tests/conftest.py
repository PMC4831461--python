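"""Shared fixtures: reference scenarios and the packaged survey table."""

from importlib.resources import files
from pathlib import Path

import pytest

from btrefuge import GenotypeFitness, HDRScenario, genotype_frequencies, landscape_fitness

DATA = files("btrefuge") / "data"


@pytest.fixture(scope="session")
def table2_path(tmp_path_factory):
    return str(DATA / "table2.tsv")


@pytest.fixture(scope="session")
def scenario_dir():
    return DATA / "scenarios"


@pytest.fixture(scope="session")
def golden_report():
    """Body lines (comments stripped) of the validated pace report."""
    path = Path(__file__).parent / "data" / "table2_pace_report.tsv"
    return [l for l in path.read_text().splitlines() if not l.startswith("#")]


@pytest.fixture
def basic_hdr():
    """Idealised high-dose/refuge scenario: omega=0.8, recessive, random mating."""
    return HDRScenario(omega=0.8)


@pytest.fixture
def epsilon_scenario():
    """Mild deviation F=h=0.025 (epsilon ~ 0.049), omega=0.8, no cost."""
    return HDRScenario(
        omega=0.8, f_assort=0.025, fitness=GenotypeFitness.from_dominance(h=0.025)
    )


@pytest.fixture
def costly_scenario():
    """Partial dominance with a recessive-ish 25% cost and incomplete resistance."""
    return HDRScenario(
        omega=0.8,
        f_assort=0.025,
        fitness=GenotypeFitness.from_dominance(h=0.025, g=0.05, u_rr=0.75, v_rr=0.75),
    )


def genotype_bookkeeping_next_q(q: float, scenario: HDRScenario) -> float:
    """Independent oracle for one generation of the recursion.

    Enumerates zygote genotype frequencies, applies landscape-weighted
    viability selection genotype by genotype, and counts alleles among the
    survivors — no allelic-fitness shortcut anywhere.
    """
    f_rr, f_rs, f_ss = genotype_frequencies(q, scenario.f_assort)
    w_rr, w_rs, w_ss = landscape_fitness(scenario.fitness, scenario.omega)
    s_rr, s_rs, s_ss = f_rr * w_rr, f_rs * w_rs, f_ss * w_ss
    total = s_rr + s_rs + s_ss
    return (s_rr + 0.5 * s_rs) / total
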