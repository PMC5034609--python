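import pytest

from methdyn import AnalysisConfig
from methdyn.simulate import SimulationConfig, simulate_study


SMALL_SIM = SimulationConfig(
    n_genes=60, n_cgis=40, genome_length=6_000_000, n_chroms=2,
    n_cpgs=5000, n_planted=10,
)


@pytest.fixture(scope="session")
def small_sim():
    """A compact synthetic study (2 chromosomes, 5k CpGs, 10 planted genes)."""
    return simulate_study(SMALL_SIM, seed=1)


@pytest.fixture(scope="session")
def small_cfg():
    return AnalysisConfig(autosomes={"chr1", "chr2"})


@pytest.fixture(scope="session")
def default_sim():
    """The standard synthetic design (5 chromosomes, 50k CpGs, 50 planted genes)."""
    return simulate_study(SimulationConfig(), seed=42)


@pytest.fixture(scope="session")
def default_cfg():
    return AnalysisConfig(autosomes={f"chr{i}" for i in range(1, 6)})


@pytest.fixture(scope="session")
def default_report(default_sim, default_cfg):
    """Full pipeline report for the standard synthetic design (seed 42)."""
    from methdyn.pipeline import analyze_study

    return analyze_study(
        default_sim.matrix, default_sim.truth.catalog, default_cfg,
        expression=default_sim.expression,
        family_genes=default_sim.truth.family_genes, seed=42)
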