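import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metatarget import simulate as sim

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def tiny_spec() -> sim.SimulationSpec:
    """A miniature end-to-end scenario: 60 genes, 2 studies, 1 cohort,
    a 40-gene/3-disease graph, and three pathways."""
    return sim.SimulationSpec(
        seed=7,
        n_genes=60,
        studies=[sim.StudySpec(5, 5, "s1"), sim.StudySpec(4, 4, "s2")],
        planted_lfc={1: 2.0, 2: 1.5, 3: 1.5, 4: -1.5, 5: -1.5, 6: -1.5, 7: -1.5},
        noise_sd=0.5,
        cohorts=[sim.CohortSpec(60, 1, 2.5, 0.2, "c0")],
        graph=sim.GraphSpec(
            n_diseases=3,
            edges_per_gene=2,
            planted_assoc=((1, 0), (2, 0), (3, 0), (4, 0)),
            n_genes=40,
            noise_edges_per_disease=1,
        ),
        pathways=[
            sim.PathwaySpec(3, "chain", "up"),
            sim.PathwaySpec(4, "diamond", "down"),
            sim.PathwaySpec(3, "fork", "null"),
        ],
    )


@pytest.fixture(scope="session")
def scenario_spec() -> sim.SimulationSpec:
    return sim.default_scenario(seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
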