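import pytest

from methdriver.config import AnalysisConfig
from methdriver.simulate import SimulationConfig, generate
from methdriver.workflow import run_pipeline


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic cohort: 10 drivers, 50 passengers, seed 0."""
    return generate(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_run(default_bundle):
    """Full pipeline on the default bundle (B=1000 replicates)."""
    b = default_bundle
    cfg = AnalysisConfig(seed=0, n_permutations=1000)
    return run_pipeline(
        b.methylation,
        b.expression,
        b.annotation,
        b.samples,
        b.pathways,
        cfg,
        cancer_genes=b.cancer_genes,
        network=b.network,
    )


@pytest.fixture(scope="session")
def null_bundle():
    """Cohort with no planted alterations at all."""
    return generate(SimulationConfig(seed=0, n_drivers=0, n_passengers=0, n_subtype_drivers=0))


@pytest.fixture(scope="session")
def null_run(null_bundle):
    b = null_bundle
    cfg = AnalysisConfig(seed=0, n_permutations=1000)
    return run_pipeline(b.methylation, b.expression, b.annotation, b.samples, b.pathways, cfg)
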