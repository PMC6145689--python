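import numpy as np
import pytest

from glycopanel import pipeline, simulate


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (5v5 TMT10, planted panel effects)."""
    config = simulate.SyntheticConfig(seed=1)
    tables, truth = simulate.generate_cohort(config)
    return config, tables, truth


@pytest.fixture(scope="session")
def default_result(default_cohort):
    config, tables, _ = default_cohort
    pc = pipeline.PipelineConfig(design=config.groups, tables=tables, seed=config.seed)
    return pipeline.run_pipeline(pc)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
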