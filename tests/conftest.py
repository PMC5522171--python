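import pytest

from herbnet.fixtures import shengma_fixture, table2_fixture
from herbnet.pipeline import run_pipeline
from herbnet.simulate import GeneratorConfig, generate


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle (seed 1), shared across the suite."""
    return generate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    return run_pipeline(
        bundle.deg_records,
        bundle.network,
        bundle.links,
        bundle.herbs,
        bundle.sl_pairs,
        bundle.pathways,
    )


@pytest.fixture(scope="session")
def t2():
    return table2_fixture()


@pytest.fixture(scope="session")
def shengma():
    return shengma_fixture()
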