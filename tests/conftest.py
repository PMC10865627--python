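import numpy as np
import pytest

from brainlink import evaluation, gcn, synthetic
from brainlink.fusion import FusionConfig


@pytest.fixture(scope="session")
def default_suite():
    """The default planted suite (seed 7), generated once per session."""
    return synthetic.generate_suite(synthetic.SuiteConfig())


@pytest.fixture(scope="session")
def small_suite():
    """A reduced suite for fast end-to-end checks."""
    return synthetic.generate_suite(
        synthetic.SuiteConfig(n_genes=50, n_diseases=10, links_per_disease=8)
    )


@pytest.fixture()
def fast_config():
    """Pipeline config with shortened training, for contract tests."""
    return evaluation.PipelineConfig(
        fusion=FusionConfig(epochs=40),
        gcn=gcn.GCNHyper(epochs=200, sae_epochs=40),
        strict=True,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
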