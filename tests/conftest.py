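import pytest
from hypothesis import HealthCheck, settings

from semomics.pipeline import build_from_bundle
from semomics.rdf_core import make_vocabulary
from semomics.synthetic_data import SyntheticConfig, simulate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def vocab():
    return make_vocabulary()


SMALL_CONFIG = SyntheticConfig(
    seed=11,
    n_terms=12,
    n_genes=30,
    n_apoptosis_genes=12,
    n_proliferation_genes=8,
    n_tfs=4,
    n_samples=4,
    sensitive_samples=("YUMAC", "YUSAC2", "YULAC"),
)


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic study: 30 genes, 4 samples, 4 TFs."""
    return simulate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_graph(small_bundle):
    """Merged, entailed semantic model for the small synthetic study."""
    return build_from_bundle(small_bundle)


CHAIN_OBO = """\
format-version: 1.2
ontology: test-go

[Term]
id: GO:0008150
name: biological process
namespace: biological_process

[Term]
id: GO:0008219
name: cell death
namespace: biological_process
is_a: GO:0008150 ! biological process

[Term]
id: GO:0006915
name: apoptotic process
namespace: biological_process
is_a: GO:0008219 ! cell death
"""


@pytest.fixture()
def chain_obo():
    """Three-term is_a chain: apoptosis -> cell death -> biological process."""
    return CHAIN_OBO
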