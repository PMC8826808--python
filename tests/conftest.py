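import numpy as np
import pytest

from pandanet.preprocess import build_network_triple
from pandanet.synthetic import FixtureSpec, gen_expression, gen_motif, gen_ppi


@pytest.fixture(scope="session")
def small_spec():
    """The 20 TF x 50 gene x 20 sample reference fixture."""
    return FixtureSpec(n_tf=20, n_genes=50, n_samples=20, seed=1)


@pytest.fixture(scope="session")
def small_inputs(small_spec):
    return gen_motif(small_spec), gen_ppi(small_spec), gen_expression(small_spec)


@pytest.fixture(scope="session")
def small_triple(small_inputs):
    motif, ppi, expr = small_inputs
    return build_network_triple(motif, ppi, expr)


@pytest.fixture(scope="session")
def tiny_triple():
    """A 3 TF x 4 gene triple for scalar-oracle comparisons."""
    spec = FixtureSpec(n_tf=3, n_genes=4, n_samples=6, motif_density=0.6,
                       ppi_density=0.6, seed=5)
    return build_network_triple(gen_motif(spec), gen_ppi(spec), gen_expression(spec))


@pytest.fixture(scope="session")
def lioness_inputs():
    """The 10 TF x 30 gene x 12 sample population fixture."""
    spec = FixtureSpec(n_tf=10, n_genes=30, n_samples=12, seed=3)
    return gen_motif(spec), gen_ppi(spec), gen_expression(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
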