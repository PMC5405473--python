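import numpy as np
import pytest

from tajscan.simulate import SimSpec, emit_genome_bundle


@pytest.fixture(scope="session")
def neutral_bundle(tmp_path_factory):
    """A small all-neutral synthetic bundle shared across tests."""
    spec = SimSpec(contig_lengths=(250_000, 100_000), theta_per_window=5.0,
                   masked_fraction=0.05, n_genes=60, seed=42)
    out = tmp_path_factory.mktemp("neutral_bundle")
    return spec, emit_genome_bundle(spec, out)


@pytest.fixture(scope="session")
def planted_bundle(tmp_path_factory):
    """A bundle with 10% balancing and 10% sweep windows."""
    spec = SimSpec(contig_lengths=(400_000, 100_000), theta_per_window=5.0,
                   balancing_fraction=0.10, sweep_fraction=0.10,
                   masked_fraction=0.05, n_genes=80, seed=7)
    out = tmp_path_factory.mktemp("planted_bundle")
    return spec, emit_genome_bundle(spec, out)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
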