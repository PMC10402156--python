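import numpy as np
import pytest

from stripehic.dataset import StripeDataset
from stripehic.geometry import ModelGeometry
from stripehic.io_formats import GenomeLayout
from stripehic.synthetic import SimConfig, simulate


@pytest.fixture
def tiny_layout():
    return GenomeLayout(["chr1", "chr2"], [100_000, 50_000])


@pytest.fixture(scope="session")
def mini_geometry():
    return ModelGeometry.mini()


@pytest.fixture(scope="session")
def micro_sim():
    """Small simulation shared by training/inference/cli-level tests."""
    cfg = SimConfig(chrom_length=2_000_000, n_chroms=3, n_cells=200,
                    n_clusters=1, n_loops=10, n_decoys=5,
                    max_loop_dist_bp=200_000, anchor_span_bins=2)
    return cfg, simulate(cfg, seed=3)


@pytest.fixture(scope="session")
def micro_dataset(micro_sim, mini_geometry):
    cfg, bundle = micro_sim
    return StripeDataset.from_fragments(
        bundle.fragments, bundle.genome.layout, mini_geometry, bundle.ctcf,
        contact_counts=bundle.contacts_bulk, metacell_k=5, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
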