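import numpy as np
import pytest

import sccrt


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset with known truth, shared across tests."""
    cfg = sccrt.SimulationConfig(n_cells=400, n_genes=10, latent_dim=3,
                                 n_causal=2, seed=7)
    return sccrt.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_counts():
    rng = np.random.default_rng(0)
    counts = rng.poisson(5.0, size=(20, 4)).astype(float) + 1.0
    return sccrt.CountDataset(counts,
                              gene_names=[f"g{i}" for i in range(4)],
                              cell_ids=[f"c{i}" for i in range(20)])


@pytest.fixture(scope="session")
def fitted_small(small_sim):
    """Split + fitted generative model + linear predictor on small_sim."""
    split = sccrt.make_split(small_sim.dataset.n_cells, 0.7, seed=7)
    dev = small_sim.dataset.subset(split.dev_idx)
    gen = sccrt.NBVAE(latent_dim=3, hidden=32, max_epochs=60, seed=7).fit(dev)
    pred = sccrt.fit_predictor(dev.counts,
                               small_sim.response.subset(split.dev_idx),
                               dev.nuisance, family="linear_gaussian", seed=7)
    return split, gen, pred
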