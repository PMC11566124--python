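"""NB-VAE fitting, posterior caching, and conditional null sampling."""

import numpy as np
import pytest

import sccrt
from sccrt.generative import (NBVAE, PerGeneNBModel, nb_nll, sample_nb,
                              sample_null_features)
from sccrt.simulate import OracleGenerativeModel


@pytest.fixture(scope="module")
def sim_and_model():
    cfg = sccrt.SimulationConfig(n_cells=500, n_genes=12, latent_dim=3,
                                 n_causal=2, seed=11)
    sim = sccrt.simulate_dataset(cfg)
    split = sccrt.make_split(500, 0.7, seed=11)
    dev = sim.dataset.subset(split.dev_idx)
    model = NBVAE(latent_dim=3, hidden=48, max_epochs=150, seed=11).fit(dev)
    return sim, split, model


@pytest.fixture(scope="module")
def well_trained():
    """Larger simulation with a fully trained matched-dimension fit."""
    cfg = sccrt.SimulationConfig(n_cells=1200, n_genes=20, latent_dim=3,
                                 n_causal=2, seed=5)
    sim = sccrt.simulate_dataset(cfg)
    split = sccrt.make_split(1200, 0.7, seed=5)
    model = NBVAE(latent_dim=3, max_epochs=300, seed=5).fit(
        sim.dataset.subset(split.dev_idx))
    return sim, split, model


class TestFit:
    def test_proportions_sum_to_one(self, sim_and_model):
        sim, split, model = sim_and_model
        val = sim.dataset.subset(split.val_idx)
        cache = model.make_cache(val, seed=0)
        np.testing.assert_allclose(cache.proportions.sum(axis=1), 1.0, atol=1e-6)

    def test_dispersions_positive(self, sim_and_model):
        _, _, model = sim_and_model
        assert np.all(model.dispersions > 0)

    def test_training_reduces_loss(self, sim_and_model):
        _, _, model = sim_and_model
        assert model.training_log[-1] < model.training_log[0]

    def test_deterministic_given_seed(self, sim_and_model):
        sim, split, model = sim_and_model
        dev = sim.dataset.subset(split.dev_idx)
        again = NBVAE(latent_dim=3, hidden=48, max_epochs=150, seed=11).fit(dev)
        for k in model.params:
            np.testing.assert_array_equal(model.params[k], again.params[k])

    def test_tiny_dataset_runs(self):
        rng = np.random.default_rng(0)
        ds = sccrt.CountDataset(rng.poisson(5, (50, 2)).astype(float) + 1,
                                ["a", "b"], [f"c{i}" for i in range(50)])
        model = NBVAE(latent_dim=2, hidden=8, max_epochs=20, seed=0).fit(ds)
        cache = model.make_cache(ds, seed=0)
        np.testing.assert_allclose(cache.proportions.sum(axis=1), 1.0, atol=1e-6)

    def test_single_gene_rejected(self):
        ds = sccrt.CountDataset(np.ones((10, 1)), ["a"],
                                [f"c{i}" for i in range(10)])
        with pytest.raises(ValueError):
            NBVAE(seed=0).fit(ds)

    def test_heldout_fit_close_to_oracle(self, well_trained):
        # a matched-dimension fit should approach the true simulator's
        # conditional NB likelihood on held-out cells
        sim, split, model = well_trained
        val = sim.dataset.subset(split.val_idx)
        idx = np.asarray(split.val_idx)
        t = sim.truth
        mu = t.library[idx][:, None] * t.proportions(t.z[idx], t.batch_ids[idx])
        oracle_nll = nb_nll(val.counts, mu, t.dispersions).sum(axis=1).mean()

        cache = model.make_cache(val, seed=0)
        fit_nll = nb_nll(val.counts, cache.means, cache.dispersions
                         ).sum(axis=1).mean()
        assert fit_nll <= 1.05 * oracle_nll


class TestCache:
    def test_zero_scale_particle_equals_mean(self, sim_and_model):
        sim, split, model = sim_and_model
        val = sim.dataset.subset(split.val_idx)
        saved = {k: model.params[k].copy() for k in ("Wv", "bv")}
        model.params["Wv"] = np.zeros_like(model.params["Wv"])
        model.params["bv"] = np.full_like(model.params["bv"], -60.0)
        try:
            cache = model.make_cache(val, seed=3)
            mu, _ = model.encode(val.counts.astype(float), val.nuisance)
            np.testing.assert_allclose(cache.zbar, mu, atol=1e-10)
        finally:
            model.params.update(saved)

    def test_different_seeds_different_particles(self, sim_and_model):
        sim, split, model = sim_and_model
        val = sim.dataset.subset(split.val_idx)
        c1, c2 = model.make_cache(val, 1), model.make_cache(val, 2)
        assert not np.allclose(c1.zbar, c2.zbar)

    def test_cache_immutable(self, sim_and_model):
        sim, split, model = sim_and_model
        cache = model.make_cache(sim.dataset.subset(split.val_idx), 0)
        with pytest.raises((ValueError, RuntimeError)):
            cache.zbar[0, 0] = 99.0

    def test_cache_identical_across_uses(self, sim_and_model):
        # the same particle serves every gene and MC replicate
        sim, split, model = sim_and_model
        val = sim.dataset.subset(split.val_idx)
        cache = model.make_cache(val, 0)
        snap = cache.zbar.copy()
        for g in range(3):
            for _ in range(5):
                sample_null_features(model, cache, np.array([g]), 2, seed=g)
        np.testing.assert_array_equal(cache.zbar, snap)

    def test_gene_set_mismatch_rejected(self, sim_and_model):
        sim, split, model = sim_and_model
        val = sim.dataset.subset(split.val_idx)
        other = sccrt.CountDataset(val.counts, [f"x{i}" for i in
                                                range(val.n_genes)], val.cell_ids)
        with pytest.raises(ValueError, match="gene set"):
            model.make_cache(other, 0)


class TestSampling:
    def test_poisson_limit_moments(self):
        # dispersion -> infinity: NB converges to Poisson, mean check
        rng = np.random.default_rng(0)
        draws = sample_nb(rng, np.full(10000, 5.0), np.array(1e9))
        assert abs(draws.mean() - 5.0) < 3 * np.sqrt(5.0 / 10000)
        assert abs(draws.var() / 5.0 - 1.0) < 0.1

    def test_full_gene_set_shape(self, sim_and_model):
        sim, split, model = sim_and_model
        val = sim.dataset.subset(split.val_idx)
        cache = model.make_cache(val, 0)
        synth = sample_null_features(model, cache,
                                     np.arange(val.n_genes), 1, seed=0)
        assert synth.shape == (1, val.n_cells, val.n_genes)

    def test_cross_gene_independence_given_particle(self, sim_and_model):
        sim, split, model = sim_and_model
        val = sim.dataset.subset(split.val_idx)
        cache = model.make_cache(val, 0)
        synth = sample_null_features(model, cache, np.array([0, 1]), 4000, seed=1)
        corr = np.corrcoef(synth[:, 0, 0], synth[:, 0, 1])[0, 1]
        assert abs(corr) < 3.5 / np.sqrt(4000)

    def test_batch_invariant_draws(self, sim_and_model):
        # a gene's draws do not depend on which other genes are requested
        sim, split, model = sim_and_model
        val = sim.dataset.subset(split.val_idx)
        cache = model.make_cache(val, 0)
        alone = sample_null_features(model, cache, np.array([2]), 5, seed=9)
        grouped = sample_null_features(model, cache, np.array([5, 2, 0]), 5, seed=9)
        np.testing.assert_array_equal(alone[:, :, 0], grouped[:, :, 1])

    def test_sampling_api_takes_no_response(self):
        import inspect

        params = inspect.signature(sample_null_features).parameters
        assert not any("response" in p or p == "y" for p in params)

    def test_k_zero_rejected(self, sim_and_model):
        sim, split, model = sim_and_model
        cache = model.make_cache(sim.dataset.subset(split.val_idx), 0)
        with pytest.raises(ValueError):
            sample_null_features(model, cache, np.array([0]), 0, seed=0)


class TestNormalizedExpression:
    def test_tracks_true_proportions(self, well_trained):
        sim, split, model = well_trained
        val = sim.dataset.subset(split.val_idx)
        cache = model.make_cache(val, 0)
        norm = sccrt.normalized_expression(model, cache)
        assert norm.shape == (val.n_cells, val.n_genes)
        np.testing.assert_allclose(norm.sum(axis=1), 1.0, atol=1e-6)
        idx = np.asarray(split.val_idx)
        true_p = sim.truth.proportions(sim.truth.z[idx],
                                       sim.truth.batch_ids[idx])
        per_gene = [np.corrcoef(norm[:, g], true_p[:, g])[0, 1]
                    for g in range(val.n_genes)]
        assert np.mean(per_gene) > 0.9


class TestPluggableModels:
    def test_per_gene_nb_model_contract(self, sim_and_model):
        sim, split, _ = sim_and_model
        dev = sim.dataset.subset(split.dev_idx)
        val = sim.dataset.subset(split.val_idx)
        simple = PerGeneNBModel().fit(dev)
        cache = simple.make_cache(val, 0)
        synth = sample_null_features(simple, cache, np.array([0]), 3, seed=0)
        assert synth.shape == (3, val.n_cells, 1)
        assert np.all(synth >= 0)

    def test_oracle_model_reproduces_marginals(self, sim_and_model):
        sim, split, _ = sim_and_model
        val = sim.dataset.subset(split.val_idx)
        oracle = OracleGenerativeModel(sim.truth, sim.dataset.gene_names)
        cache = oracle.make_cache(val, 0)
        synth = sample_null_features(oracle, cache, np.array([0]), 400, seed=0)
        # mean of synthetic draws tracks the true NB mean per cell, within
        # the per-cell NB standard error of a 400-draw Monte-Carlo average
        m = cache.means[:, 0]
        se = np.sqrt((m + m ** 2 / cache.dispersions[0]) / 400)
        z = np.abs(synth[:, :, 0].mean(axis=0) - m) / se
        assert np.quantile(z, 0.99) < 4.0


class TestPersistence:
    def test_save_load_roundtrip(self, sim_and_model, tmp_path):
        sim, split, model = sim_and_model
        path = str(tmp_path / "model.npz")
        model.save(path)
        back = NBVAE.load(path)
        val = sim.dataset.subset(split.val_idx)
        c1, c2 = model.make_cache(val, 5), back.make_cache(val, 5)
        np.testing.assert_array_equal(c1.zbar, c2.zbar)
        np.testing.assert_array_equal(c1.proportions, c2.proportions)
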