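"""CRT engine: p-value formula, feature randomization, BH, cell scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sccrt
from sccrt.crt import (HypothesisSpec, bh_correct, compute_cell_scores,
                       crt_pvalue, randomize_features, run_crt)


def bh_stepup_oracle(p, alpha):
    """Hand-rolled step-up BH: reject the k smallest where p_(k) <= k*a/m."""
    m = len(p)
    order = np.argsort(p)
    thresh = alpha * np.arange(1, m + 1) / m
    below = np.asarray(p)[order] <= thresh
    k = np.max(np.where(below)[0]) + 1 if below.any() else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestPvalue:
    def test_all_synthetic_larger(self):
        assert crt_pvalue(0.0, np.array([1.0, 2.0, 3.0, 4.0])) == 0.2

    def test_observed_largest(self):
        assert crt_pvalue(5.0, np.array([1.0, 2.0, 3.0])) == 1.0

    def test_count_and_divide(self):
        assert crt_pvalue(1.0, np.array([0.5, 1.2, 0.9])) == 0.75

    def test_tie_counts_toward_null(self):
        assert crt_pvalue(1.0, np.array([1.0, 2.0])) == pytest.approx(2 / 3)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            crt_pvalue(np.nan, np.array([1.0]))

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1,
                    max_size=40), st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_brute_force_enumeration(self, synth, obs):
        synth = np.array(synth)
        expected = (1 + sum(1 for s in synth if s <= obs)) / (len(synth) + 1)
        assert crt_pvalue(obs, synth) == pytest.approx(expected)
        assert 0 < crt_pvalue(obs, synth) <= 1


class TestRandomizeFeatures:
    def test_identity_replacement(self):
        X = np.arange(12.0).reshape(4, 3)
        synth = X[:, [1]][None, :, :]
        out = randomize_features(X, [1], synth)
        np.testing.assert_array_equal(out[0], X)

    def test_non_target_untouched(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(5, (6, 4)).astype(float)
        synth = rng.poisson(5, (3, 6, 1)).astype(float)
        for k, Xk in enumerate(randomize_features(X, [2], synth)):
            np.testing.assert_array_equal(Xk[:, [0, 1, 3]], X[:, [0, 1, 3]])
            np.testing.assert_array_equal(Xk[:, 2], synth[k, :, 0])

    def test_explicit_enumeration_two_columns(self):
        X = np.arange(20.0).reshape(4, 5)
        synth = np.stack([np.full((4, 2), v) for v in (100.0, 200.0, 300.0)])
        out = randomize_features(X, [1, 3], synth)
        assert len(out) == 3
        for k, v in enumerate((100.0, 200.0, 300.0)):
            expected = X.copy()
            expected[:, [1, 3]] = v
            np.testing.assert_array_equal(out[k], expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            randomize_features(np.ones((2, 2)), [5], np.ones((1, 2, 1)))


class TestBH:
    def test_all_ones(self):
        q, rej = bh_correct(np.ones(6), alpha=0.05)
        assert not rej.any() and np.all(q == 1.0)

    def test_stepup_by_hand(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.5])
        _, rej = bh_correct(p, alpha=0.05)
        np.testing.assert_array_equal(rej, [True, True, True, True, False])

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        _, r5 = bh_correct(p, alpha=0.05)
        _, r10 = bh_correct(p, alpha=0.1)
        assert np.all(r10[r5])

    def test_matches_handrolled_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.uniform(1e-6, 1.0, size=m)
            alpha = rng.choice([0.01, 0.05, 0.1, 0.2])
            _, rej = bh_correct(p, alpha)
            np.testing.assert_array_equal(rej, bh_stepup_oracle(p, alpha))

    def test_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        q, _ = bh_correct(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_correct(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_correct(np.array([1.5]))


class TestCellScores:
    def test_identity_synthetic_zero(self):
        nll = np.array([1.0, 2.0])
        np.testing.assert_allclose(
            compute_cell_scores(nll, np.tile(nll, (3, 1))), 0.0)

    def test_arithmetic_oracle(self):
        obs = np.array([1.0])
        synth = np.array([[1.2], [1.4]])
        assert compute_cell_scores(obs, synth)[0] == pytest.approx(0.3)

    def test_mean_equals_score_difference(self):
        rng = np.random.default_rng(4)
        obs = rng.normal(size=20)
        synth = rng.normal(size=(7, 20))
        lhs = compute_cell_scores(obs, synth).mean()
        rhs = synth.mean(axis=1).mean() - obs.mean()
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestRunCrt:
    def test_k1_pvalue_support(self, small_sim, fitted_small):
        split, gen, pred = fitted_small
        res = run_crt(small_sim.dataset, small_sim.response, split, gen, pred,
                      n_mc=1, seed=0)
        assert set(np.round(res.p_values, 6)) <= {0.5, 1.0}

    def test_copied_column_detected(self):
        # y literally equals log1p of one gene's counts: maximal signal
        cfg = sccrt.SimulationConfig(n_cells=600, n_genes=8, latent_dim=2,
                                     n_causal=1, seed=13)
        ds, truth = sccrt.simulate_counts_with_truth(cfg)
        y = sccrt.ResponseVector(np.log1p(ds.counts[:, 3]), name="copy")
        split = sccrt.make_split(600, 0.7, seed=13)
        dev = ds.subset(split.dev_idx)
        pred = sccrt.fit_predictor(dev.counts, y.subset(split.dev_idx),
                                   dev.nuisance, family="linear_gaussian",
                                   seed=13)
        oracle = sccrt.OracleGenerativeModel(truth, ds.gene_names)
        res = run_crt(ds, y, split, oracle, pred,
                      hypotheses=[HypothesisSpec((3,))], n_mc=19, seed=13)
        assert res.p_values[0] == pytest.approx(1 / 20)

    def test_hypothesis_order_irrelevant(self, small_sim, fitted_small):
        split, gen, pred = fitted_small
        hyps = [HypothesisSpec((g,)) for g in range(5)]
        a = run_crt(small_sim.dataset, small_sim.response, split, gen, pred,
                    hypotheses=hyps, n_mc=7, seed=3)
        b = run_crt(small_sim.dataset, small_sim.response, split, gen, pred,
                    hypotheses=hyps[::-1], n_mc=7, seed=3)
        np.testing.assert_array_equal(a.p_values, b.p_values[::-1])

    def test_reproducible_given_seed(self, small_sim, fitted_small):
        split, gen, pred = fitted_small
        a = run_crt(small_sim.dataset, small_sim.response, split, gen, pred,
                    n_mc=5, seed=2)
        b = run_crt(small_sim.dataset, small_sim.response, split, gen, pred,
                    n_mc=5, seed=2)
        np.testing.assert_array_equal(a.p_values, b.p_values)
        np.testing.assert_array_equal(a.cell_scores, b.cell_scores)

    def test_cell_score_linearity_invariant(self, small_sim, fitted_small):
        split, gen, pred = fitted_small
        res = run_crt(small_sim.dataset, small_sim.response, split, gen, pred,
                      n_mc=11, seed=1)
        for i in range(res.n_hypotheses):
            lhs = res.cell_scores[i].mean()
            rhs = res.synthetic_scores[i].mean() - res.observed_score
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_length_mismatch_rejected(self, small_sim, fitted_small):
        split, gen, pred = fitted_small
        bad = sccrt.ResponseVector(np.zeros(3))
        with pytest.raises(ValueError):
            run_crt(small_sim.dataset, bad, split, gen, pred, n_mc=2, seed=0)

    def test_tidy_frame_contract(self, small_sim, fitted_small):
        split, gen, pred = fitted_small
        res = run_crt(small_sim.dataset, small_sim.response, split, gen, pred,
                      n_mc=4, seed=0)
        df = res.to_frame()
        assert list(df.columns[:4]) == ["hypothesis_label", "genes", "p_value",
                                        "q_value"]
        assert len(df) == small_sim.dataset.n_genes
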