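"""Synthetic data generator and benchmark harness.

The generator emulates a semi-synthetic single-cell benchmark: counts come
from a known latent NB model (low-dimensional cell state, softmax
proportions, log-normal library sizes, optional batch offsets and an
optional block of strongly correlated genes), and the response is a linear
combination of the *squared* mean-centered log-CPM of a random causal gene
subset, corrupted by Gaussian noise (or mapped through a log-link Poisson).
The squared link makes the truth nonlinear: linear baselines are
misspecified by construction, which is the point of the benchmark.

Because the generating model is known exactly, it can also serve as an
oracle conditional-null sampler (:class:`OracleGenerativeModel`), which is
how the validity of the CRT machinery is checked independently of model
fitting.

The default benchmark configuration (2000 cells, 100 genes, 20 causal,
latent dimension 5, noise at 25% of the signal sd, K = 200 Monte-Carlo
draws, 5 replicates) keeps the causal fraction and the nonlinearity of the
full-scale design while running in minutes on one CPU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from ._seeds import rng_for, small_int_seed
from .crt import bh_correct, run_crt
from .data import (CountDataset, ResponseVector, center_columns,
                   compute_log_cpm, make_split)
from .generative import NBVAE, PosteriorCache
from .importance import fit_predictor


@dataclass(frozen=True)
class SimulationConfig:
    n_cells: int = 2000
    n_genes: int = 100
    latent_dim: int = 5
    n_batches: int = 1
    n_causal: int = 20
    noise_family: str = "gaussian"      # gaussian | poisson
    noise_scale: float = 0.25           # fraction of the signal sd
    within_cluster_correlation: float = 0.0
    block_size: int = 2                 # genes in the correlated block
    force_causal: tuple = ()            # gene indices always in the causal set
    mean_library: float = 2000.0
    library_sd: float = 0.25            # sd of log library size
    logit_scale: float = 1.0            # sd of latent-driven logits
    batch_scale: float = 0.3            # sd of per-gene batch offsets
    seed: int = 0

    def __post_init__(self):
        if self.n_causal > self.n_genes:
            raise ValueError("n_causal exceeds n_genes")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.noise_family not in ("gaussian", "poisson"):
            raise ValueError("noise_family must be gaussian or poisson")
        if not 0.0 <= self.within_cluster_correlation <= 1.0:
            raise ValueError("within_cluster_correlation must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground-truth parameters and latent states of a simulated dataset."""

    z: np.ndarray               # N x d
    loadings: np.ndarray        # G x d
    intercepts: np.ndarray      # G
    batch_offsets: np.ndarray   # n_batches x G (first row zero)
    batch_ids: np.ndarray       # N
    dispersions: np.ndarray     # G
    library: np.ndarray         # N

    def proportions(self, z: np.ndarray | None = None,
                    batch_ids: np.ndarray | None = None) -> np.ndarray:
        z = self.z if z is None else z
        b = self.batch_ids if batch_ids is None else batch_ids
        logits = z @ self.loadings.T + self.intercepts + self.batch_offsets[b]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


@dataclass
class SimulatedDataset:
    dataset: CountDataset
    response: ResponseVector
    causal_set: np.ndarray
    weights: np.ndarray
    truth: SimTruth


def simulate_counts(config: SimulationConfig) -> CountDataset:
    """Counts only; see :func:`simulate_counts_with_truth` for the truth."""
    return simulate_counts_with_truth(config)[0]


def simulate_counts_with_truth(config: SimulationConfig):
    rng = rng_for(config.seed, "simulation")
    n, g, d = config.n_cells, config.n_genes, config.latent_dim

    z = rng.standard_normal((n, d))
    loadings = rng.standard_normal((g, d)) * (config.logit_scale / np.sqrt(d))
    intercepts = rng.standard_normal(g)
    dispersions = np.exp(rng.normal(np.log(5.0), 0.5, size=g))

    c = config.within_cluster_correlation
    if c > 0 and config.block_size >= 2:
        b = config.block_size
        # fixed-norm loadings so the block's logit correlation is c exactly;
        # 1.5x scale keeps count noise small relative to the shared signal
        scale = 1.5 * config.logit_scale
        shared = rng.standard_normal(d)
        shared *= scale / np.linalg.norm(shared)
        own = rng.standard_normal((b, d))
        own *= scale / np.linalg.norm(own, axis=1, keepdims=True)
        loadings[:b] = np.sqrt(c) * shared + np.sqrt(1.0 - c) * own
        # keep block genes abundant and weakly overdispersed so the shared
        # latent signal dominates their count noise
        intercepts[:b] = 2.0
        dispersions[:b] = 500.0

    batch_ids = rng.integers(0, config.n_batches, size=n)
    batch_offsets = np.zeros((config.n_batches, g))
    if config.n_batches > 1:
        batch_offsets[1:] = rng.normal(0.0, config.batch_scale,
                                       size=(config.n_batches - 1, g))

    library = np.exp(rng.normal(np.log(config.mean_library), config.library_sd,
                                size=n))
    truth = SimTruth(z=z, loadings=loadings, intercepts=intercepts,
                     batch_offsets=batch_offsets, batch_ids=batch_ids,
                     dispersions=dispersions, library=library)
    mu = library[:, None] * truth.proportions()
    lam = rng.gamma(shape=dispersions, scale=mu / dispersions)
    counts = rng.poisson(lam).astype(float)

    if config.n_batches > 1:
        # reference coding keeps downstream regression designs full-rank
        nuisance = np.zeros((n, config.n_batches - 1))
        for b in range(1, config.n_batches):
            nuisance[:, b - 1] = (batch_ids == b).astype(float)
        names = [f"batch_{b}" for b in range(1, config.n_batches)]
    else:
        nuisance, names = None, []

    ds = CountDataset(counts=counts,
                      gene_names=[f"g{j}" for j in range(g)],
                      cell_ids=[f"c{i}" for i in range(n)],
                      nuisance=nuisance, nuisance_names=names)
    return ds, truth


def simulate_response(dataset: CountDataset, config: SimulationConfig,
                      truth: SimTruth | None = None) -> SimulatedDataset:
    """Response = sum_g w_g * (centered log-CPM_g)^2 over a causal set.

    Weights are i.i.d. standard normal on the causal genes, zero
    elsewhere.  Gaussian family adds noise with sd equal to
    ``noise_scale`` times the signal sd; the Poisson family draws counts
    with rate exp(a + u) for the standardized signal u, with a chosen so
    the mean rate is about 5.
    """
    g = dataset.n_genes
    rng_w = rng_for(config.seed, "weights")
    forced = np.asarray(config.force_causal, dtype=int)
    n_free = config.n_causal - forced.size
    if n_free < 0:
        raise ValueError("force_causal is larger than n_causal")
    pool = np.setdiff1d(np.arange(g), forced)
    causal = np.sort(np.concatenate([forced,
                                     rng_w.choice(pool, n_free, replace=False)]))
    weights = np.zeros(g)
    weights[causal] = rng_w.standard_normal(causal.size)

    feats = center_columns(compute_log_cpm(dataset.counts))
    signal = (feats[:, causal] ** 2) @ weights[causal]
    sd = float(signal.std())
    rng_e = rng_for(config.seed, "response_noise")
    if config.noise_family == "gaussian":
        if sd == 0 and config.noise_scale > 0:
            raise ValueError("degenerate signal (sd = 0) with positive noise")
        y = signal + rng_e.normal(0.0, config.noise_scale * sd, size=len(signal))
        response = ResponseVector(y, family="gaussian", name="sim_gaussian")
    else:
        if sd == 0:
            raise ValueError("degenerate signal (sd = 0)")
        u = (signal - signal.mean()) / sd
        rate = np.exp(np.log(5.0) - 0.5 + u)
        y = rng_e.poisson(rate).astype(float)
        response = ResponseVector(y, family="poisson", name="sim_poisson")
    return SimulatedDataset(dataset=dataset, response=response,
                            causal_set=causal, weights=weights,
                            truth=truth if truth is not None else _refit_truth(config))


def _refit_truth(config: SimulationConfig) -> SimTruth:
    return simulate_counts_with_truth(config)[1]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    ds, truth = simulate_counts_with_truth(config)
    return simulate_response(ds, config, truth)


class OracleGenerativeModel:
    """The true simulator exposed through the generative-model contract.

    The cached particle per cell is the latent state that actually
    generated it, under which observed and synthetic counts for any gene
    are exchangeable i.i.d. NB draws — the exact conditional null.  Used
    to check CRT validity with no model-fitting error in the way.
    """

    def __init__(self, truth: SimTruth, gene_names):
        self.truth = truth
        self.gene_names = tuple(gene_names)

    def fit(self, dev_data: CountDataset, seed: int = 0) -> "OracleGenerativeModel":
        return self

    def make_cache(self, val_data: CountDataset, seed: int,
                   cell_indices: np.ndarray | None = None) -> PosteriorCache:
        if tuple(val_data.gene_names) != self.gene_names:
            raise ValueError("gene set mismatch")
        if cell_indices is None:
            # cell ids of the simulator are "c<i>"
            cell_indices = np.array([int(c[1:]) for c in val_data.cell_ids])
        t = self.truth
        rho = t.proportions(t.z[cell_indices], t.batch_ids[cell_indices])
        return PosteriorCache(zbar=t.z[cell_indices], proportions=rho,
                              dispersions=t.dispersions.copy(),
                              library=t.library[cell_indices].copy(),
                              gene_names=self.gene_names, seed=seed)


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def ols_baseline(X: np.ndarray, y: np.ndarray,
                 S: np.ndarray | None = None) -> np.ndarray:
    """Per-feature t-test p-values from one multiple regression of y on all
    columns of X (plus intercept and nuisance columns)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, g = X.shape
    blocks = [X] if S is None or S.size == 0 else [X, np.asarray(S, float)]
    design = sm.add_constant(np.column_stack(blocks))
    if n <= design.shape[1]:
        raise ValueError("need N > G + T + 1 for a full-rank OLS design")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, r, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
        tol = np.abs(r[0, 0]) * max(design.shape) * np.finfo(float).eps
        bad = sorted(piv[np.abs(np.diag(r)) < tol].tolist())
        raise ValueError(f"rank-deficient design; collinear columns {bad}")
    fit = sm.OLS(y, design).fit()
    return np.asarray(fit.pvalues[1:1 + g])


def marginal_baseline(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Simple-regression t-test p-value of y on each feature separately."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 cells")
    xs = X.std(axis=0)
    const = xs <= 0
    if np.any(const):
        warnings.warn(f"{int(const.sum())} constant feature(s); p set to 1")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (np.sqrt((xc ** 2).sum(axis=0))
                                              * np.sqrt((yc ** 2).sum()))
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p[const] = 1.0
    return p


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalMetrics:
    fdr: float
    tpr: float
    f1: float
    n_discoveries: int


def evaluate(discovery_set, causal_set, group_partition: bool = False) -> EvalMetrics:
    """FDR/TPR/F1 of a discovery set against the true causal genes.

    Gene level: discoveries are gene indices.  Group level
    (``group_partition=True``): discoveries are iterables of gene
    indices; a group counts as a true positive iff it contains at least
    one causal gene, and power is the fraction of causal genes covered by
    detected groups.  Empty discovery sets give FDR 0 by convention.
    """
    causal = set(int(c) for c in np.atleast_1d(np.asarray(causal_set, dtype=int)))
    if group_partition:
        groups = [set(int(g) for g in grp) for grp in discovery_set]
        tp = sum(1 for grp in groups if grp & causal)
        fp = len(groups) - tp
        covered = set().union(*[grp & causal for grp in groups]) if groups else set()
        tpr = len(covered) / max(1, len(causal))
        n_disc = len(groups)
    else:
        disc = set(int(g) for g in discovery_set)
        tp = len(disc & causal)
        fp = len(disc) - tp
        tpr = tp / max(1, len(causal))
        n_disc = len(disc)
    fdr = fp / max(1, fp + tp)
    precision = tp / max(1, n_disc)
    f1 = (2 * precision * tpr / (precision + tpr)) if (precision + tpr) > 0 else 0.0
    return EvalMetrics(fdr=float(fdr), tpr=float(tpr), f1=float(f1),
                       n_discoveries=n_disc)


# ---------------------------------------------------------------------------
# Full benchmark
# ---------------------------------------------------------------------------

DEFAULT_METHODS = ("crt_mlp", "crt_linear", "ols", "marginal")


def run_benchmark(config: SimulationConfig | None = None,
                  methods=DEFAULT_METHODS,
                  alphas=(0.05, 0.1, 0.2),
                  n_replicates: int = 5,
                  seed: int = 0,
                  n_mc: int = 200,
                  dev_fraction: float = 0.7,
                  gen_config: dict | None = None) -> pd.DataFrame:
    """Simulate, run every method, and score FDR/TPR per replicate.

    CRT methods follow the full pipeline: dev/val split, NB-VAE fit on
    dev, predictor fit on dev, gene-level CRT with K Monte-Carlo draws,
    BH at each alpha.  Baselines (OLS, marginal t-test on log-CPM
    features) use all cells — the advantage the comparison deliberately
    grants them.  Returns a tidy frame with one row per
    (replicate, method, alpha).
    """
    config = config or SimulationConfig()
    rows = []
    for r in range(n_replicates):
        rep_seed = small_int_seed(seed, "simulation", 1000 + r)
        sim = simulate_dataset(replace(config, seed=rep_seed))
        ds, y, causal = sim.dataset, sim.response, sim.causal_set
        split = make_split(ds.n_cells, dev_fraction, seed=rep_seed)
        dev = ds.subset(split.dev_idx)
        y_dev = y.subset(split.dev_idx)

        crt_p: dict[str, np.ndarray] = {}
        crt_methods = [m for m in methods if m.startswith("crt")]
        if crt_methods:
            gen = NBVAE(**(gen_config or {}), seed=rep_seed).fit(dev)
            for m in crt_methods:
                fam = {"crt_mlp": "mlp_gaussian",
                       "crt_linear": "linear_gaussian"}[m]
                pred = fit_predictor(dev.counts, y_dev, dev.nuisance,
                                     family=fam, seed=rep_seed)
                res = run_crt(ds, y, split, gen, pred, n_mc=n_mc,
                              alpha=alphas[0], seed=rep_seed)
                crt_p[m] = res.p_values

        base_p: dict[str, np.ndarray] = {}
        if "ols" in methods or "marginal" in methods:
            feats = center_columns(compute_log_cpm(ds.counts))
            if "ols" in methods:
                base_p["ols"] = ols_baseline(feats, y.values, ds.nuisance)
            if "marginal" in methods:
                base_p["marginal"] = marginal_baseline(feats, y.values)

        for method in methods:
            p = crt_p.get(method, base_p.get(method))
            if p is None:
                raise ValueError(f"unknown method {method!r}")
            for alpha in alphas:
                _, rej = bh_correct(np.clip(p, np.nextafter(0, 1), 1.0), alpha)
                metrics = evaluate(np.where(rej)[0], causal)
                rows.append({"replicate": r, "method": method, "alpha": alpha,
                             "fdr": metrics.fdr, "tpr": metrics.tpr,
                             "f1": metrics.f1,
                             "n_discoveries": metrics.n_discoveries})
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of FDR/TPR per (method, alpha)."""
    def se(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    return (table.groupby(["method", "alpha"])
            .agg(fdr_mean=("fdr", "mean"), fdr_se=("fdr", se),
                 tpr_mean=("tpr", "mean"), tpr_se=("tpr", se),
                 n_discoveries=("n_discoveries", "mean"))
            .reset_index())
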