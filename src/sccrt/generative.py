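"""Latent-variable generative model of counts and conditional null sampling.

The conditional randomization test needs synthetic draws of a gene's counts
that are consistent with the null of conditional independence.  We model
counts with a latent-variable factorization

    p(x, z | s) = p(z) * prod_g p(x_g | z, s),

with a standard-normal prior on a low-dimensional cell state z and a
negative-binomial likelihood per gene whose mean is the cell's library size
times a decoded proportion.  Amortized variational inference (a VAE with
one hidden layer in encoder and decoder) fits the model on development
cells only.

Null sampling uses the fixed-posterior-sample scheme: one particle
z-bar ~ q(z | x, s) is drawn per validation cell, cached, and every
synthetic count for every gene, group and Monte-Carlo replicate is drawn
i.i.d. from NB(mean(z-bar, s), dispersion).  Caching a single z-bar per
cell is what makes group resampling factorize and keeps the whole CRT a
matter of cheap forward passes.  Sampling never sees the response: the
API has no response argument.

The model is implemented directly in NumPy (hand-written gradients, Adam);
at the scale this package targets a few thousand cells by a few hundred
genes fit in seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

from ._seeds import rng_for
from .data import CountDataset

_LOGVAR_MIN, _LOGVAR_MAX = -15.0, 10.0
_EPS = 1e-8


@dataclass(frozen=True)
class PosteriorCache:
    """Fixed posterior particles and the decoded null distribution.

    One z-bar per validation cell, drawn once and reused for every gene,
    group and Monte-Carlo replicate.  ``proportions`` are the decoder's
    library-size-free mean proportions at z-bar (rows sum to 1);
    ``library`` is the observed total count per cell; ``dispersions`` are
    the per-gene NB inverse-dispersion parameters.
    """

    zbar: np.ndarray           # N_val x d
    proportions: np.ndarray    # N_val x G
    dispersions: np.ndarray    # G
    library: np.ndarray        # N_val
    gene_names: tuple
    seed: int

    def __post_init__(self):
        for name in ("zbar", "proportions", "dispersions", "library"):
            arr = getattr(self, name)
            arr.setflags(write=False)

    @property
    def means(self) -> np.ndarray:
        """NB means at z-bar: library * proportion."""
        return self.library[:, None] * self.proportions


@runtime_checkable
class GenerativeModel(Protocol):
    """Pluggable contract: anything that can fit, cache and decode.

    A simpler model (e.g. per-gene NB with constant proportions) can stand
    in for the VAE; validity of the CRT depends only on the model
    describing the gene-gene dependence structure well.
    """

    def fit(self, dev_data: CountDataset, seed: int) -> "GenerativeModel": ...

    def make_cache(self, val_data: CountDataset, seed: int) -> PosteriorCache: ...


def nb_nll(x: np.ndarray, mean: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Elementwise negative log-likelihood of NB(mean, theta)."""
    m = mean + _EPS
    ll = (gammaln(x + theta) - gammaln(theta) - gammaln(x + 1.0)
          + theta * np.log(theta / (theta + m)) + x * np.log(m / (theta + m)))
    return -ll


def sample_nb(rng: np.random.Generator, mean: np.ndarray, theta: np.ndarray,
              size=None) -> np.ndarray:
    """NB draws via the gamma-Poisson mixture."""
    lam = rng.gamma(shape=theta, scale=(mean + _EPS) / theta, size=size)
    return rng.poisson(lam).astype(float)


class NBVAE:
    """Conditional NB variational autoencoder, NumPy implementation.

    One ReLU hidden layer in encoder and decoder; nuisance covariates are
    concatenated to both encoder and decoder inputs (the standard
    conditional-VAE scheme).  Decoder outputs softmax proportions scaled
    by the observed library size; dispersion is a free per-gene parameter.

    Defaults (latent_dim 10, 128 hidden units, lr 1e-3, KL warmup over 40
    epochs, early stopping on a 10% slice of the development cells with
    patience 10, max 400 epochs) are sized for desk-scale data and all
    exposed.  Model fit quality is a calibration parameter, not just a
    likelihood one: a decoder that misrepresents the conditional means of
    genes correlated with informative ones surfaces as false positives,
    while one that overfits the development cells does the same on the
    validation side.
    """

    def __init__(self, latent_dim: int = 10, hidden: int = 128, lr: float = 1e-3,
                 max_epochs: int = 400, batch_size: int = 256, patience: int = 10,
                 kl_warmup_epochs: int = 40, seed: int = 0):
        self.latent_dim = latent_dim
        self.hidden = hidden
        self.lr = lr
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.kl_warmup_epochs = kl_warmup_epochs
        self.seed = seed
        self.params: dict[str, np.ndarray] | None = None
        self.gene_names: tuple = ()
        self.n_nuisance = 0
        self.training_log: list[float] = []

    # -- architecture ------------------------------------------------------

    def _init_params(self, n_genes: int, n_nuis: int, rng) -> dict:
        d, h = self.latent_dim, self.hidden
        gin, din = n_genes + n_nuis, d + n_nuis

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        return {
            "We1": he((gin, h), gin), "be1": np.zeros(h),
            "Wm": he((h, d), h) * 0.1, "bm": np.zeros(d),
            "Wv": he((h, d), h) * 0.01, "bv": np.full(d, -1.0),
            "Wd1": he((din, h), din), "bd1": np.zeros(h),
            "Wo": he((h, n_genes), h) * 0.1, "bo": np.zeros(n_genes),
            "log_theta": np.zeros(n_genes),
        }

    def encode(self, counts: np.ndarray, nuisance: np.ndarray):
        p = self.params
        enc_in = np.column_stack([np.log1p(counts), nuisance])
        h = np.maximum(enc_in @ p["We1"] + p["be1"], 0.0)
        mu = h @ p["Wm"] + p["bm"]
        # only the upper bound matters at inference; a tiny scale is legitimate
        logvar = np.minimum(h @ p["Wv"] + p["bv"], _LOGVAR_MAX)
        return mu, logvar

    def decode_proportions(self, z: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
        p = self.params
        dec_in = np.column_stack([z, nuisance])
        h = np.maximum(dec_in @ p["Wd1"] + p["bd1"], 0.0)
        logits = h @ p["Wo"] + p["bo"]
        return np.exp(logits - logsumexp(logits, axis=1, keepdims=True))

    @property
    def dispersions(self) -> np.ndarray:
        return np.exp(self.params["log_theta"])

    # -- training ----------------------------------------------------------

    def fit(self, dev_data: CountDataset, seed: int | None = None) -> "NBVAE":
        if seed is not None:
            self.seed = seed
        if dev_data.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if dev_data.n_cells < 2:
            raise ValueError("development split is empty or too small")
        rng = rng_for(self.seed, "generative_fit")
        X = dev_data.counts.astype(float)
        S = dev_data.nuisance
        self.gene_names = tuple(dev_data.gene_names)
        self.n_nuisance = S.shape[1]
        n, g = X.shape
        self.params = self._init_params(g, S.shape[1], rng)

        # internal 10% early-stopping slice of dev
        n_eval = max(1, int(round(0.1 * n))) if n >= 10 else 0
        perm = rng.permutation(n)
        eval_idx, train_idx = perm[:n_eval], perm[n_eval:]
        Xtr, Str = X[train_idx], S[train_idx]
        Xev, Sev = X[eval_idx], S[eval_idx]

        m_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        v_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        t = 0
        best_loss, best_params, wait = np.inf, None, 0
        self.training_log = []

        for epoch in range(self.max_epochs):
            # KL warmup: anneal the prior term in so the decoder learns the
            # count structure before the posterior is squeezed
            beta = min(1.0, (epoch + 1) / max(1, self.kl_warmup_epochs))
            order = rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), self.batch_size):
                idx = order[start:start + self.batch_size]
                grads, loss = self._loss_and_grads(Xtr[idx], Str[idx], rng, beta)
                if not np.isfinite(loss):
                    raise RuntimeError(f"generative training diverged at epoch {epoch}")
                t += 1
                self._adam(grads, m_state, v_state, t)
            ev = self._eval_loss(Xev, Sev) if n_eval else self._eval_loss(Xtr, Str)
            if not np.isfinite(ev):
                raise RuntimeError(f"generative training diverged at epoch {epoch}")
            self.training_log.append(float(ev))
            if beta < 1.0:
                continue  # early stopping engages only at the full objective
            if ev < best_loss - 1e-4:
                best_loss, wait = ev, 0
                best_params = {k: v.copy() for k, v in self.params.items()}
            else:
                wait += 1
                if wait >= self.patience:
                    break
        if best_params is not None:
            self.params = best_params
        return self

    # log-dispersions move on a log scale spanning several units; with
    # Adam's unit-normalized steps they need a larger rate than the weights
    _LR_MULT = {"log_theta": 20.0}

    def _adam(self, grads, m_state, v_state, t, b1=0.9, b2=0.999, eps=1e-8):
        for k, gr in grads.items():
            m_state[k] = b1 * m_state[k] + (1 - b1) * gr
            v_state[k] = b2 * v_state[k] + (1 - b2) * gr * gr
            mhat = m_state[k] / (1 - b1 ** t)
            vhat = v_state[k] / (1 - b2 ** t)
            lr = self.lr * self._LR_MULT.get(k, 1.0)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        np.clip(self.params["log_theta"], -8.0, 12.0, out=self.params["log_theta"])

    def _loss_and_grads(self, X, S, rng, beta=1.0):
        p = self.params
        B = len(X)
        lib = X.sum(axis=1)
        theta = np.exp(p["log_theta"])

        enc_in = np.column_stack([np.log1p(X), S])
        he_pre = enc_in @ p["We1"] + p["be1"]
        he = np.maximum(he_pre, 0.0)
        mu = he @ p["Wm"] + p["bm"]
        lv_raw = he @ p["Wv"] + p["bv"]
        lv = np.clip(lv_raw, _LOGVAR_MIN, _LOGVAR_MAX)
        sig = np.exp(0.5 * lv)
        eps_z = rng.standard_normal(mu.shape)
        z = mu + sig * eps_z

        dec_in = np.column_stack([z, S])
        hd_pre = dec_in @ p["Wd1"] + p["bd1"]
        hd = np.maximum(hd_pre, 0.0)
        logits = hd @ p["Wo"] + p["bo"]
        rho = np.exp(logits - logsumexp(logits, axis=1, keepdims=True))
        m = lib[:, None] * rho + _EPS

        nll = nb_nll(X, m - _EPS, theta)
        kl = 0.5 * np.sum(mu ** 2 + np.exp(lv) - 1.0 - lv, axis=1)
        loss = float(np.mean(nll.sum(axis=1) + beta * kl))

        # gradients of the mean loss
        dndm = -(X / m - (X + theta) / (m + theta)) / B
        g_rho = dndm * lib[:, None]
        g_logits = rho * (g_rho - np.sum(g_rho * rho, axis=1, keepdims=True))
        dndtheta = -(digamma(X + theta) - digamma(theta)
                     + np.log(theta / (theta + m)) + 1.0
                     - (X + theta) / (theta + m)) / B
        g_log_theta = (dndtheta * theta).sum(axis=0)

        g_hd = g_logits @ p["Wo"].T
        g_hd_pre = g_hd * (hd_pre > 0)
        g_dec_in = g_hd_pre @ p["Wd1"].T
        g_z = g_dec_in[:, :self.latent_dim]

        g_mu = g_z + beta * mu / B
        g_lv = (g_z * eps_z * 0.5 * sig + beta * 0.5 * (np.exp(lv) - 1.0) / B)
        g_lv = g_lv * ((lv_raw > _LOGVAR_MIN) & (lv_raw < _LOGVAR_MAX))

        g_he = g_mu @ p["Wm"].T + g_lv @ p["Wv"].T
        g_he_pre = g_he * (he_pre > 0)

        grads = {
            "We1": enc_in.T @ g_he_pre, "be1": g_he_pre.sum(axis=0),
            "Wm": he.T @ g_mu, "bm": g_mu.sum(axis=0),
            "Wv": he.T @ g_lv, "bv": g_lv.sum(axis=0),
            "Wd1": dec_in.T @ g_hd_pre, "bd1": g_hd_pre.sum(axis=0),
            "Wo": hd.T @ g_logits, "bo": g_logits.sum(axis=0),
            "log_theta": g_log_theta,
        }
        return grads, loss

    def _eval_loss(self, X, S) -> float:
        """Deterministic ELBO proxy: z at the posterior mean, analytic KL."""
        lib = X.sum(axis=1)
        mu, lv = self.encode(X, S)
        rho = self.decode_proportions(mu, S)
        m = lib[:, None] * rho
        nll = nb_nll(X, m, self.dispersions).sum(axis=1)
        kl = 0.5 * np.sum(mu ** 2 + np.exp(lv) - 1.0 - lv, axis=1)
        return float(np.mean(nll + kl))

    def held_out_loss(self, data: CountDataset) -> float:
        """Mean per-cell negative ELBO proxy on arbitrary cells."""
        return self._eval_loss(data.counts.astype(float), data.nuisance)

    # -- caching -----------------------------------------------------------

    def make_cache(self, val_data: CountDataset, seed: int) -> PosteriorCache:
        if tuple(val_data.gene_names) != self.gene_names:
            raise ValueError("validation gene set does not match the fitted model")
        X = val_data.counts.astype(float)
        S = val_data.nuisance
        mu, lv = self.encode(X, S)
        rng = rng_for(seed, "posterior_cache")
        zbar = mu + np.exp(0.5 * lv) * rng.standard_normal(mu.shape)
        rho = self.decode_proportions(zbar, S)
        return PosteriorCache(zbar=zbar, proportions=rho,
                              dispersions=self.dispersions.copy(),
                              library=X.sum(axis=1), gene_names=self.gene_names,
                              seed=seed)

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        np.savez(path,
                 __config=np.array([self.latent_dim, self.hidden, self.lr,
                                    self.max_epochs, self.batch_size,
                                    self.patience, self.seed, self.n_nuisance]),
                 __genes=np.array(self.gene_names, dtype=object),
                 **self.params)

    @classmethod
    def load(cls, path: str) -> "NBVAE":
        with np.load(path, allow_pickle=True) as z:
            cfg = z["__config"]
            model = cls(latent_dim=int(cfg[0]), hidden=int(cfg[1]), lr=float(cfg[2]),
                        max_epochs=int(cfg[3]), batch_size=int(cfg[4]),
                        patience=int(cfg[5]), seed=int(cfg[6]))
            model.n_nuisance = int(cfg[7])
            model.gene_names = tuple(z["__genes"].tolist())
            model.params = {k: z[k] for k in z.files if not k.startswith("__")}
        return model


class PerGeneNBModel:
    """Minimal pluggable model: constant proportions, no latent structure.

    Fits one NB per gene with a shared proportion across cells (moment
    estimate of the dispersion).  Useful as a model-free fallback and as a
    demonstration that the CRT machinery only requires the pluggable
    fit / cache contract.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed
        self.proportions_: np.ndarray | None = None
        self.dispersions_: np.ndarray | None = None
        self.gene_names: tuple = ()

    def fit(self, dev_data: CountDataset, seed: int | None = None) -> "PerGeneNBModel":
        X = dev_data.counts.astype(float)
        lib = X.sum(axis=1)
        self.gene_names = tuple(dev_data.gene_names)
        p = X.sum(axis=0) / lib.sum()
        mean_g = lib[:, None] * p
        var_hat = np.var(X - mean_g, axis=0) + _EPS
        excess = np.maximum(var_hat - mean_g.mean(axis=0), _EPS)
        self.dispersions_ = np.clip((mean_g ** 2).mean(axis=0) / excess, 1e-2, 1e6)
        self.proportions_ = p
        return self

    def make_cache(self, val_data: CountDataset, seed: int) -> PosteriorCache:
        if tuple(val_data.gene_names) != self.gene_names:
            raise ValueError("validation gene set does not match the fitted model")
        n = val_data.n_cells
        rho = np.tile(self.proportions_, (n, 1))
        return PosteriorCache(zbar=np.zeros((n, 1)), proportions=rho,
                              dispersions=self.dispersions_.copy(),
                              library=val_data.counts.sum(axis=1).astype(float),
                              gene_names=self.gene_names, seed=seed)


# ---------------------------------------------------------------------------
# Module-level operations on a cache
# ---------------------------------------------------------------------------

def fit_generative(dev_data: CountDataset, config: dict | None = None,
                   seed: int = 0) -> NBVAE:
    """Fit the NB-VAE on development cells with config overrides."""
    cfg = dict(config or {})
    model = NBVAE(latent_dim=cfg.get("latent_dim", 10),
                  hidden=cfg.get("hidden", 128),
                  lr=cfg.get("lr", 1e-3),
                  max_epochs=cfg.get("max_epochs", 400),
                  batch_size=cfg.get("batch_size", 256),
                  patience=cfg.get("patience", 10),
                  seed=seed)
    return model.fit(dev_data)


def draw_posterior_cache(model: GenerativeModel, val_data: CountDataset,
                         seed: int = 0) -> PosteriorCache:
    """One fixed z-bar per validation cell, plus the decoded null law."""
    return model.make_cache(val_data, seed)


def sample_null_features(model: GenerativeModel, cache: PosteriorCache,
                         target: np.ndarray, n_mc: int, seed: int = 0) -> np.ndarray:
    """K x N_val x |A| synthetic counts for the genes in ``target``.

    Entries are i.i.d. NB draws given the cached z-bar, independent across
    cells, genes and Monte-Carlo replicates (the factorized conditional).
    Each gene has its own seed substream keyed by gene index, so values do
    not depend on batching, gene order, or which other genes share the
    group; singleton groups reproduce gene-level draws exactly.
    """
    target = np.atleast_1d(np.asarray(target, dtype=int))
    if target.size == 0:
        raise ValueError("target gene set is empty")
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    g_total = cache.proportions.shape[1]
    if np.any((target < 0) | (target >= g_total)):
        raise IndexError("target gene index out of range")
    n = cache.proportions.shape[0]
    means = cache.library[:, None] * cache.proportions
    out = np.empty((n_mc, n, target.size))
    for j, g in enumerate(target):
        rng = rng_for(seed, "null_draws", int(g))
        out[:, :, j] = sample_nb(rng, np.broadcast_to(means[:, g], (n_mc, n)),
                                 cache.dispersions[g])
    return out


def normalized_expression(model: GenerativeModel, cache: PosteriorCache) -> np.ndarray:
    """Library-size-free decoder mean proportions; rows sum to 1."""
    return np.asarray(cache.proportions)
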