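"""Importance scores: predictive models of the response with per-cell NLL.

The CRT's test statistic is the average validation-set negative
log-likelihood of a predictor p(y | x, s) fit on development cells:

    T(X, Y, S) = (1/N) sum_n -log p(y_n | x_n, s_n).

Any predictor yields a valid test — a poor one only costs power, never
calibration — so the module exposes a small family (linear Gaussian,
one-hidden-layer MLP for Gaussian or Bernoulli responses, a constant
baseline) plus a plug-in contract for external models: any object with
``per_cell_nll(X, y, S) -> (N,) array`` runs end-to-end in the engine.

Predictors consume raw counts and apply their own feature transform
(log1p by default, configurable to raw); the identical transform is
applied to observed and synthetic columns so the score comparison is
well defined.  Continuous responses use a Gaussian NLL with a single
learned variance, which orders scores identically to MSE but keeps the
statistic on the same scale as the Bernoulli case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier, MLPRegressor

from ._seeds import rng_for, small_int_seed

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)
_P_CLIP = 1e-12

_FAMILY_RANK = {"constant": 0, "linear_gaussian": 1, "mlp_gaussian": 2,
                "mlp_bernoulli": 2, "plugin": 3}


def _transform(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "log1p":
        return np.log1p(x)
    if kind == "raw":
        return np.asarray(x, dtype=float)
    raise ValueError(f"unknown feature transform {kind!r}")


def gaussian_nll(y: np.ndarray, pred: np.ndarray, var: float) -> np.ndarray:
    r = y - pred
    return _HALF_LOG_2PI + 0.5 * np.log(var) + r * r / (2.0 * var)


def bernoulli_nll(y: np.ndarray, prob: np.ndarray) -> np.ndarray:
    p = np.clip(prob, _P_CLIP, 1.0 - _P_CLIP)
    return -(y * np.log(p) + (1.0 - y) * np.log1p(-p))


class _BasePredictor:
    """Shared plumbing: feature assembly and the replaced-column fast path."""

    family = "base"
    response_family = "gaussian"

    def __init__(self, transform: str = "log1p"):
        self.transform = transform
        self.fit_log: dict = {}

    def _features(self, X: np.ndarray, S: np.ndarray | None) -> np.ndarray:
        F = _transform(X, self.transform)
        if S is not None and S.shape[1] > 0:
            F = np.column_stack([F, S])
        return F

    def per_cell_nll(self, X, y, S=None) -> np.ndarray:
        raise NotImplementedError

    def per_cell_nll_replaced(self, X, y, S, cols, synth) -> np.ndarray:
        """(K, N) NLLs with columns ``cols`` of X replaced by synth[k].

        Generic fallback materializes each replaced matrix; linear and MLP
        subclasses override with a rank-|cols| hidden-layer update.
        """
        cols = np.atleast_1d(np.asarray(cols, dtype=int))
        out = np.empty((synth.shape[0], len(y)))
        Xk = np.array(X, dtype=float, copy=True)
        for k in range(synth.shape[0]):
            Xk[:, cols] = synth[k]
            out[k] = self.per_cell_nll(Xk, y, S)
        return out


class LinearGaussianPredictor(_BasePredictor):
    """OLS of y on features with a learned homoscedastic variance."""

    family = "linear_gaussian"
    response_family = "gaussian"

    def fit(self, X, y, S=None, seed: int = 0) -> "LinearGaussianPredictor":
        F = self._features(X, S)
        A = np.column_stack([np.ones(len(F)), F])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]
        resid = y - A @ coef
        self.var_ = float(max(np.mean(resid ** 2), 1e-12))
        return self

    def predict(self, X, S=None) -> np.ndarray:
        return self.intercept_ + self._features(X, S) @ self.coef_

    def per_cell_nll(self, X, y, S=None) -> np.ndarray:
        return gaussian_nll(np.asarray(y, float), self.predict(X, S), self.var_)

    def per_cell_nll_replaced(self, X, y, S, cols, synth) -> np.ndarray:
        cols = np.atleast_1d(np.asarray(cols, dtype=int))
        base = self.predict(X, S)
        f_obs = _transform(np.asarray(X, float)[:, cols], self.transform)
        delta = _transform(synth, self.transform) - f_obs[None, :, :]
        preds = base[None, :] + delta @ self.coef_[cols]
        return gaussian_nll(np.asarray(y, float)[None, :], preds, self.var_)


class _MLPMixin:
    """NumPy forward pass over a fitted one-hidden-layer sklearn MLP."""

    def _extract(self, net):
        self.W1_, self.W2_ = [w.copy() for w in net.coefs_]
        self.b1_, self.b2_ = [b.copy() for b in net.intercepts_]

    def _hidden_pre(self, F):
        return F @ self.W1_ + self.b1_

    def _out_from_hidden(self, Hpre):
        return np.maximum(Hpre, 0.0) @ self.W2_ + self.b2_

    def _replaced_hidden(self, X, S, cols, synth):
        cols = np.atleast_1d(np.asarray(cols, dtype=int))
        H0 = self._hidden_pre(self._features(X, S))
        f_obs = _transform(np.asarray(X, float)[:, cols], self.transform)
        delta = _transform(synth, self.transform) - f_obs[None, :, :]
        # feature columns of genes coincide with gene indices (transform block first)
        return H0[None, :, :] + delta @ self.W1_[cols]


class MLPGaussianPredictor(_BasePredictor, _MLPMixin):
    """One-hidden-layer (64 unit, ReLU) regressor with Gaussian NLL."""

    family = "mlp_gaussian"
    response_family = "gaussian"

    def __init__(self, hidden_units: int = 64, max_epochs: int = 1000,
                 lr: float = 1e-3, transform: str = "log1p"):
        super().__init__(transform)
        self.hidden_units = hidden_units
        self.max_epochs = max_epochs
        self.lr = lr

    def fit(self, X, y, S=None, seed: int = 0) -> "MLPGaussianPredictor":
        F = self._features(X, S)
        net = MLPRegressor(hidden_layer_sizes=(self.hidden_units,),
                           activation="relu", solver="adam",
                           learning_rate_init=self.lr, max_iter=self.max_epochs,
                           early_stopping=True, validation_fraction=0.15,
                           n_iter_no_change=20, random_state=seed)
        net.fit(F, y)
        self._extract(net)
        resid = y - self._out_from_hidden(self._hidden_pre(F)).ravel()
        self.var_ = float(max(np.mean(resid ** 2), 1e-12))
        return self

    def predict(self, X, S=None) -> np.ndarray:
        return self._out_from_hidden(self._hidden_pre(self._features(X, S))).ravel()

    def per_cell_nll(self, X, y, S=None) -> np.ndarray:
        return gaussian_nll(np.asarray(y, float), self.predict(X, S), self.var_)

    def per_cell_nll_replaced(self, X, y, S, cols, synth) -> np.ndarray:
        H = self._replaced_hidden(X, S, cols, synth)          # K x N x h
        preds = self._out_from_hidden(H)[:, :, 0]
        return gaussian_nll(np.asarray(y, float)[None, :], preds, self.var_)


class MLPBernoulliPredictor(_BasePredictor, _MLPMixin):
    """One-hidden-layer classifier with Bernoulli log-loss."""

    family = "mlp_bernoulli"
    response_family = "bernoulli"

    def __init__(self, hidden_units: int = 64, max_epochs: int = 1000,
                 lr: float = 1e-3, transform: str = "log1p"):
        super().__init__(transform)
        self.hidden_units = hidden_units
        self.max_epochs = max_epochs
        self.lr = lr

    def fit(self, X, y, S=None, seed: int = 0) -> "MLPBernoulliPredictor":
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("bernoulli predictor requires a 0/1 response")
        F = self._features(X, S)
        net = MLPClassifier(hidden_layer_sizes=(self.hidden_units,),
                            activation="relu", solver="adam",
                            learning_rate_init=self.lr, max_iter=self.max_epochs,
                            early_stopping=True, validation_fraction=0.15,
                            n_iter_no_change=20, random_state=seed)
        net.fit(F, y.astype(int))
        self._extract(net)
        return self

    def predict_proba(self, X, S=None) -> np.ndarray:
        logit = self._out_from_hidden(self._hidden_pre(self._features(X, S))).ravel()
        return 1.0 / (1.0 + np.exp(-logit))

    def per_cell_nll(self, X, y, S=None) -> np.ndarray:
        return bernoulli_nll(np.asarray(y, float), self.predict_proba(X, S))

    def per_cell_nll_replaced(self, X, y, S, cols, synth) -> np.ndarray:
        H = self._replaced_hidden(X, S, cols, synth)
        prob = 1.0 / (1.0 + np.exp(-self._out_from_hidden(H)[:, :, 0]))
        return bernoulli_nll(np.asarray(y, float)[None, :], prob)


class ConstantPredictor(_BasePredictor):
    """Intercept-only model; a deliberately uninformative importance score.

    Useful for calibration checks: the CRT stays valid with it, it just
    has no power.
    """

    family = "constant"

    def __init__(self, response_family: str = "gaussian"):
        super().__init__("log1p")
        self.response_family = response_family

    def fit(self, X, y, S=None, seed: int = 0) -> "ConstantPredictor":
        if self.response_family == "bernoulli":
            self.rate_ = float(np.clip(np.mean(y), _P_CLIP, 1 - _P_CLIP))
        else:
            self.mean_ = float(np.mean(y))
            self.var_ = float(max(np.var(y), 1e-12))
        return self

    def per_cell_nll(self, X, y, S=None) -> np.ndarray:
        y = np.asarray(y, float)
        if self.response_family == "bernoulli":
            return bernoulli_nll(y, np.full_like(y, self.rate_))
        return gaussian_nll(y, np.full_like(y, self.mean_), self.var_)

    def per_cell_nll_replaced(self, X, y, S, cols, synth) -> np.ndarray:
        return np.tile(self.per_cell_nll(X, y, S), (synth.shape[0], 1))


@dataclass
class PluginPredictor:
    """Adapter accepting any external model under the plug-in contract.

    ``nll_fn(X, y, S) -> (N,)`` must return per-cell negative
    log-likelihoods (or any per-cell prediction loss; only comparisons
    between observed and synthetic scores matter).  The external model is
    fit once on development data by its owner; it is never refit per
    Monte-Carlo replicate.
    """

    nll_fn: object
    family: str = "plugin"
    response_family: str = "gaussian"
    fit_log: dict = field(default_factory=dict)

    def fit(self, X, y, S=None, seed: int = 0) -> "PluginPredictor":
        return self

    def per_cell_nll(self, X, y, S=None) -> np.ndarray:
        out = np.asarray(self.nll_fn(X, y, S), dtype=float).ravel()
        if len(out) != len(y):
            raise ValueError("plugin returned wrong number of per-cell losses")
        return out

    def per_cell_nll_replaced(self, X, y, S, cols, synth) -> np.ndarray:
        return _BasePredictor.per_cell_nll_replaced(self, X, y, S, cols, synth)

    def _features(self, X, S):  # pragma: no cover - unused, contract only
        raise NotImplementedError


PREDICTOR_FAMILIES = {
    "linear_gaussian": LinearGaussianPredictor,
    "mlp_gaussian": MLPGaussianPredictor,
    "mlp_bernoulli": MLPBernoulliPredictor,
    "constant": ConstantPredictor,
}


def fit_predictor(dev_X: np.ndarray, dev_y, dev_S: np.ndarray | None = None,
                  family: str = "mlp_gaussian", config: dict | None = None,
                  seed: int = 0):
    """Fit a predictor on development data and record its held-out loss.

    A 15% evaluation slice of the development cells (shared across
    families for a given seed, so candidates are comparable) is held out;
    the recorded mean NLL on it is the model-selection criterion used by
    :func:`select_predictor`.
    """
    from .data import ResponseVector

    yv = dev_y.values if isinstance(dev_y, ResponseVector) else np.asarray(dev_y, float)
    yfam = dev_y.family if isinstance(dev_y, ResponseVector) else None
    if family not in PREDICTOR_FAMILIES:
        raise ValueError(f"unknown predictor family {family!r}")
    cfg = dict(config or {})
    cls = PREDICTOR_FAMILIES[family]
    kwargs = {}
    if family.startswith("mlp"):
        kwargs = {k: cfg[k] for k in ("hidden_units", "max_epochs", "lr") if k in cfg}
    if "transform" in cfg and family != "constant":
        kwargs["transform"] = cfg["transform"]
    if family == "constant":
        kwargs = {"response_family": yfam or "gaussian"}
    model = cls(**kwargs)
    if yfam is not None:
        if model.response_family == "bernoulli" and yfam != "bernoulli":
            raise ValueError(f"{family} predictor is incompatible with a "
                             f"{yfam} response")
        if model.response_family == "gaussian" and yfam == "bernoulli":
            raise ValueError(f"{family} predictor is incompatible with a "
                             f"bernoulli response")

    n = len(yv)
    n_eval = max(1, int(round(0.15 * n)))
    perm = rng_for(seed, "predictor_fit", 0).permutation(n)
    ev, tr = perm[:n_eval], perm[n_eval:]
    Se = None if dev_S is None else dev_S[ev]
    St = None if dev_S is None else dev_S[tr]
    fit_seed = small_int_seed(seed, "predictor_fit", 1)
    model.fit(np.asarray(dev_X, float)[tr], yv[tr], St, seed=fit_seed)
    model.fit_log = {"holdout_loss": float(np.mean(
        model.per_cell_nll(np.asarray(dev_X, float)[ev], yv[ev], Se)))}
    # the evaluation slice served model selection; the returned model is
    # refit on the full development split (select-then-refit)
    model.fit(np.asarray(dev_X, float), yv, dev_S, seed=fit_seed)
    return model


def importance_score(model, X, Y, S=None) -> float:
    """Average per-cell NLL over validation cells (the test statistic)."""
    from .data import ResponseVector

    yv = Y.values if isinstance(Y, ResponseVector) else np.asarray(Y, float)
    if len(yv) == 0:
        raise ValueError("validation set is empty")
    return float(np.mean(model.per_cell_nll(np.asarray(X, float), yv, S)))


def select_predictor(candidates: list):
    """Pick the candidate with the best held-out predictive loss.

    Ties go to the simplest family (constant < linear < mlp < plugin):
    predictive performance is the criterion for choosing the importance
    score, and a simpler model is preferred when it predicts as well.
    """
    if not candidates:
        raise ValueError("no candidate predictors")
    for c in candidates:
        if "holdout_loss" not in getattr(c, "fit_log", {}):
            raise ValueError("candidate lacks a recorded held-out loss")
    return min(candidates,
               key=lambda c: (c.fit_log["holdout_loss"],
                              _FAMILY_RANK.get(c.family, 99)))
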