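"""Classifier families under a uniform train/predict contract.

Four model kinds: random forest, gradient-boosted trees (LightGBM),
L2-regularized logistic regression, and a self-attention neural network
implemented here from scratch in numpy.

The attention network computes, for input vector ``inp``,

    W_att = softmax(W @ inp + b)        (attention weights, sum to 1)
    v     = W_att * inp                 (element-wise reweighting)
    p     = MLP(v)                      (dense 512 -> BN -> ReLU -> dropout,
                                         sigmoid output)

trained with binary cross-entropy, Adam, minibatches of 32, up to 100
epochs with early stopping on a stratified validation split. Because the
attention weights are a function of the input itself, they double as a
per-compound feature attribution.

Gradients are derived by hand (softmax Jacobian, batch-norm backward,
inverted dropout) and checked against finite differences in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import randint, uniform
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RandomizedSearchCV
import lightgbm as lgb

from .featurize import ScalerState, apply_scaler

_BN_EPS = 1e-5


def _softmax(a: np.ndarray) -> np.ndarray:
    z = a - a.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class AttentionNetwork:
    """Self-attention feed-forward binary classifier (numpy, CPU).

    Parameters
    ----------
    input_dim : feature dimension; attention layer is input_dim x input_dim.
    hidden : hidden layer widths of the MLP head (default one 512 layer).
    dropout : dropout rate after each hidden layer (0.25 as published).
    lr : Adam learning rate.
    seed : controls initialization, shuffling, dropout and the
        validation split; a fixed seed makes training fully reproducible.
    """

    def __init__(
        self,
        input_dim: int,
        hidden: Sequence[int] = (512,),
        dropout: float = 0.25,
        lr: float = 1e-3,
        seed: int = 0,
    ):
        if not 0 <= dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        self.input_dim = int(input_dim)
        self.hidden = tuple(int(h) for h in hidden)
        self.dropout = float(dropout)
        self.lr = float(lr)
        self.seed = int(seed)
        self.history_: list[dict] = []
        self._rng = np.random.default_rng(seed)
        self._init_params()

    # -- parameters ---------------------------------------------------------

    def _init_params(self) -> None:
        rng = self._rng
        D = self.input_dim
        p: dict[str, np.ndarray] = {}
        # attention layer: small-variance init, zero bias (He init is only
        # used for the ReLU dense layers)
        p["Wa"] = rng.normal(0.0, 0.01, size=(D, D))
        p["ba"] = np.zeros(D)
        fan_in = D
        for i, h in enumerate(self.hidden):
            p[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(h, fan_in))
            p[f"b{i}"] = np.zeros(h)
            p[f"gamma{i}"] = np.ones(h)
            p[f"beta{i}"] = np.zeros(h)
            fan_in = h
        p["Wo"] = rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(1, fan_in))
        p["bo"] = np.zeros(1)
        self.params = p
        # batch-norm running statistics (not trained by gradient)
        self.running = {
            f"mean{i}": np.zeros(h) for i, h in enumerate(self.hidden)
        } | {f"var{i}": np.ones(h) for i, h in enumerate(self.hidden)}

    # -- forward ------------------------------------------------------------

    def forward(self, X: np.ndarray, training: bool = False, rng=None) -> dict:
        """Full forward pass; returns a cache with W_att, v, p and layerwise
        intermediates (used for backprop when ``training``)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"input dim {X.shape[1]} != model dim {self.input_dim}"
            )
        p = self.params
        cache: dict = {"X": X}
        a = X @ p["Wa"].T + p["ba"]
        s = _softmax(a)
        v = s * X
        cache["s"], cache["v"] = s, v
        h = v
        cache["layers"] = []
        for i in range(len(self.hidden)):
            z = h @ p[f"W{i}"].T + p[f"b{i}"]
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                m = 0.9
                self.running[f"mean{i}"] = m * self.running[f"mean{i}"] + (1 - m) * mu
                self.running[f"var{i}"] = m * self.running[f"var{i}"] + (1 - m) * var
            else:
                mu = self.running[f"mean{i}"]
                var = self.running[f"var{i}"]
            inv_sd = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mu) * inv_sd
            bn = p[f"gamma{i}"] * zhat + p[f"beta{i}"]
            relu = np.maximum(bn, 0.0)
            if training and self.dropout > 0:
                if rng is None:
                    rng = self._rng
                mask = (rng.random(relu.shape) >= self.dropout) / (1 - self.dropout)
            else:
                mask = None
            out = relu * mask if mask is not None else relu
            cache["layers"].append(
                {"h_in": h, "z": z, "mu": mu, "var": var, "inv_sd": inv_sd,
                 "zhat": zhat, "bn": bn, "relu": relu, "mask": mask}
            )
            h = out
        logit = h @ p["Wo"].T + p["bo"]
        prob = _sigmoid(logit)
        cache["h_last"], cache["logit"], cache["p"] = h, logit, prob
        return cache

    def attention(self, X: np.ndarray) -> np.ndarray:
        """Attention weight vectors W_att (rows sum to 1)."""
        return self.forward(X, training=False)["s"]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) class probabilities, sklearn column convention."""
        p1 = self.forward(X, training=False)["p"].ravel()
        return np.column_stack([1 - p1, p1])

    # -- backward -----------------------------------------------------------

    def _loss_and_grads(self, X, y, training: bool = True, rng=None):
        y = np.asarray(y, dtype=float).ravel()
        cache = self.forward(X, training=training, rng=rng)
        prob = cache["p"].ravel()
        eps = 1e-12
        loss = -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
        B = len(y)
        p = self.params
        g = {k: np.zeros_like(v) for k, v in p.items()}

        dlogit = ((prob - y) / B)[:, None]
        g["Wo"] = dlogit.T @ cache["h_last"]
        g["bo"] = dlogit.sum(axis=0)
        dh = dlogit @ p["Wo"]
        for i in reversed(range(len(self.hidden))):
            lc = cache["layers"][i]
            if lc["mask"] is not None:
                dh = dh * lc["mask"]
            drelu = dh * (lc["bn"] > 0)
            g[f"gamma{i}"] = (drelu * lc["zhat"]).sum(axis=0)
            g[f"beta{i}"] = drelu.sum(axis=0)
            dzhat = drelu * p[f"gamma{i}"]
            if training:
                # batch statistics participate in the graph
                z, mu, inv_sd = lc["z"], lc["mu"], lc["inv_sd"]
                dvar = (dzhat * (z - mu)).sum(axis=0) * (-0.5) * inv_sd**3
                dmu = (-dzhat * inv_sd).sum(axis=0) + dvar * (-2.0 / B) * (z - mu).sum(axis=0)
                dz = dzhat * inv_sd + dvar * 2.0 * (z - mu) / B + dmu / B
            else:
                dz = dzhat * lc["inv_sd"]
            g[f"W{i}"] = dz.T @ lc["h_in"]
            g[f"b{i}"] = dz.sum(axis=0)
            dh = dz @ p[f"W{i}"]
        # attention block: v = s * X, s = softmax(X Wa^T + ba)
        X_arr, s = cache["X"], cache["s"]
        ds = dh * X_arr
        da = s * (ds - (ds * s).sum(axis=1, keepdims=True))
        g["Wa"] = da.T @ X_arr
        g["ba"] = da.sum(axis=0)
        return loss, g, cache

    # -- training -----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y,
        epochs: int = 100,
        batch_size: int = 32,
        val_fraction: float = 0.1,
        patience: int = 10,
    ) -> "AttentionNetwork":
        """Minibatch Adam training with early stopping.

        A stratified ``val_fraction`` of the data is held out; training
        stops when validation loss has not improved for ``patience``
        epochs and the best-validation parameters are restored.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int).ravel()
        if epochs < 1 or batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(self.seed + 1)

        # stratified validation split
        val_idx: list[int] = []
        if val_fraction > 0:
            for cls in (0, 1):
                idx = np.flatnonzero(y == cls)
                rng.shuffle(idx)
                k = max(1, int(round(val_fraction * len(idx))))
                val_idx.extend(idx[:k])
        val_idx = np.array(sorted(val_idx), dtype=int)
        train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
        Xtr, ytr = X[train_idx], y[train_idx]
        Xval, yval = X[val_idx], y[val_idx]

        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v_adam = {k: np.zeros_like(v) for k, v in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_val = np.inf
        best_params = None
        best_running = None
        stale = 0
        self.history_ = []
        for epoch in range(epochs):
            order = rng.permutation(len(ytr))
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, len(ytr), batch_size):
                bidx = order[start : start + batch_size]
                loss, grads, _ = self._loss_and_grads(Xtr[bidx], ytr[bidx], training=True, rng=rng)
                epoch_loss += loss
                n_batches += 1
                t += 1
                for k in self.params:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v_adam[k] = b2 * v_adam[k] + (1 - b2) * grads[k] ** 2
                    mh = m[k] / (1 - b1**t)
                    vh = v_adam[k] / (1 - b2**t)
                    self.params[k] -= self.lr * mh / (np.sqrt(vh) + eps)
            train_loss = epoch_loss / max(n_batches, 1)
            if len(val_idx):
                pv = self.forward(Xval, training=False)["p"].ravel()
                e = 1e-12
                val_loss = float(
                    -np.mean(yval * np.log(pv + e) + (1 - yval) * np.log(1 - pv + e))
                )
            else:
                val_loss = train_loss
            self.history_.append(
                {"epoch": epoch, "train_loss": float(train_loss), "val_loss": val_loss}
            )
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                best_running = {k: v.copy() for k, v in self.running.items()}
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
        if best_params is not None:
            self.params = best_params
            self.running = best_running
        return self

    # -- (de)serialization --------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "hidden": list(self.hidden),
            "dropout": self.dropout,
            "lr": self.lr,
            "seed": self.seed,
            "params": {k: v.tolist() for k, v in self.params.items()},
            "running": {k: v.tolist() for k, v in self.running.items()},
        }

    @classmethod
    def from_state_dict(cls, d: dict) -> "AttentionNetwork":
        net = cls(d["input_dim"], hidden=d["hidden"], dropout=d["dropout"],
                  lr=d["lr"], seed=d["seed"])
        net.params = {k: np.asarray(v, float) for k, v in d["params"].items()}
        net.running = {k: np.asarray(v, float) for k, v in d["running"].items()}
        return net


# ---------------------------------------------------------------------------
# baseline families and randomized hyperparameter search
# ---------------------------------------------------------------------------

BASELINE_KINDS = ("rf", "lgbm", "lr")


@dataclass
class SearchSpec:
    """Randomized hyperparameter search configuration (50 draws by default)."""

    kind: str
    iterations: int = 50
    cv: int = 5
    seed: int = 0
    distributions: dict | None = None

    def resolved_distributions(self) -> dict:
        if self.distributions is not None:
            return self.distributions
        if self.kind == "rf":
            return {
                "n_estimators": randint(100, 500),
                "max_features": ["sqrt", "log2", 0.1, 0.3, 0.5],
                "max_depth": [None, 5, 10, 20, 30],
            }
        if self.kind == "lgbm":
            return {
                "num_leaves": randint(8, 128),
                "n_estimators": randint(50, 400),
                "min_child_samples": randint(5, 50),
                "max_depth": [-1, 3, 5, 10, 20],
            }
        if self.kind == "lr":
            return {"max_iter": randint(100, 2000), "C": uniform(0.01, 10.0)}
        raise ValueError(f"unknown baseline kind {self.kind!r}")


@dataclass
class FittedBaseline:
    kind: str
    model: object
    best_params: dict | None = None
    search_log: list[dict] = field(default_factory=list)

    def predict_proba(self, X):
        with warnings.catch_warnings():
            # LightGBM's sklearn wrapper records synthetic feature names on
            # ndarray fits; the mismatch warning at predict time is spurious
            warnings.filterwarnings("ignore", message=".*valid feature names.*")
            return self.model.predict_proba(X)

    def fit(self, X, y):  # refit with the same hyperparameters (CV contract)
        self.model.fit(X, y)
        return self


def _make_estimator(kind: str, seed: int, params: dict | None = None):
    params = dict(params or {})
    if kind == "rf":
        params.setdefault("n_estimators", 200)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if kind == "lgbm":
        params.setdefault("n_estimators", 200)
        return lgb.LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **params)
    if kind == "lr":
        params.setdefault("max_iter", 1000)
        return LogisticRegression(random_state=seed, **params)
    raise ValueError(f"unknown baseline kind {kind!r}; expected one of {BASELINE_KINDS}")


def fit_baseline(
    kind: str,
    X: np.ndarray,
    y,
    params: dict | None = None,
    search: SearchSpec | None = None,
    seed: int = 0,
) -> FittedBaseline:
    """Fit one baseline family, optionally after randomized search.

    With a :class:`SearchSpec`, ``iterations`` random hyperparameter
    draws are scored by cross-validated AUROC and the best refit model is
    returned together with the full search log (one entry per draw).
    """
    y = np.asarray(y, dtype=int).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if search is None:
        est = _make_estimator(kind, seed, params)
        est.fit(np.asarray(X, float), y)
        return FittedBaseline(kind=kind, model=est, best_params=params)
    rs = RandomizedSearchCV(
        _make_estimator(kind, seed),
        param_distributions=search.resolved_distributions(),
        n_iter=search.iterations,
        cv=search.cv,
        scoring="roc_auc",
        random_state=search.seed,
        n_jobs=1,
        refit=True,
    )
    rs.fit(np.asarray(X, float), y)
    log = [
        {"params": {k: (v.item() if hasattr(v, "item") else v) for k, v in p.items()},
         "mean_cv_auroc": float(s)}
        for p, s in zip(rs.cv_results_["params"], rs.cv_results_["mean_test_score"])
    ]
    return FittedBaseline(kind=kind, model=rs.best_estimator_, best_params=rs.best_params_,
                          search_log=log)


def search_architecture(
    X: np.ndarray,
    y,
    layer_options: Sequence[int] = (1, 2, 3),
    node_options: Sequence[int] = (128, 256, 512, 1024),
    budget: int = 8,
    seed: int = 0,
    epochs: int = 20,
    val_fraction: float = 0.2,
) -> tuple[tuple[int, int], list[dict]]:
    """Sequential model-based search over (layer count, nodes per layer).

    Each evaluated configuration trains a short attention network and is
    scored by validation AUROC. After three observations a random-forest
    surrogate proposes the next candidate (highest predicted score among
    the unevaluated ones); before that — or if the surrogate cannot be
    fit — candidates are drawn at random.
    """
    from .evaluate import auroc

    if budget < 1:
        raise ValueError("budget must be >= 1")
    candidates = [(l, n) for l in layer_options for n in node_options]
    if not candidates:
        raise ValueError("empty search bounds")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, float)
    y = np.asarray(y, int).ravel()
    # fixed stratified holdout for scoring
    val_idx = []
    rs = np.random.default_rng(seed + 7)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rs.shuffle(idx)
        val_idx.extend(idx[: max(1, int(val_fraction * len(idx)))])
    val_idx = np.array(sorted(val_idx))
    tr_idx = np.setdiff1d(np.arange(len(y)), val_idx)

    def score(layers: int, nodes: int) -> float:
        net = AttentionNetwork(X.shape[1], hidden=(nodes,) * layers, seed=seed)
        net.fit(X[tr_idx], y[tr_idx], epochs=epochs, val_fraction=0.0, patience=epochs)
        return auroc(y[val_idx], net.predict_proba(X[val_idx])[:, 1])

    log: list[dict] = []
    remaining = list(candidates)
    for step in range(min(budget, len(candidates))):
        pick = None
        if len(log) >= 3:
            try:
                surr = RandomForestRegressor(n_estimators=50, random_state=seed)
                surr.fit(
                    np.array([[e["layers"], e["nodes"]] for e in log]),
                    np.array([e["score"] for e in log]),
                )
                preds = surr.predict(np.array(remaining, dtype=float))
                pick = remaining[int(np.argmax(preds))]
            except Exception:
                pick = None
        if pick is None:
            pick = remaining[int(rng.integers(len(remaining)))]
        remaining.remove(pick)
        log.append({"layers": pick[0], "nodes": pick[1], "score": float(score(*pick))})
    best = max(log, key=lambda e: e["score"])
    return (best["layers"], best["nodes"]), log


# ---------------------------------------------------------------------------
# portable model archive: estimator + scaler + featurization config
# ---------------------------------------------------------------------------


@dataclass
class DiliModel:
    """A fitted classifier bundled with its descriptor scaler.

    ``predict_proba`` accepts *raw* feature matrices (structural bits
    followed by unscaled descriptors) and applies the stored training-set
    standardization before prediction, so train/test scaling can never
    diverge.
    """

    kind: str  # rf | lgbm | lr | attn
    model: object
    scaler: ScalerState
    n_bits: int
    history: list[dict] = field(default_factory=list)
    search_log: list[dict] = field(default_factory=list)

    def transform(self, X_raw: np.ndarray) -> np.ndarray:
        X = np.asarray(X_raw, dtype=float)
        out = X.copy()
        out[:, self.n_bits :] = apply_scaler(self.scaler, X[:, self.n_bits :])
        return out

    def predict_proba(self, X_raw: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*valid feature names.*")
            return self.model.predict_proba(self.transform(X_raw))

    def attention(self, X_raw: np.ndarray) -> np.ndarray:
        if self.kind != "attn":
            raise ValueError("attention weights only exist for the attention network")
        return self.model.attention(self.transform(X_raw))

    def save(self, path) -> None:
        import joblib

        payload = {"kind": self.kind, "scaler": self.scaler.to_jsonable(),
                   "n_bits": self.n_bits, "history": self.history,
                   "search_log": self.search_log}
        if self.kind == "attn":
            payload["state"] = self.model.state_dict()
        else:
            payload["model"] = self.model
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "DiliModel":
        import joblib

        d = joblib.load(path)
        if d["kind"] == "attn":
            model = AttentionNetwork.from_state_dict(d["state"])
        else:
            model = d["model"]
        return cls(kind=d["kind"], model=model,
                   scaler=ScalerState.from_jsonable(d["scaler"]),
                   n_bits=d["n_bits"], history=d.get("history", []),
                   search_log=d.get("search_log", []))
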