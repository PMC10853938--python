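"""Dimensionality reduction, the dense network, training, and persistence.

The raw descriptor vector is z-scored and projected onto its leading
principal components, dropping the 9 trailing ones (58 -> 49 features for
water, 61 -> 52 for nonaqueous solvents); the projected coordinates are
scaled by their standard deviations.  The regressor is a small dense
network -- two ReLU hidden layers (16x8 aqueous, 14x7 nonaqueous) and a
linear output, all with biases -- trained by Nesterov-accelerated adaptive
moment estimation (Nadam) on a weighted mean squared error with an L2
weight penalty (lambda = 0.01 by default).

The parameter counts of the two stock architectures are
(49+1)*16 + (16+1)*8 + (8+1) = 945 and (52+1)*14 + (14+1)*7 + (7+1) = 855.

Because the hidden activations are rectifiers, the network output is
piecewise linear in its input, and when every hidden unit is inactive the
prediction equals the output-layer bias -- the model's hard ceiling for
weakly solvated solutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.decomposition import PCA

from .features import FeatureSchema, featurize
from .molecule import Molecule, SolventDescriptor

# --------------------------------------------------------------------------
# Dimensionality reduction


class FeatureReducer(TransformerMixin, BaseEstimator):
    """Z-score, project onto leading principal components, rescale.

    Parameters
    ----------
    n_drop : int
        Number of trailing (smallest-variance) components discarded;
        the output dimension is ``n_features - n_drop``.

    Attributes
    ----------
    center_ : per-feature means.
    scale_ : per-feature standard deviations (zero-variance features -> 1).
    components_ : orthonormal projection rows, signs fixed so each row's
        largest-magnitude loading is positive.
    comp_scale_ : standard deviation of each projected coordinate.
    """

    def __init__(self, n_drop: int = 9):
        self.n_drop = n_drop

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n_samples, n_feat = X.shape
        n_keep = n_feat - self.n_drop
        if n_keep < 1:
            raise ValueError("n_drop leaves no components")
        if n_samples <= n_keep:
            raise ValueError(
                f"need more than {n_keep} samples to fit a {n_keep}-component basis"
            )
        self.center_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 1e-12, sd, 1.0)
        Z = (X - self.center_) / self.scale_
        pca = PCA(n_components=n_keep, svd_solver="full")
        pca.fit(Z)
        if pca.explained_variance_[-1] < 1e-12 and self.n_drop > 0:
            import warnings

            warnings.warn(
                "feature matrix rank is below the target dimension; trailing "
                "components are null directions (their coordinates are zero "
                "on the training data) -- supply more varied data if possible",
                stacklevel=2,
            )
        comps = pca.components_.copy()
        for k in range(comps.shape[0]):
            if comps[k, np.argmax(np.abs(comps[k]))] < 0:
                comps[k] = -comps[k]
        self.components_ = comps
        var = (Z @ comps.T).var(axis=0)
        self.comp_scale_ = np.where(var > 1e-24, np.sqrt(var), 1.0)
        self.explained_variance_ = pca.explained_variance_
        self.n_features_in_ = n_feat
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        Z = (X - self.center_) / self.scale_
        return (Z @ self.components_.T) / self.comp_scale_


def fit_transform_spec(raw_features, n_drop: int = 9) -> FeatureReducer:
    """Fit the reduction on a matrix of raw descriptor vectors."""
    return FeatureReducer(n_drop=n_drop).fit(np.asarray(raw_features))


def apply_transform(reducer: FeatureReducer, raw) -> np.ndarray:
    """Apply a fitted reduction to one vector or a matrix of vectors."""
    raw = np.asarray(raw, dtype=float)
    single = raw.ndim == 1
    out = reducer.transform(raw)
    return out[0] if single else out


# --------------------------------------------------------------------------
# Network arithmetic


def count_parameters(layer_sizes) -> int:
    """Trainable parameters (weights + biases) of a dense stack."""
    sizes = list(layer_sizes)
    return int(sum((a + 1) * b for a, b in zip(sizes[:-1], sizes[1:])))


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    """Mean signed error, MAE, RMSE, and calc-vs-reference slope/intercept/R^2."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    resid = y_pred - y_true
    out = {
        "mse": float(resid.mean()),
        "mae": float(np.abs(resid).mean()),
        "rmse": float(np.sqrt((resid**2).mean())),
    }
    if len(y_true) > 1 and y_true.std() > 0:
        lr = stats.linregress(y_true, y_pred)
        out.update(slope=float(lr.slope), intercept=float(lr.intercept),
                   r2=float(lr.rvalue**2))
    else:
        out.update(slope=float("nan"), intercept=float("nan"), r2=float("nan"))
    return out


class SolvationNetwork(RegressorMixin, BaseEstimator):
    """Dense ReLU network regressor trained with Nadam on weighted MSE + L2.

    Parameters
    ----------
    hidden_layer_sizes : (h1, h2)
        Hidden widths; (16, 8) for the aqueous model, (14, 7) nonaqueous.
    l2 : float
        L2 penalty strength on weights (biases are not penalized).
    learning_rate : float
        Initial Nadam step size (0.001 or 0.0001 are the working choices).
    lr_patience : int or None
        Drop the step size tenfold (to a floor of 1e-5) when the validation
        loss has not improved for this many epochs; ``None`` keeps the step
        size fixed.
    epochs, batch_size : training schedule.
    validation_split : fraction held out for validation, stratified by the
        optional ``strata`` labels passed to :meth:`fit`.
    patience : int or None
        Early stopping: halt when the validation loss has not improved for
        this many epochs and restore the best-epoch weights.  ``None``
        disables it (the full epoch budget is always an upper bound).
    seed : int
        Controls initialization, shuffling, and the split; fixing it makes
        training bit-reproducible.

    Attributes
    ----------
    weights_, biases_ : per-layer arrays.
    history_ : dict with per-epoch train/validation loss.
    train_metrics_, val_metrics_ : metric dicts on the two splits.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, int] = (16, 8),
        l2: float = 0.01,
        learning_rate: float = 0.001,
        epochs: int = 400,
        batch_size: int = 32,
        validation_split: float = 0.2,
        patience: int | None = 150,
        lr_patience: int | None = 40,
        seed: int = 0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.l2 = l2
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_split = validation_split
        self.patience = patience
        self.lr_patience = lr_patience
        self.seed = seed
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps

    # -- forward pass ------------------------------------------------------

    def _forward(self, X, weights, biases):
        a = X
        pre = []
        acts = [a]
        for W, b in zip(weights[:-1], biases[:-1]):
            z = a @ W + b
            pre.append(z)
            a = np.maximum(z, 0.0)
            acts.append(a)
        out = a @ weights[-1] + biases[-1]
        return out[:, 0], pre, acts

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} inputs, got {X.shape[1]}")
        y, _, _ = self._forward(X, self.weights_, self.biases_)
        return y

    # -- training ----------------------------------------------------------

    def _init_params(self, n_in, rng):
        sizes = [n_in, *self.hidden_layer_sizes, 1]
        weights, biases = [], []
        for a, b in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (a + b))  # Glorot uniform
            weights.append(rng.uniform(-limit, limit, size=(a, b)))
            biases.append(np.zeros(b))
        return weights, biases

    def _split(self, n, strata, rng):
        strata = np.zeros(n, dtype=int) if strata is None else np.asarray(strata)
        val_idx = []
        for s in np.unique(strata):
            idx = np.flatnonzero(strata == s)
            rng.shuffle(idx)
            k = int(round(self.validation_split * len(idx)))
            val_idx.extend(idx[:k])
        val = np.zeros(n, dtype=bool)
        val[val_idx] = True
        return ~val, val

    def _loss_grad(self, X, y, w, weights, biases):
        """Batch estimate of the weighted-MSE + L2 gradient (backprop).

        The data term is normalized by the batch weight sum so each step
        approximates the gradient of the full weighted mean, keeping the
        L2 term at its nominal strength relative to the data term.
        """
        yhat, pre, acts = self._forward(X, weights, biases)
        resid = yhat - y
        batch_w = max(float(w.sum()), 1e-12)
        dL_dout = (2.0 * w * resid / batch_w)[:, None]
        gW = [None] * len(weights)
        gb = [None] * len(biases)
        delta = dL_dout
        gW[-1] = acts[-1].T @ delta + 2.0 * self.l2 * weights[-1]
        gb[-1] = delta.sum(axis=0)
        for k in range(len(weights) - 2, -1, -1):
            delta = (delta @ weights[k + 1].T) * (pre[k] > 0)
            gW[k] = acts[k].T @ delta + 2.0 * self.l2 * weights[k]
            gb[k] = delta.sum(axis=0)
        data_loss = float((w * resid**2).sum() / batch_w)
        return data_loss, gW, gb

    def _penalty(self, weights):
        return self.l2 * sum(float((W**2).sum()) for W in weights)

    def fit(self, X, y, sample_weight=None, strata=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        if np.any(w < 0):
            raise ValueError("sample weights must be non-negative")
        # zero-weight records contribute nothing; drop them so they cannot
        # perturb batching or the split
        keep = w > 0
        X, y, w = X[keep], y[keep], w[keep]
        strata = None if strata is None else np.asarray(strata)[keep]
        n = len(y)
        self.n_features_in_ = X.shape[1]
        n_params = count_parameters([X.shape[1], *self.hidden_layer_sizes, 1])
        self.n_parameters_ = n_params
        if n < n_params:
            import warnings

            warnings.warn(
                f"{n} training records for {n_params} parameters; "
                "expect heavy reliance on the L2 penalty",
                stacklevel=2,
            )
        rng = np.random.default_rng(self.seed)
        tr, va = self._split(n, strata, rng)
        Xtr, ytr, wtr = X[tr], y[tr], w[tr]
        Xva, yva, wva = X[va], y[va], w[va]
        weights, biases = self._init_params(X.shape[1], rng)
        m_w = [np.zeros_like(W) for W in weights]
        v_w = [np.zeros_like(W) for W in weights]
        m_b = [np.zeros_like(b) for b in biases]
        v_b = [np.zeros_like(b) for b in biases]
        step = 0
        total_w = float(wtr.sum())
        hist = {"loss": [], "val_loss": []}
        best_vloss = np.inf
        best_state = None
        stale = 0
        lr_stale = 0
        lr = self.learning_rate

        def nadam_update(p, g, m, v, t):
            b1, b2 = self.beta1, self.beta2
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            # Nesterov look-ahead on the first moment
            m_bar = b1 * mhat + (1 - b1) * g / (1 - b1**t)
            p -= lr * m_bar / (np.sqrt(vhat) + self.eps)

        for epoch in range(self.epochs):
            order = rng.permutation(len(ytr))
            for start in range(0, len(ytr), self.batch_size):
                sel = order[start : start + self.batch_size]
                _, gW, gb = self._loss_grad(
                    Xtr[sel], ytr[sel], wtr[sel], weights, biases
                )
                step += 1
                for k in range(len(weights)):
                    nadam_update(weights[k], gW[k], m_w[k], v_w[k], step)
                    nadam_update(biases[k], gb[k], m_b[k], v_b[k], step)
            yhat_tr, _, _ = self._forward(Xtr, weights, biases)
            loss = float((wtr * (yhat_tr - ytr) ** 2).sum() / total_w) + self._penalty(
                weights
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={loss}); "
                    "lower the learning rate"
                )
            hist["loss"].append(loss)
            if len(yva):
                yhat_va, _, _ = self._forward(Xva, weights, biases)
                vloss = float((wva * (yhat_va - yva) ** 2).sum() / max(wva.sum(), 1e-12))
                hist["val_loss"].append(vloss)
                if vloss < best_vloss - 1e-12:
                    best_vloss = vloss
                    best_state = ([W.copy() for W in weights],
                                  [b.copy() for b in biases])
                    stale = 0
                    lr_stale = 0
                else:
                    stale += 1
                    lr_stale += 1
                if (self.lr_patience is not None and lr_stale >= self.lr_patience
                        and lr > 1e-5):
                    lr = max(lr * 0.1, 1e-5)
                    lr_stale = 0
                if self.patience is not None and stale >= self.patience:
                    break
        if best_state is not None and self.patience is not None:
            weights, biases = best_state
        self.weights_ = weights
        self.biases_ = biases
        self.history_ = hist
        self.train_metrics_ = regression_metrics(ytr, self.predict(Xtr))
        self.val_metrics_ = (
            regression_metrics(yva, self.predict(Xva)) if len(yva) else {}
        )
        return self


# --------------------------------------------------------------------------
# Composed model with persistence


@dataclass
class SolvationModel:
    """Reducer + network + feature schema: geometry in, kcal/mol out."""

    schema: FeatureSchema
    reducer: FeatureReducer
    network: SolvationNetwork

    def predict_raw(self, raw_features) -> np.ndarray:
        return self.network.predict(self.reducer.transform(np.atleast_2d(raw_features)))

    def predict_molecule(self, mol: Molecule, solvent: SolventDescriptor) -> float:
        raw = featurize(mol, solvent, schema=self.schema)
        return float(self.predict_raw(raw)[0])

    # -- archive (JSON text container) ------------------------------------

    def save(self, path) -> None:
        net = self.network
        payload = {
            "format": "gbsolv-model/1",
            "schema": {
                "aqueous": self.schema.aqueous,
                "pair_list": [f"{a}-{b}" for a, b in self.schema.pair_list],
            },
            "reducer": {
                "n_drop": self.reducer.n_drop,
                "center": self.reducer.center_.tolist(),
                "scale": self.reducer.scale_.tolist(),
                "components": self.reducer.components_.tolist(),
                "comp_scale": self.reducer.comp_scale_.tolist(),
            },
            "network": {
                "hidden_layer_sizes": list(net.hidden_layer_sizes),
                "l2": net.l2,
                "weights": [W.tolist() for W in net.weights_],
                "biases": [b.tolist() for b in net.biases_],
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "SolvationModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "gbsolv-model/1":
            raise ValueError(f"{path}: not a recognized model archive")
        sc = payload["schema"]
        schema = FeatureSchema(
            aqueous=sc["aqueous"],
            pair_list=tuple(tuple(p.split("-")) for p in sc["pair_list"]),
        )
        red = FeatureReducer(n_drop=payload["reducer"]["n_drop"])
        red.center_ = np.array(payload["reducer"]["center"])
        red.scale_ = np.array(payload["reducer"]["scale"])
        red.components_ = np.array(payload["reducer"]["components"])
        red.comp_scale_ = np.array(payload["reducer"]["comp_scale"])
        red.n_features_in_ = len(red.center_)
        nc = payload["network"]
        net = SolvationNetwork(
            hidden_layer_sizes=tuple(nc["hidden_layer_sizes"]), l2=nc["l2"]
        )
        net.weights_ = [np.array(W) for W in nc["weights"]]
        net.biases_ = [np.array(b) for b in nc["biases"]]
        net.n_features_in_ = net.weights_[0].shape[0]
        return cls(schema=schema, reducer=red, network=net)


def train_model(
    raw_features,
    targets,
    schema: FeatureSchema,
    sample_weight=None,
    strata=None,
    n_drop: int = 9,
    **net_kwargs,
) -> SolvationModel:
    """Fit reduction and network on a table of raw descriptor vectors."""
    X = np.asarray(raw_features, dtype=float)
    hidden = net_kwargs.pop(
        "hidden_layer_sizes", (16, 8) if schema.aqueous else (14, 7)
    )
    reducer = FeatureReducer(n_drop=n_drop).fit(X)
    net = SolvationNetwork(hidden_layer_sizes=hidden, **net_kwargs)
    net.fit(reducer.transform(X), np.asarray(targets, float),
            sample_weight=sample_weight, strata=strata)
    return SolvationModel(schema=schema, reducer=reducer, network=net)
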