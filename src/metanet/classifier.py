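"""Connectome-matrix classifier: E2E -> E2N -> N2G -> FC network.

Classifies 14 x 14 network interaction matrices (metastability or
synchrony) into one of eight states (seven tasks plus rest). Because a
connectome matrix has no shift invariance, ordinary square convolutions
are replaced by topology-aware filters:

* edge-to-edge (E2E): a cross-shaped filter; the response at edge
  (i, j) is a weighted sum of all edges sharing row i plus all edges
  sharing column j,
* edge-to-node (E2N): each node receives a weighted sum of its edges,
* node-to-graph (N2G): a single response from all weighted nodes,

followed by three fully connected layers and a softmax over the eight
classes. ReLU activations sit between layers, with dropout at train
time; the network minimises cross-entropy with the Adam optimiser.

The implementation is self-contained (numpy forward and backward
passes), which keeps the guided-backpropagation saliency rule — only
positive gradients propagated through positively activated units —
explicit and auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "CNNConfig",
    "ConnectomeCNN",
    "e2e_layer",
    "e2n_layer",
    "n2g_layer",
    "train_classifier",
    "TrainResult",
    "guided_backprop_saliency",
    "consensus_mask",
    "occlude_and_evaluate",
    "evaluate",
    "chance_level",
]


@dataclass
class CNNConfig:
    d: int = 14
    n_classes: int = 8
    e2e_maps: int = 16
    e2n_maps: int = 32
    n2g_maps: int = 64
    fc_sizes: tuple[int, int] = (64, 32)
    dropout: float = 0.6
    learning_rate: float = 0.001
    momentum: float = 0.9  # Adam first-moment decay (beta1)
    batch_size: int = 128
    max_epochs: int = 300
    patience: int = 20  # early stopping on validation loss
    folds: int = 5
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not (0.0 < self.dropout < 1.0):
            raise ValueError("dropout must be in (0, 1)")
        if not (0.0 < self.momentum < 1.0):
            raise ValueError("momentum must be in (0, 1)")


# ---------------------------------------------------------------------------
# layer primitives (functional forms; the model wires them with caches)


def e2e_layer(X: np.ndarray, r: np.ndarray, s: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Edge-to-edge cross filter.

    ``X``: (batch, d, d, c_in); ``r``/``s``: (d, c_in, c_out) row and
    column weights; output (batch, d, d, c_out) with

        Y(i, j) = sum_c [ sum_k r_kc X(i, k, c) + sum_k s_kc X(k, j, c) ] + b
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 4 or X.shape[1] != X.shape[2]:
        raise ValueError("E2E input must be (batch, d, d, c) with square maps")
    if r.shape != s.shape or r.shape[0] != X.shape[1] or r.shape[1] != X.shape[3]:
        raise ValueError("E2E weight shapes do not match the input")
    A = np.einsum("bikc,kco->bio", X, r)
    B = np.einsum("bkjc,kco->bjo", X, s)
    return A[:, :, None, :] + B[:, None, :, :] + bias


def e2n_layer(X: np.ndarray, w: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Edge-to-node filter: node i gets a weighted sum of its edges.

    ``X``: (batch, d, d, c_in); ``w``: (d, c_in, c_out); output
    (batch, d, c_out)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 4 or X.shape[1] != X.shape[2]:
        raise ValueError("E2N input must be (batch, d, d, c) with square maps")
    if w.shape[0] != X.shape[1] or w.shape[1] != X.shape[3]:
        raise ValueError("E2N weight shape does not match the input")
    return np.einsum("bikc,kco->bio", X, w) + bias


def n2g_layer(n: np.ndarray, v: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Node-to-graph filter: one response per output map from all nodes.

    ``n``: (batch, d, c_in); ``v``: (d, c_in, c_out); output (batch, c_out)."""
    n = np.asarray(n, dtype=float)
    if v.shape[0] != n.shape[1] or v.shape[1] != n.shape[2]:
        raise ValueError("N2G weight shape does not match the input")
    return np.einsum("bic,ico->bo", n, v) + bias


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConnectomeCNN:
    """The trained model: parameters, input standardisation and the
    forward/backward machinery."""

    def __init__(self, config: CNNConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        d, c1, c2, c3 = config.d, config.e2e_maps, config.e2n_maps, config.n2g_maps
        f1, f2 = config.fc_sizes
        k = config.n_classes

        def glorot(*shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params: dict[str, np.ndarray] = {
            "e2e_r": glorot(d, 1, c1, fan_in=2 * d),
            "e2e_s": glorot(d, 1, c1, fan_in=2 * d),
            "e2e_b": np.zeros(c1),
            "e2n_w": glorot(d, c1, c2, fan_in=d * c1),
            "e2n_b": np.zeros(c2),
            "n2g_v": glorot(d, c2, c3, fan_in=d * c2),
            "n2g_b": np.zeros(c3),
            "fc1_w": glorot(c3, f1, fan_in=c3),
            "fc1_b": np.zeros(f1),
            "fc2_w": glorot(f1, f2, fan_in=f1),
            "fc2_b": np.zeros(f2),
            "fc3_w": glorot(f2, k, fan_in=f2),
            "fc3_b": np.zeros(k),
        }
        # per-entry standardisation fitted on the training set
        self.input_mean = np.zeros((d, d))
        self.input_sd = np.ones((d, d))
        self.trained = False
        self.classes_: np.ndarray | None = None

    # -- input handling -----------------------------------------------------

    def fit_standardizer(self, X: np.ndarray) -> None:
        self.input_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.input_sd = sd

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        Z = (X - self.input_mean) / self.input_sd
        return Z[..., None]  # (batch, d, d, 1)

    # -- forward / backward -------------------------------------------------

    def _forward(
        self,
        X4: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        guided: bool = False,
    ):
        """Returns (logits, cache). Dropout only when ``train``."""
        p = self.params
        cache: dict[str, np.ndarray] = {"x": X4, "guided": guided}
        drop = self.config.dropout if train else 0.0

        def relu(name, z):
            a = np.maximum(z, 0.0)
            cache[f"{name}_act"] = a
            return a

        def dropout(name, a):
            if drop > 0.0:
                mask = (rng.random(a.shape) >= drop) / (1.0 - drop)
                cache[f"{name}_mask"] = mask
                return a * mask
            return a

        # dropout sits on the dense head (N2G output and first FC
        # layer); dropping entire feature maps of the narrow E2E/E2N
        # stages at rate 0.6 starves the forward signal
        z1 = e2e_layer(X4, p["e2e_r"], p["e2e_s"], p["e2e_b"])
        a1 = relu("l1", z1)
        cache["a1"] = a1
        z2 = e2n_layer(a1, p["e2n_w"], p["e2n_b"])
        a2 = relu("l2", z2)
        cache["a2"] = a2
        z3 = n2g_layer(a2, p["n2g_v"], p["n2g_b"])
        a3 = dropout("l3", relu("l3", z3))
        cache["a3"] = a3
        z4 = a3 @ p["fc1_w"] + p["fc1_b"]
        a4 = dropout("l4", relu("l4", z4))
        cache["a4"] = a4
        z5 = a4 @ p["fc2_w"] + p["fc2_b"]
        a5 = relu("l5", z5)
        cache["a5"] = a5
        logits = a5 @ p["fc3_w"] + p["fc3_b"]
        return logits, cache

    def _backward(self, cache, dlogits: np.ndarray):
        """Gradients of all parameters and of the standardized input."""
        p = self.params
        g: dict[str, np.ndarray] = {}
        guided = cache["guided"]

        def through_relu(name, dout):
            act = cache[f"{name}_act"]
            dz = dout * (act > 0)
            if guided:
                dz = np.maximum(dz, 0.0)  # guided rule: positive grads only
            return dz

        def through_dropout(name, dout):
            mask = cache.get(f"{name}_mask")
            return dout if mask is None else dout * mask

        a4, a5 = cache["a4"], cache["a5"]
        g["fc3_w"] = a5.reshape(len(a5), -1).T @ dlogits
        g["fc3_b"] = dlogits.sum(axis=0)
        da5 = dlogits @ p["fc3_w"].T
        dz5 = through_relu("l5", da5)
        g["fc2_w"] = a4.T @ dz5
        g["fc2_b"] = dz5.sum(axis=0)
        da4 = through_dropout("l4", dz5 @ p["fc2_w"].T)
        dz4 = through_relu("l4", da4)
        a3 = cache["a3"]
        g["fc1_w"] = a3.T @ dz4
        g["fc1_b"] = dz4.sum(axis=0)
        da3 = through_dropout("l3", dz4 @ p["fc1_w"].T)
        dz3 = through_relu("l3", da3)
        a2 = cache["a2"]
        g["n2g_v"] = np.einsum("bic,bo->ico", a2, dz3)
        g["n2g_b"] = dz3.sum(axis=0)
        da2 = through_dropout("l2", np.einsum("bo,ico->bic", dz3, p["n2g_v"]))
        dz2 = through_relu("l2", da2)
        a1 = cache["a1"]
        g["e2n_w"] = np.einsum("bikc,bio->kco", a1, dz2)
        g["e2n_b"] = dz2.sum(axis=(0, 1))
        da1 = through_dropout("l1", np.einsum("bio,kco->bikc", dz2, p["e2n_w"]))
        dz1 = through_relu("l1", da1)
        x = cache["x"]
        dA = dz1.sum(axis=2)  # (b, d, o)
        dB = dz1.sum(axis=1)  # (b, d, o)
        g["e2e_r"] = np.einsum("bikc,bio->kco", x, dA)
        g["e2e_s"] = np.einsum("bkjc,bjo->kco", x, dB)
        g["e2e_b"] = dz1.sum(axis=(0, 1, 2))
        dx = np.einsum("bio,kco->bikc", dA, p["e2e_r"]) + np.einsum(
            "bjo,kco->bkjc", dB, p["e2e_s"]
        )
        return g, dx

    # -- public API ---------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(self._prepare(X), train=False)
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = np.argmax(self.predict_proba(X), axis=1)
        if self.classes_ is not None:
            return self.classes_[idx]
        return idx

    def loss(self, X: np.ndarray, y_idx: np.ndarray) -> float:
        proba = self.predict_proba(X)
        return float(-np.log(proba[np.arange(len(y_idx)), y_idx] + 1e-12).mean())

    def fit(
        self,
        X: np.ndarray,
        y_idx: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val_idx: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> list[float]:
        """Adam/cross-entropy training with early stopping on the
        validation loss; returns the per-epoch validation losses."""
        cfg = self.config
        rng = rng or np.random.default_rng(cfg.seed)
        self.fit_standardizer(X)
        Xp = self._prepare(X)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(w) for k, w in self.params.items()}
        b1, b2, eps = cfg.momentum, 0.999, 1e-8
        step = 0
        best = np.inf
        best_params = {k: w.copy() for k, w in self.params.items()}
        stall = 0
        history: list[float] = []
        n = len(Xp)
        for _epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                xb, yb = Xp[sel], y_idx[sel]
                logits, cache = self._forward(xb, train=True, rng=rng)
                proba = _softmax(logits)
                dlogits = proba.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                grads, _ = self._backward(cache, dlogits)
                step += 1
                for k in self.params:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mhat = m[k] / (1 - b1**step)
                    vhat = v[k] / (1 - b2**step)
                    self.params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            if X_val is not None and len(X_val):
                val = self.loss(X_val, y_val_idx)
            else:
                val = self.loss(X, y_idx)
            history.append(val)
            if val < best - 1e-6:
                best = val
                best_params = {k: w.copy() for k, w in self.params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
        self.params = best_params
        self.trained = True
        return history


@dataclass
class TrainResult:
    models: list[ConnectomeCNN]
    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: np.ndarray  # row-normalized, rows = true class
    classes: np.ndarray
    test_indices: list[np.ndarray] = field(default_factory=list)


def _confusion(y_true_idx, y_pred_idx, k) -> np.ndarray:
    C = np.zeros((k, k))
    for t, p in zip(y_true_idx, y_pred_idx):
        C[t, p] += 1
    rows = C.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return C / rows


def train_classifier(
    X: np.ndarray, y: np.ndarray, config: CNNConfig | None = None
) -> TrainResult:
    """k-fold protocol: disjoint stratified test folds (20% each for
    k = 5); the remainder is split into training (60% of the total) and
    validation (20%, for early stopping), matching the 0.6/0.2/0.2
    partition. Reports mean test accuracy and the pooled row-normalized
    confusion matrix.
    """
    config = config or CNNConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    counts = np.bincount(y_idx)
    if np.any(counts < config.folds):
        raise ValueError(
            "every class needs at least one example per fold "
            f"(counts: {dict(zip(classes, counts))})"
        )
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    val_frac = config.split[1] / (config.split[0] + config.split[1])
    models, accs, tests = [], [], []
    all_true, all_pred = [], []
    for fold, (fit_ix, test_ix) in enumerate(skf.split(X, y_idx)):
        tr_ix, val_ix = train_test_split(
            fit_ix,
            test_size=val_frac,
            stratify=y_idx[fit_ix],
            random_state=config.seed + fold,
        )
        model = ConnectomeCNN(config, rng=np.random.default_rng([config.seed, fold]))
        model.classes_ = classes
        model.fit(
            X[tr_ix], y_idx[tr_ix], X[val_ix], y_idx[val_ix],
            rng=np.random.default_rng([config.seed, fold, 1]),
        )
        pred = np.argmax(model.predict_proba(X[test_ix]), axis=1)
        accs.append(float(np.mean(pred == y_idx[test_ix])))
        all_true.append(y_idx[test_ix])
        all_pred.append(pred)
        models.append(model)
        tests.append(test_ix)
    confusion = _confusion(np.concatenate(all_true), np.concatenate(all_pred),
                           len(classes))
    return TrainResult(
        models=models,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        confusion=confusion,
        classes=classes,
        test_indices=tests,
    )


def evaluate(model: ConnectomeCNN, X: np.ndarray, y: np.ndarray):
    """Accuracy and row-normalized confusion of a trained model."""
    classes = model.classes_ if model.classes_ is not None else np.unique(y)
    lut = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([lut[v] for v in np.asarray(y)])
    pred = np.argmax(model.predict_proba(X), axis=1)
    return float(np.mean(pred == y_idx)), _confusion(y_idx, pred, len(classes))


def guided_backprop_saliency(model: ConnectomeCNN, x: np.ndarray) -> np.ndarray:
    """Gradient of the winning class score w.r.t. the input matrix,
    with only positive gradients propagated through positively
    activated units (the guided-backpropagation rule)."""
    if not model.trained:
        warnings.warn("saliency requested from an untrained model")
    X4 = model._prepare(x)
    logits, cache = model._forward(X4, train=False, guided=True)
    win = np.argmax(logits, axis=1)
    dlogits = np.zeros_like(logits)
    dlogits[np.arange(len(win)), win] = 1.0
    _, dx = model._backward(cache, dlogits)
    sal = dx[..., 0]  # single input channel
    return sal[0] if np.asarray(x).ndim == 2 else sal


def consensus_mask(
    saliencies, top_frac: float = 0.10, consensus: float = 0.90
) -> np.ndarray:
    """Cohort-consensus occlusion mask.

    Per subject the ``top_frac`` most positive saliency entries are set
    to 1; the binary maps are averaged and entries exceeding the
    ``consensus`` fraction (strictly) form the mask.
    """
    maps = [np.asarray(s, dtype=float) for s in saliencies]
    if not maps:
        raise ValueError("need at least one saliency map")
    d2 = maps[0].size
    k = max(1, int(round(top_frac * d2)))
    binar = []
    for s in maps:
        flat = s.ravel()
        top = np.argsort(flat)[::-1][:k]  # ties broken by sort order
        b = np.zeros(d2)
        b[top] = 1.0
        binar.append(b.reshape(s.shape))
    frac = np.mean(binar, axis=0)
    return frac > consensus


def occlude_and_evaluate(
    model: ConnectomeCNN, X: np.ndarray, y: np.ndarray, mask: np.ndarray
):
    """Zero the masked entries of every input matrix and re-evaluate
    the pre-trained model; returns (accuracy, confusion)."""
    X = np.asarray(X, dtype=float)
    occluded = X * (~np.asarray(mask, dtype=bool))
    return evaluate(model, occluded, y)


def per_class_occlusion(
    model: ConnectomeCNN,
    X: np.ndarray,
    y: np.ndarray,
    top_frac: float = 0.10,
    consensus: float = 0.90,
):
    """Class-wise consensus occlusion experiment.

    For every class a consensus mask is built from the guided-backprop
    saliency maps of that class's examples, and that class's inputs are
    occluded with their own mask (the connections that drive the
    class's identification are removed). Returns ``(X_occluded,
    masks_by_class)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    occluded = X.copy()
    masks: dict = {}
    for c in np.unique(y):
        sel = np.flatnonzero(y == c)
        sal = guided_backprop_saliency(model, X[sel])
        if sal.ndim == 2:
            sal = sal[None]
        mask = consensus_mask(list(sal), top_frac=top_frac, consensus=consensus)
        masks[c] = mask
        occluded[sel] = X[sel] * (~mask)
    return occluded, masks


def chance_level(
    n_draws: int = 100_000, n_classes: int = 8, seed: int = 0
) -> float:
    """Monte-Carlo accuracy of a uniform-random classifier on balanced
    labels (analytically 1/n_classes)."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_classes, size=n_draws)
    guesses = rng.integers(0, n_classes, size=n_draws)
    return float(np.mean(labels == guesses))
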