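"""Predictor head families trained on frozen embeddings.

Classical families (elastic net, SVM/SVR, gradient-boosted trees, MLP)
consume pooled embeddings; positional families (CNN, transformer) consume
unpooled, padded-and-masked batches so convolutional kernels and
self-attention can exploit positional structure.  The routing rule is
enforced, not advisory.

Gradient boosting is backed by scikit-learn's histogram GBT; the CNN and
transformer heads run on the in-package autodiff engine, so no deep
learning framework is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.ensemble import HistGradientBoostingClassifier, HistGradientBoostingRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.svm import SVC, SVR

from . import nn
from .embed import EmbeddingMatrix

__all__ = [
    "HeadSpec",
    "TrainedHead",
    "train_head",
    "predict_head",
    "huber_loss",
    "POOLED_FAMILIES",
    "UNPOOLED_FAMILIES",
    "FAMILIES",
    "pad_batch",
]

POOLED_FAMILIES = frozenset({"enet", "svm", "svr", "gbt", "mlp"})
UNPOOLED_FAMILIES = frozenset({"cnn", "transformer"})
FAMILIES = POOLED_FAMILIES | UNPOOLED_FAMILIES


def huber_loss(residual: float, delta: float) -> float:
    """r^2/2 inside |r| <= delta, delta * (|r| - delta/2) outside."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = abs(float(residual))
    if r <= delta:
        return 0.5 * r * r
    return delta * (r - 0.5 * delta)


@dataclass(frozen=True)
class HeadSpec:
    family: str
    task_type: str  # "binary" or "regression"
    hyperparams: tuple = ()  # sorted (key, value) pairs; dicts accepted in ctor
    input_mode: str = "pooled"
    loss: str = "default"  # "default", "mse" or "huber"
    huber_delta: Optional[float] = None
    seed: int = 0

    def __init__(
        self,
        family: str,
        task_type: str,
        hyperparams: Union[dict, tuple, None] = None,
        input_mode: Optional[str] = None,
        loss: str = "default",
        huber_delta: Optional[float] = None,
        seed: int = 0,
    ):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        if task_type not in ("binary", "regression"):
            raise ValueError(f"unknown task_type {task_type!r}")
        if family == "svm" and task_type != "binary":
            raise ValueError("svm is a classifier; use svr for regression")
        if family == "svr" and task_type != "regression":
            raise ValueError("svr is a regressor; use svm for classification")
        if input_mode is None:
            input_mode = "unpooled" if family in UNPOOLED_FAMILIES else "pooled"
        if family in UNPOOLED_FAMILIES and input_mode != "unpooled":
            raise ValueError(f"{family} requires unpooled input")
        if family in POOLED_FAMILIES and input_mode != "pooled":
            raise ValueError(f"{family} requires pooled input")
        if loss == "huber" and (huber_delta is None or huber_delta <= 0):
            raise ValueError("huber loss requires huber_delta > 0")
        if isinstance(hyperparams, dict):
            hyperparams = tuple(sorted(hyperparams.items()))
        object.__setattr__(self, "family", family)
        object.__setattr__(self, "task_type", task_type)
        object.__setattr__(self, "hyperparams", hyperparams or ())
        object.__setattr__(self, "input_mode", input_mode)
        object.__setattr__(self, "loss", loss)
        object.__setattr__(self, "huber_delta", huber_delta)
        object.__setattr__(self, "seed", seed)

    @property
    def hp(self) -> dict:
        return dict(self.hyperparams)


@dataclass
class TrainedHead:
    spec: HeadSpec
    model: object
    featurizer_id: str = ""
    train_meta: dict = field(default_factory=dict)
    metrics: Optional[object] = None
    y_scale: Tuple[float, float] = (0.0, 1.0)  # (mean, std) for neural regression

    def predict(self, X) -> np.ndarray:
        return predict_head(self, X)


# -- input normalization ------------------------------------------------


def _pooled_matrix(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        if X.ndim != 2:
            raise ValueError("pooled input must be (n, D)")
        return X.astype(np.float64)
    rows = []
    for m in X:
        if isinstance(m, EmbeddingMatrix):
            if not m.pooled:
                raise ValueError("pooled head received unpooled embedding")
            rows.append(m.values[0])
        else:
            rows.append(np.asarray(m, dtype=np.float64).ravel())
    return np.stack(rows)


def _unpooled_list(X) -> List[np.ndarray]:
    out = []
    for m in X:
        if isinstance(m, EmbeddingMatrix):
            if m.pooled:
                raise ValueError("unpooled head received pooled embedding")
            out.append(m.values)
        else:
            a = np.asarray(m, dtype=np.float64)
            if a.ndim != 2:
                raise ValueError("unpooled inputs must be (L, D) matrices")
            out.append(a)
    return out


def pad_batch(mats: Sequence[np.ndarray], L: Optional[int] = None):
    """Zero-pad (L_i, D) matrices to (B, L, D) plus a 0/1 mask (B, L)."""
    Lmax = L if L is not None else max(m.shape[0] for m in mats)
    D = mats[0].shape[1]
    X = np.zeros((len(mats), Lmax, D))
    mask = np.zeros((len(mats), Lmax))
    for i, m in enumerate(mats):
        X[i, : m.shape[0]] = m
        mask[i, : m.shape[0]] = 1.0
    return X, mask


def _featurizer_of(X) -> str:
    try:
        first = X[0]
    except (TypeError, IndexError):
        return ""
    return first.featurizer_id if isinstance(first, EmbeddingMatrix) else ""


# -- neural heads -------------------------------------------------------


class _CNNHead(nn.Module):
    def __init__(self, d_in: int, hidden: int, kernel: int, rng):
        self.conv1 = nn.Conv1d(d_in, hidden, kernel, rng)
        self.conv2 = nn.Conv1d(hidden, hidden, kernel, rng)
        self.out = nn.Linear(hidden, 1, rng)

    def __call__(self, x: nn.Tensor, mask: np.ndarray) -> nn.Tensor:
        m = nn.constant(mask[:, :, None])
        h = (self.conv1(x) * m).relu()
        h = (self.conv2(h) * m).relu()
        return self.out(nn.masked_mean(h, mask)).reshape(-1)


class _TransformerHead(nn.Module):
    def __init__(self, d_in: int, d_model: int, n_heads: int, n_layers: int, rng):
        self.proj = nn.Linear(d_in, d_model, rng)
        self.attn = [nn.MultiHeadAttention(d_model, n_heads, rng) for _ in range(n_layers)]
        self.ffn = [nn.FeedForward(d_model, 2 * d_model, rng) for _ in range(n_layers)]
        self.ln1 = [nn.LayerNorm(d_model) for _ in range(n_layers)]
        self.ln2 = [nn.LayerNorm(d_model) for _ in range(n_layers)]
        self.out = nn.Linear(d_model, 1, rng)
        self.d_model = d_model

    def __call__(self, x: nn.Tensor, mask: np.ndarray) -> nn.Tensor:
        L = x.shape[1]
        h = self.proj(x) + nn.constant(nn.sinusoidal_positions(L, self.d_model)[None])
        h = h * nn.constant(mask[:, :, None])
        for attn, ffn, ln1, ln2 in zip(self.attn, self.ffn, self.ln1, self.ln2):
            h = ln1(h + attn(h, h, kv_mask=mask))
            h = ln2(h + ffn(h))
        return self.out(nn.masked_mean(h, mask)).reshape(-1)


def _neural_loss(pred: nn.Tensor, y: np.ndarray, spec: HeadSpec) -> nn.Tensor:
    yt = nn.constant(y)
    if spec.task_type == "binary":
        p = pred.sigmoid()
        eps = 1e-9
        return -(yt * (p + eps).log() + (1.0 - yt) * (1.0 - p + eps).log()).mean()
    r = pred - yt
    if spec.loss == "huber":
        d = spec.huber_delta
        absr = r.abs()
        inside = (np.abs(r.data) <= d).astype(float)
        quad = r * r * 0.5
        lin = absr * d - 0.5 * d * d
        return (quad * nn.constant(inside) + lin * nn.constant(1.0 - inside)).mean()
    return (r * r).mean()


def _build_neural(spec: HeadSpec, d_in: int, rng: np.random.Generator):
    hp = spec.hp
    if spec.family == "cnn":
        return _CNNHead(d_in, int(hp.get("hidden", 32)), int(hp.get("kernel", 5)), rng)
    return _TransformerHead(
        d_in,
        int(hp.get("d_model", 32)),
        int(hp.get("n_heads", 4)),
        int(hp.get("n_layers", 2)),
        rng,
    )


def _fit_neural(
    spec: HeadSpec, mats: List[np.ndarray], y: np.ndarray, init_from=None
) -> TrainedHead:
    hp = spec.hp
    rng = np.random.default_rng(spec.seed)
    d_in = mats[0].shape[1]
    model = _build_neural(spec, d_in, rng)
    if init_from is not None:
        # warm start: copy all pretrained weights except the output layer
        skip = {id(p) for p in _collect_linear(model.out)}
        old = init_from.parameters()
        new = model.parameters()
        if len(old) != len(new):
            raise ValueError("warm start requires identical architectures")
        for p_new, p_old in zip(new, old):
            if id(p_new) in skip:
                continue
            if p_new.data.shape != p_old.data.shape:
                raise ValueError("warm start requires identical architectures")
            p_new.data = p_old.data.copy()
    epochs = int(hp.get("epochs", 30))
    batch = int(hp.get("batch_size", 64))
    lr = float(hp.get("lr", 3e-3))
    y = np.asarray(y, dtype=np.float64)
    y_scale = (0.0, 1.0)
    yt = y
    if spec.task_type == "regression":
        mu, sd = float(y.mean()), float(y.std())
        sd = sd if sd > 0 else 1.0
        y_scale = (mu, sd)
        yt = (y - mu) / sd
    opt = nn.Adam(model.parameters(), lr=lr, weight_decay=float(hp.get("weight_decay", 0.0)))
    n = len(mats)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            Xb, maskb = pad_batch([mats[i] for i in idx])
            pred = model(nn.constant(Xb), maskb)
            loss = _neural_loss(pred, yt[idx], spec)
            opt.zero_grad()
            loss.backward()
            opt.step()
    return TrainedHead(
        spec=spec,
        model=model,
        train_meta={"n_train": n, "epochs": epochs, "seed": spec.seed},
        y_scale=y_scale,
    )


def _collect_linear(layer):
    return [layer.W, layer.b]


def fine_tune_head(pretrained: TrainedHead, spec: HeadSpec, X, y) -> TrainedHead:
    """Warm-start a neural head from a pretrained one and train on (X, y).

    All weights except the output layer are copied; the output layer is
    re-initialized from ``spec.seed``.  Architecture hyperparameters must
    match the pretrained head's.
    """
    if spec.family not in UNPOOLED_FAMILIES:
        raise ValueError(f"family {spec.family!r} does not support warm starts")
    if pretrained.spec.family != spec.family:
        raise ValueError("family mismatch between pretrained head and spec")
    mats = _unpooled_list(X)
    y = np.asarray(y, dtype=np.float64)
    head = _fit_neural(spec, mats, y, init_from=pretrained.model)
    head.featurizer_id = _featurizer_of(X) or pretrained.featurizer_id
    head.train_meta["warm_started"] = True
    return head


# -- classical heads ----------------------------------------------------


def _make_sklearn(spec: HeadSpec):
    hp = spec.hp
    fam, binary = spec.family, spec.task_type == "binary"
    if fam == "enet":
        if binary:
            return LogisticRegression(
                penalty="elasticnet",
                solver="saga",
                l1_ratio=float(hp.get("l1_ratio", 0.5)),
                C=float(hp.get("C", 1.0)),
                max_iter=int(hp.get("max_iter", 3000)),
                random_state=spec.seed,
            )
        return ElasticNet(
            alpha=float(hp.get("alpha", 0.01)),
            l1_ratio=float(hp.get("l1_ratio", 0.5)),
            max_iter=int(hp.get("max_iter", 5000)),
            random_state=spec.seed,
        )
    if fam == "svm":
        from sklearn.calibration import CalibratedClassifierCV

        base = SVC(C=float(hp.get("C", 1.0)), gamma=hp.get("gamma", "scale"),
                   random_state=spec.seed)
        return CalibratedClassifierCV(base, cv=3, ensemble=False)
    if fam == "svr":
        return SVR(C=float(hp.get("C", 1.0)), epsilon=float(hp.get("epsilon", 0.1)))
    if fam == "gbt":
        cls = HistGradientBoostingClassifier if binary else HistGradientBoostingRegressor
        return cls(
            max_iter=int(hp.get("n_estimators", 200)),
            learning_rate=float(hp.get("learning_rate", 0.1)),
            max_depth=hp.get("max_depth", None),
            random_state=spec.seed,
        )
    if fam == "mlp":
        cls = MLPClassifier if binary else MLPRegressor
        return cls(
            hidden_layer_sizes=tuple(hp.get("hidden_layer_sizes", (64,))),
            alpha=float(hp.get("alpha", 1e-4)),
            max_iter=int(hp.get("max_iter", 500)),
            random_state=spec.seed,
        )
    raise ValueError(fam)  # pragma: no cover


def train_head(spec: HeadSpec, X, y) -> TrainedHead:
    """Fit one head; reproducible given ``spec.seed``.

    Raises on label/task mismatch (continuous labels with a binary task,
    or a single-class binary training set).
    """
    y = np.asarray(y, dtype=np.float64)
    featurizer_id = _featurizer_of(X)
    if spec.task_type == "binary":
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binary task requires 0/1 labels")
        if len(np.unique(y)) < 2:
            raise ValueError("binary task requires both classes in training data")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite labels")
    if spec.family in UNPOOLED_FAMILIES:
        mats = _unpooled_list(X)
        if len(mats) != len(y):
            raise ValueError("X/y length mismatch")
        head = _fit_neural(spec, mats, y)
    else:
        Xp = _pooled_matrix(X)
        if Xp.shape[0] != len(y):
            raise ValueError("X/y length mismatch")
        model = _make_sklearn(spec)
        model.fit(Xp, y.astype(int) if spec.task_type == "binary" else y)
        head = TrainedHead(
            spec=spec, model=model, train_meta={"n_train": len(y), "seed": spec.seed}
        )
    head.featurizer_id = featurizer_id
    return head


def predict_head(head: TrainedHead, X, strict_featurizer: bool = False) -> np.ndarray:
    """Scores: class-1 probability in [0, 1] for binary, real values otherwise."""
    fid = _featurizer_of(X)
    if fid and head.featurizer_id and fid != head.featurizer_id:
        msg = f"featurizer mismatch: head={head.featurizer_id!r}, input={fid!r}"
        if strict_featurizer:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    spec = head.spec
    if spec.family in UNPOOLED_FAMILIES:
        mats = _unpooled_list(X)
        Xb, mask = pad_batch(mats)
        out = head.model(nn.constant(Xb), mask).data
        if spec.task_type == "binary":
            return 1.0 / (1.0 + np.exp(-out))
        mu, sd = head.y_scale
        return out * sd + mu
    Xp = _pooled_matrix(X)
    if spec.task_type == "binary":
        return head.model.predict_proba(Xp)[:, 1]
    return np.asarray(head.model.predict(Xp), dtype=np.float64)
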