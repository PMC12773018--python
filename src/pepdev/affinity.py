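"""Unified binding-affinity scale, cross-attention affinity model, and the
stability-pretrain -> half-life fine-tune protocol.

Affinity readouts (Kd/Ki/IC50, any molar unit) are pooled onto one
negative-log10-molar scale without assay correction; the readout kind is
kept as metadata.  Scores >= 9 are strong binders, [7, 9) medium, < 7 weak
(ties at the boundaries go to the stronger class).

Half-life values are normalized to hours; the regression target defaults
to ln(1 + hours).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .core import AA_ALPHABET, PeptideRecord, ValidationError
from .embed import EmbeddingMatrix
from .heads import pad_batch
from .metrics import regression_metrics

__all__ = [
    "UNIT_FACTORS",
    "unify_affinity",
    "affinity_class",
    "AffinityPair",
    "AffinityModelSpec",
    "CrossAttentionAffinity",
    "train_affinity",
    "halflife_normalize",
    "HalfLifeRecord",
    "pretrain_finetune_halflife",
]

UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "μM": 1e-6, "nM": 1e-9, "pM": 1e-12}
READOUT_KINDS = ("Kd", "Ki", "IC50")


def unify_affinity(value: float, unit: str, kind: str = "Kd") -> float:
    """-log10 of the value expressed in molar; kind is metadata only."""
    if unit not in UNIT_FACTORS:
        raise ValidationError(f"unknown unit {unit!r}")
    if kind not in READOUT_KINDS:
        raise ValidationError(f"unknown readout kind {kind!r}")
    if not (value > 0):
        raise ValidationError(f"affinity value must be positive, got {value}")
    return -math.log10(value * UNIT_FACTORS[unit])


def affinity_class(score: float) -> str:
    """strong iff score >= 9; medium iff 7 <= score < 9; weak iff score < 7."""
    if not math.isfinite(score):
        raise ValidationError("non-finite affinity score")
    if score >= 9.0:
        return "strong"
    if score >= 7.0:
        return "medium"
    return "weak"


_CLASS_INDEX = {"weak": 0, "medium": 1, "strong": 2}


@dataclass
class AffinityPair:
    peptide: PeptideRecord
    protein_seq: str
    score: float
    kind: str = "Kd"

    def __post_init__(self) -> None:
        if not self.protein_seq or set(self.protein_seq) - set(AA_ALPHABET):
            raise ValidationError("protein_seq must be non-empty canonical AA")
        if not math.isfinite(self.score):
            raise ValidationError("non-finite affinity score")

    @property
    def klass(self) -> str:
        return affinity_class(self.score)


@dataclass(frozen=True)
class AffinityModelSpec:
    d_model: int = 32
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 64
    peptide_pooled: bool = False
    class_loss_weight: float = 0.2
    huber_delta: float = 1.0
    lr: float = 3e-3
    epochs: int = 40
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.class_loss_weight < 0:
            raise ValueError("class_loss_weight must be >= 0")


class CrossAttentionAffinity(nn.Module):
    """Peptide tokens attend to protein tokens; multitask output.

    Both streams are projected to a shared width and get sinusoidal
    position channels; ``n_layers`` blocks of one-directional
    peptide -> protein cross attention plus feed-forward (pre-norm
    residuals) feed a masked mean pool over peptide positions, split into a
    scalar score head and a 3-logit class head.  Deterministic at
    inference.
    """

    def __init__(self, d_pep: int, d_prot: int, spec: AffinityModelSpec):
        rng = np.random.default_rng(spec.seed)
        d = spec.d_model
        self.spec = spec
        self.proj_pep = nn.Linear(d_pep, d, rng)
        self.proj_prot = nn.Linear(d_prot, d, rng)
        self.attn = [nn.MultiHeadAttention(d, spec.n_heads, rng) for _ in range(spec.n_layers)]
        self.ffn = [nn.FeedForward(d, spec.d_ff, rng) for _ in range(spec.n_layers)]
        self.ln1 = [nn.LayerNorm(d) for _ in range(spec.n_layers)]
        self.ln2 = [nn.LayerNorm(d) for _ in range(spec.n_layers)]
        # score is a masked mean of per-token contributions (binding signals
        # are additive over peptide positions); classes read the pooled state
        self.score_mlp1 = nn.Linear(d, d, rng)
        self.score_mlp2 = nn.Linear(d, 1, rng)
        self.class_head = nn.Linear(d, 3, rng)

    def __call__(
        self,
        pep: np.ndarray,
        pep_mask: np.ndarray,
        prot: np.ndarray,
        prot_mask: np.ndarray,
    ) -> Tuple[nn.Tensor, nn.Tensor]:
        d = self.spec.d_model
        Lp, Lt = pep.shape[1], prot.shape[1]
        hp = self.proj_pep(nn.constant(pep)) + nn.constant(
            nn.sinusoidal_positions(Lp, d)[None]
        )
        ht = self.proj_prot(nn.constant(prot)) + nn.constant(
            nn.sinusoidal_positions(Lt, d)[None]
        )
        hp = hp * nn.constant(pep_mask[:, :, None])
        ht = ht * nn.constant(prot_mask[:, :, None])
        for attn, ffn, ln1, ln2 in zip(self.attn, self.ffn, self.ln1, self.ln2):
            hp = hp + attn(ln1(hp), ht, kv_mask=prot_mask)
            hp = hp + ffn(ln2(hp))
        per_token = self.score_mlp2(self.score_mlp1(hp).tanh())
        score = nn.masked_mean(per_token, pep_mask).reshape(-1)
        pooled = nn.masked_mean(hp, pep_mask)
        logits = self.class_head(pooled)
        return score, logits


def _multitask_loss(
    score: nn.Tensor,
    logits: nn.Tensor,
    y_std: np.ndarray,
    y_orig: np.ndarray,
    spec: AffinityModelSpec,
) -> nn.Tensor:
    """Huber on the standardized score + weighted CE over true-score classes."""
    r = score - nn.constant(y_std)
    d = spec.huber_delta
    absr = r.abs()
    inside = (np.abs(r.data) <= d).astype(float)
    reg = (
        r * r * 0.5 * nn.constant(inside)
        + (absr * d - 0.5 * d * d) * nn.constant(1.0 - inside)
    ).mean()
    if spec.class_loss_weight == 0:
        return reg
    klass = np.array([_CLASS_INDEX[affinity_class(v)] for v in y_orig])
    onehot = np.eye(3)[klass]
    probs = logits.softmax(axis=-1)
    ce = -(nn.constant(onehot) * (probs + 1e-9).log()).sum(axis=-1).mean()
    return reg + spec.class_loss_weight * ce


@dataclass
class TrainedAffinityModel:
    model: CrossAttentionAffinity
    spec: AffinityModelSpec
    y_scale: Tuple[float, float]
    metrics: Dict[str, object] = field(default_factory=dict)

    def predict(
        self, pep_mats: Sequence[np.ndarray], prot_mats: Sequence[np.ndarray]
    ) -> Tuple[np.ndarray, np.ndarray]:
        """(scores, class_logits) for a batch of raw embedding matrices."""
        pep, pmask = pad_batch(list(pep_mats))
        prot, tmask = pad_batch(list(prot_mats))
        score, logits = self.model(pep, pmask, prot, tmask)
        mu, sd = self.y_scale
        return score.data * sd + mu, logits.data


def _as_matrix(m) -> np.ndarray:
    return m.values if isinstance(m, EmbeddingMatrix) else np.asarray(m, dtype=np.float64)


def train_affinity(
    pep_mats: Sequence,
    prot_mats: Sequence,
    scores: Sequence[float],
    spec: AffinityModelSpec,
    split,
) -> TrainedAffinityModel:
    """Fit the cross-attention model on pre-featurized pairs.

    ``split`` is a SplitAssignment over record indices ("0", "1", ...) or
    record ids matching the order of the inputs; its validation part is the
    selection set.  The loss is Huber on the (standardized) score plus
    ``class_loss_weight`` times cross-entropy over classes derived from the
    true scores; the selection metric is validation Spearman rho.
    """
    pep_mats = [_as_matrix(m) for m in pep_mats]
    prot_mats = [_as_matrix(m) for m in prot_mats]
    y = np.asarray(scores, dtype=np.float64)
    n = len(y)
    ids = list(split.cluster_of)
    if len(ids) != n:
        raise ValueError("split does not cover the pairs")
    part = split.record_partition
    order_ids = sorted(ids, key=lambda r: int(r)) if all(i.isdigit() for i in ids) else ids
    train_idx = [k for k, rid in enumerate(order_ids) if part[rid] == "train"]
    val_idx = [k for k, rid in enumerate(order_ids) if part[rid] == "val"]
    if not train_idx or not val_idx:
        raise ValueError("degenerate split: need both train and val pairs")
    mu, sd = float(y[train_idx].mean()), float(y[train_idx].std())
    sd = sd if sd > 0 else 1.0
    yt = (y - mu) / sd
    model = CrossAttentionAffinity(pep_mats[0].shape[1], prot_mats[0].shape[1], spec)
    opt = nn.Adam(model.parameters(), lr=spec.lr)
    rng = np.random.default_rng(spec.seed)
    # pre-padded per-partition tensors (corpora are small and fixed-width)
    for _ in range(spec.epochs):
        order = rng.permutation(len(train_idx))
        for start in range(0, len(order), spec.batch_size):
            idx = [train_idx[i] for i in order[start : start + spec.batch_size]]
            pep, pmask = pad_batch([pep_mats[i] for i in idx])
            prot, tmask = pad_batch([prot_mats[i] for i in idx])
            score, logits = model(pep, pmask, prot, tmask)
            loss = _multitask_loss(score, logits, yt[idx], y[idx], spec)
            opt.zero_grad()
            loss.backward()
            opt.step()
    trained = TrainedAffinityModel(model=model, spec=spec, y_scale=(mu, sd))
    val_scores, val_logits = trained.predict(
        [pep_mats[i] for i in val_idx], [prot_mats[i] for i in val_idx]
    )
    rep = regression_metrics(y[val_idx], val_scores)
    pred_class = np.argmax(val_logits, axis=1)
    true_class = np.array([_CLASS_INDEX[affinity_class(v)] for v in y[val_idx]])
    score_class = np.array([_CLASS_INDEX[affinity_class(v)] for v in val_scores])
    trained.metrics = {
        "val": rep,
        "val_spearman": rep.spearman_rho,
        "class_agreement": float(np.mean(pred_class == true_class)),
        # multitask consistency: do the two output heads tell the same story?
        "head_consistency": float(np.mean(pred_class == score_class)),
        "n_train": len(train_idx),
        "n_val": len(val_idx),
    }
    return trained


# -- half-life ----------------------------------------------------------

_HOURS_PER_UNIT = {"min": 1.0 / 60.0, "h": 1.0, "d": 24.0}


def halflife_normalize(value: float, unit: str) -> float:
    """Convert a half-life measurement to hours."""
    if unit not in _HOURS_PER_UNIT:
        raise ValidationError(f"unknown unit {unit!r}; use min, h or d")
    if not (value > 0):
        raise ValidationError(f"half-life must be positive, got {value}")
    return value * _HOURS_PER_UNIT[unit]


@dataclass
class HalfLifeRecord:
    peptide: PeptideRecord
    hours: float

    def __post_init__(self) -> None:
        if not (self.hours > 0):
            raise ValidationError("hours must be positive")

    @property
    def target(self) -> float:
        """ln(1 + hours) — the default regression target."""
        return math.log1p(self.hours)


def pretrain_finetune_halflife(
    stability_X,
    stability_y: Sequence[float],
    halflife_X,
    halflife_hours: Sequence[float],
    family: str = "transformer",
    target: str = "log1p",
    n_folds: int = 5,
    seed: int = 0,
    hyperparams: Optional[dict] = None,
    pretrain: bool = True,
) -> Dict[str, object]:
    """Stability-pretrain then fine-tune a half-life regressor under k-fold CV.

    Neural families copy all pretrained weights except the output layer;
    tree/linear families do not support warm starts and are trained
    directly on half-life data (a notice is recorded in the result).
    Returns per-fold and mean Pearson/Spearman/R^2.
    """
    from sklearn.model_selection import KFold

    from .heads import HeadSpec, UNPOOLED_FAMILIES, fine_tune_head, train_head, predict_head

    hours = np.asarray(halflife_hours, dtype=np.float64)
    if np.any(hours <= 0):
        raise ValidationError("hours must be positive")
    if len(hours) < n_folds:
        raise ValueError(f"{len(hours)} records cannot support {n_folds}-fold CV")
    y = np.log1p(hours) if target == "log1p" else hours
    hp = dict(hyperparams or {})
    spec = HeadSpec(family, "regression", hyperparams=hp, seed=seed)
    pretrained = None
    notice = ""
    if pretrain and family in UNPOOLED_FAMILIES:
        pre_hp = dict(hp)
        pre_hp["epochs"] = int(pre_hp.get("pretrain_epochs", pre_hp.get("epochs", 20)))
        pre_spec = HeadSpec(family, "regression", hyperparams=pre_hp, seed=seed)
        pretrained = train_head(pre_spec, stability_X, np.asarray(stability_y, float))
    elif pretrain:
        notice = f"family {family!r} does not support warm starts; trained directly"
    halflife_X = list(halflife_X)
    folds = []
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for fold_i, (tr, te) in enumerate(kf.split(hours)):
        fold_spec = HeadSpec(family, "regression", hyperparams=hp, seed=seed + fold_i)
        Xtr = [halflife_X[i] for i in tr]
        Xte = [halflife_X[i] for i in te]
        if pretrained is not None:
            head = fine_tune_head(pretrained, fold_spec, Xtr, y[tr])
        else:
            head = train_head(fold_spec, Xtr, y[tr])
        pred = predict_head(head, Xte)
        folds.append(regression_metrics(y[te], pred))
    def _mean(attr: str) -> Optional[float]:
        vals = [getattr(f, attr) for f in folds if getattr(f, attr) is not None]
        return float(np.mean(vals)) if vals else None

    return {
        "family": family,
        "target": target,
        "pretrained": pretrained is not None,
        "notice": notice,
        "folds": folds,
        "mean_pearson_r": _mean("pearson_r"),
        "mean_spearman_rho": _mean("spearman_rho"),
        "mean_r2": _mean("r2"),
    }
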