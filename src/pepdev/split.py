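"""Leakage-aware clustering and splitting.

Two clustering routes — greedy sequence-identity clustering (AA modality)
and Taylor-Butina sphere exclusion on fingerprint Tanimoto similarity
(SMILES modality) — feed a cluster-level 80/20 split.  Whole clusters are
atomic: no cluster ever straddles the train/validation boundary.  A
distribution-matched record-level split covers the paired-affinity task,
and an audit operation quantifies residual leakage.

The greedy identity clustering replaces an external clustering tool; the
identity/coverage thresholds (0.3 / 0.8, bidirectional coverage) are kept
but memberships are not bit-identical to that tool's output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .align import pairwise_identity
from .chem import Fingerprint, tanimoto
from .core import Modality, PeptideRecord, PropertyDataset

__all__ = [
    "ClusterAssignment",
    "SplitAssignment",
    "cluster_sequences_by_identity",
    "cluster_smiles_butina",
    "cluster_split",
    "propagate_split",
    "distribution_matched_split",
    "audit_leakage",
]

TRAIN = "train"
VAL = "val"
PARTITIONS = (TRAIN, VAL)


@dataclass
class ClusterAssignment:
    """record_id -> cluster_id map; cluster ids are contiguous from 0."""

    member_of: Dict[str, int]
    method: str
    params: Dict[str, object] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.member_of.values())) if self.member_of else 0

    def validate(self) -> "ClusterAssignment":
        ids = sorted(set(self.member_of.values()))
        if ids and ids != list(range(len(ids))):
            raise ValueError("cluster ids must be contiguous from 0")
        return self


@dataclass
class SplitAssignment:
    """Cluster-level train/val partition plus the derived record-level map."""

    cluster_of: Dict[str, int]
    partition_of: Dict[int, str]
    train_frac: float
    seed: Optional[int]
    method: str
    params: Dict[str, object] = field(default_factory=dict)

    @property
    def record_partition(self) -> Dict[str, str]:
        return {rid: self.partition_of[cid] for rid, cid in self.cluster_of.items()}

    def partition(self, record_id: str) -> str:
        return self.partition_of[self.cluster_of[record_id]]

    def record_ids(self, partition: str) -> List[str]:
        return [r for r, c in self.cluster_of.items() if self.partition_of[c] == partition]

    def validate(self) -> "SplitAssignment":
        for p in self.partition_of.values():
            if p not in PARTITIONS:
                raise ValueError(f"unknown partition token {p!r}")
        missing = set(self.cluster_of.values()) - set(self.partition_of)
        if missing:
            raise ValueError(f"clusters without partition: {sorted(missing)}")
        return self


def _record_seq(rec) -> str:
    return rec.payload if isinstance(rec, PeptideRecord) else str(rec)


def _record_id(rec, idx: int) -> str:
    return rec.id if isinstance(rec, PeptideRecord) else str(idx)


def cluster_sequences_by_identity(
    records: Sequence,
    min_id: float = 0.3,
    min_cov: float = 0.8,
    identity_fn: Callable[[str, str], Tuple[float, float, float]] = pairwise_identity,
) -> ClusterAssignment:
    """Greedy incremental identity clustering.

    Records are visited in order of descending length (ties broken by
    lexicographic sequence, then by id); each record joins the
    earliest-founded cluster whose representative aligns with identity
    >= ``min_id`` and both coverages >= ``min_cov``, otherwise it founds a
    new cluster with itself as representative.
    """
    items = []
    for idx, rec in enumerate(records):
        if isinstance(rec, PeptideRecord) and rec.modality is not Modality.AA:
            raise ValueError(f"record {rec.id!r} is not AA modality")
        items.append((_record_id(rec, idx), _record_seq(rec)))
    order = sorted(items, key=lambda t: (-len(t[1]), t[1], t[0]))
    reps: List[str] = []  # representative sequence per cluster, founding order
    member_of: Dict[str, int] = {}
    for rid, seq in order:
        assigned = None
        for cid, rep in enumerate(reps):
            ident, cov_a, cov_b = identity_fn(seq, rep)
            if ident >= min_id and cov_a >= min_cov and cov_b >= min_cov:
                assigned = cid
                break
        if assigned is None:
            assigned = len(reps)
            reps.append(seq)
        member_of[rid] = assigned
    return ClusterAssignment(
        member_of=member_of,
        method="identity_greedy",
        params={"min_id": min_id, "min_cov": min_cov},
    ).validate()


def cluster_smiles_butina(
    fps: Sequence[Fingerprint],
    sim_threshold: float = 0.6,
    record_ids: Optional[Sequence[str]] = None,
) -> ClusterAssignment:
    """Taylor-Butina sphere-exclusion clustering on Tanimoto similarity.

    Neighbor lists are built at similarity >= ``sim_threshold``; centroids
    are picked greedily by descending unassigned-neighbor count (ties: lowest
    input index) and absorb their unassigned neighbors; remaining molecules
    become singletons.  Cluster ids follow centroid-picking order.
    """
    n = len(fps)
    ids = [str(i) for i in range(n)] if record_ids is None else list(record_ids)
    if len(ids) != n:
        raise ValueError("record_ids length mismatch")
    for fp in fps[1:]:
        if not fps[0].same_params(fp):
            raise ValueError("fingerprint parameter mismatch")
    neighbors: List[set] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if tanimoto(fps[i], fps[j]) >= sim_threshold:
                neighbors[i].add(j)
                neighbors[j].add(i)
    unassigned = set(range(n))
    member_of: Dict[str, int] = {}
    next_cluster = 0
    while unassigned:
        best = min(unassigned, key=lambda i: (-len(neighbors[i] & unassigned), i))
        cluster = {best} | (neighbors[best] & unassigned)
        for i in cluster:
            member_of[ids[i]] = next_cluster
        unassigned -= cluster
        next_cluster += 1
    return ClusterAssignment(
        member_of=member_of,
        method="butina",
        params={"sim_threshold": sim_threshold},
    ).validate()


def cluster_split(
    ca: ClusterAssignment, train_frac: float = 0.8, seed: int = 0
) -> SplitAssignment:
    """Shuffle clusters with the seed; the first ceil(train_frac * n) go to train."""
    n = ca.n_clusters
    if n < 2:
        raise ValueError(f"need at least 2 clusters, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = math.ceil(train_frac * n)
    partition_of = {
        int(cid): (TRAIN if k < n_train else VAL) for k, cid in enumerate(order)
    }
    return SplitAssignment(
        cluster_of=dict(ca.member_of),
        partition_of=partition_of,
        train_frac=train_frac,
        seed=seed,
        method=f"{ca.method}+cluster_split",
        params=dict(ca.params),
    ).validate()


def propagate_split(split: SplitAssignment, converted: PropertyDataset) -> SplitAssignment:
    """Carry a source-modality split over to converted records by id."""
    cluster_of: Dict[str, int] = {}
    for rec in converted.records:
        if rec.id not in split.cluster_of:
            raise KeyError(f"record {rec.id!r} missing from the source split")
        cluster_of[rec.id] = split.cluster_of[rec.id]
    partition_of = (
        {c: split.partition_of[c] for c in set(cluster_of.values())}
        if cluster_of
        else {}
    )
    return SplitAssignment(
        cluster_of=cluster_of,
        partition_of=partition_of,
        train_frac=split.train_frac,
        seed=split.seed,
        method=split.method + "+propagated",
        params=dict(split.params),
    )


def distribution_matched_split(
    values: Sequence[float],
    train_frac: float = 0.8,
    n_bins: int = 10,
    seed: int = 0,
    record_ids: Optional[Sequence[str]] = None,
) -> Tuple[SplitAssignment, float]:
    """Quantile-binned record-level split that matches label distributions.

    Values are cut into quantile bins; within each bin records are shuffled
    and the first ceil(train_frac * k) go to train.  Every record is its own
    cluster.  Returns the split and the two-sample Kolmogorov-Smirnov
    distance between train and val label distributions.
    """
    from scipy.stats import ks_2samp

    vals = np.asarray(values, dtype=float)
    n = len(vals)
    if n < 5:
        raise ValueError(f"need at least 5 records, got {n}")
    ids = [str(i) for i in range(n)] if record_ids is None else list(record_ids)
    edges = np.quantile(vals, np.linspace(0, 1, n_bins + 1))
    bin_of = np.clip(np.searchsorted(edges[1:-1], vals, side="right"), 0, n_bins - 1)
    rng = np.random.default_rng(seed)
    partition = np.empty(n, dtype=object)
    for b in range(n_bins):
        idx = np.flatnonzero(bin_of == b)
        if idx.size == 0:
            continue
        idx = idx[rng.permutation(idx.size)]
        k_train = math.ceil(train_frac * idx.size)
        partition[idx[:k_train]] = TRAIN
        partition[idx[k_train:]] = VAL
    # Guarantee both partitions are non-empty (clusters of size 1, so any
    # record can move without breaking atomicity).
    for part, other in ((VAL, TRAIN), (TRAIN, VAL)):
        if not np.any(partition == part):
            movable = np.flatnonzero(partition == other)
            partition[movable[-1]] = part
    train_vals = vals[partition == TRAIN]
    val_vals = vals[partition == VAL]
    if np.ptp(vals) == 0:
        ks = 0.0
    else:
        ks = float(ks_2samp(train_vals, val_vals).statistic)
    cluster_of = {ids[i]: i for i in range(n)}
    partition_of = {i: str(partition[i]) for i in range(n)}
    split = SplitAssignment(
        cluster_of=cluster_of,
        partition_of=partition_of,
        train_frac=train_frac,
        seed=seed,
        method="distribution_matched",
        params={"n_bins": n_bins, "ks_distance": ks},
    ).validate()
    return split, ks


def audit_leakage(
    split: SplitAssignment,
    records: Sequence,
    similarity_fn: Callable[[object, object], float],
    threshold: float,
    max_exhaustive: int = 5000,
    sample_size: int = 200_000,
    seed: int = 0,
) -> dict:
    """Count cross-partition pairs with similarity >= threshold.

    Exhaustive for corpora up to ``max_exhaustive`` records; sampled above,
    with the sample size reported.  ``records`` may be PeptideRecords or
    (id, payload-like) tuples; ``similarity_fn`` receives the payload-like
    objects.
    """
    items = []
    for idx, rec in enumerate(records):
        if isinstance(rec, PeptideRecord):
            items.append((rec.id, rec.payload))
        else:
            rid, payload = rec
            items.append((str(rid), payload))
    train = [(rid, p) for rid, p in items if split.partition(rid) == TRAIN]
    val = [(rid, p) for rid, p in items if split.partition(rid) == VAL]
    n_cross = len(train) * len(val)
    exhaustive = len(items) <= max_exhaustive or n_cross == 0
    if exhaustive:
        gen = ((t, v) for t in train for v in val)
        n_checked = n_cross
    else:
        rng = np.random.default_rng(seed)
        n_checked = min(sample_size, n_cross)
        ti = rng.integers(0, len(train), size=n_checked)
        vi = rng.integers(0, len(val), size=n_checked)
        gen = ((train[a], val[b]) for a, b in zip(ti, vi))
    n_violations = 0
    worst: List[Tuple[float, str, str]] = []
    for (tid, tp), (vid, vp) in gen:
        s = similarity_fn(tp, vp)
        if s >= threshold:
            n_violations += 1
            worst.append((s, tid, vid))
            worst.sort(reverse=True)
            del worst[5:]
    return {
        "n_violations": n_violations,
        "worst_pairs": [(tid, vid, s) for s, tid, vid in worst],
        "n_checked": n_checked,
        "exhaustive": exhaustive,
    }
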