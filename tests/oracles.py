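"""Independent brute-force oracles used by the tests.

Each oracle mirrors a documented contract with a deliberately naive,
separately written implementation (plain recursion/scans, no shared code
paths with the package beyond primitive inputs).
"""

from __future__ import annotations

from functools import lru_cache
from typing import List, Optional, Tuple

import numpy as np

MATCH = 10.0
MISMATCH = 0.0
GAP_OPEN = -7.0
GAP_EXT = -1.0

_NEG = float("-inf")


def naive_affine_alignment(a: str, b: str):
    """Gotoh DP written independently (memoized recursion over 3 states).

    Same scoring and tie rules as the package: diagonal > gap-in-a (left)
    > gap-in-b (up); gap of length L costs OPEN + (L-1)*EXT; on ties the
    gap closes early (H preferred over extension).
    """
    m, n = len(a), len(b)

    @lru_cache(maxsize=None)
    def H(i, j):
        if i == 0 and j == 0:
            return 0.0
        best = _NEG
        if i > 0 and j > 0:
            best = H(i - 1, j - 1) + (MATCH if a[i - 1] == b[j - 1] else MISMATCH)
        if j > 0:
            best = max(best, E(i, j))
        if i > 0:
            best = max(best, F(i, j))
        return best

    @lru_cache(maxsize=None)
    def E(i, j):  # ends consuming b[j-1] against a gap
        if j == 0:
            return _NEG
        if j == 1:
            return H(i, 0) + GAP_OPEN
        return max(E(i, j - 1) + GAP_EXT, H(i, j - 1) + GAP_OPEN)

    @lru_cache(maxsize=None)
    def F(i, j):  # ends consuming a[i-1] against a gap
        if i == 0:
            return _NEG
        if i == 1:
            return H(0, j) + GAP_OPEN
        return max(F(i - 1, j) + GAP_EXT, H(i - 1, j) + GAP_OPEN)

    cols: List[Tuple[Optional[int], Optional[int]]] = []
    i, j, state = m, n, "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and H(i, j) == H(i - 1, j - 1) + (
                MATCH if a[i - 1] == b[j - 1] else MISMATCH
            ):
                cols.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif j > 0 and H(i, j) == E(i, j):
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols.append((None, j - 1))
            if j > 1 and E(i, j) != H(i, j - 1) + GAP_OPEN and E(i, j) == E(i, j - 1) + GAP_EXT:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            cols.append((i - 1, None))
            if i > 1 and F(i, j) != H(i - 1, j) + GAP_OPEN and F(i, j) == F(i - 1, j) + GAP_EXT:
                i -= 1
            else:
                i -= 1
                state = "H"
    cols.reverse()
    return cols, H(m, n)


def naive_identity_coverage(a: str, b: str) -> Tuple[float, float, float]:
    cols, _ = naive_affine_alignment(a, b)
    matches = sum(
        1 for ia, ib in cols if ia is not None and ib is not None and a[ia] == b[ib]
    )
    paired = [k for k, (ia, ib) in enumerate(cols) if ia is not None and ib is not None]
    if not paired:
        return matches / len(cols), 0.0, 0.0
    lo, hi = paired[0], paired[-1]
    span_a = sum(1 for ia, _ in cols[lo : hi + 1] if ia is not None)
    span_b = sum(1 for _, ib in cols[lo : hi + 1] if ib is not None)
    return matches / len(cols), span_a / len(a), span_b / len(b)


def naive_greedy_identity_clusters(
    id_seq_pairs, min_id, min_cov, identity_fn
) -> dict:
    """Representative-scan clustering with the documented visit order."""
    order = sorted(id_seq_pairs, key=lambda t: (-len(t[1]), t[1], t[0]))
    reps = []
    member_of = {}
    for rid, seq in order:
        target = None
        for cid, rep in enumerate(reps):
            ident, ca, cb = identity_fn(seq, rep)
            if ident >= min_id and ca >= min_cov and cb >= min_cov:
                target = cid
                break
        if target is None:
            reps.append(seq)
            target = len(reps) - 1
        member_of[rid] = target
    return member_of


def naive_butina(sim: np.ndarray, threshold: float) -> List[int]:
    """Butina on a precomputed similarity matrix; returns cluster id per index."""
    n = sim.shape[0]
    neighbors = [
        {j for j in range(n) if j != i and sim[i, j] >= threshold} for i in range(n)
    ]
    assigned = [-1] * n
    cid = 0
    remaining = set(range(n))
    while remaining:
        counts = {i: len(neighbors[i] & remaining) for i in remaining}
        best = sorted(remaining, key=lambda i: (-counts[i], i))[0]
        members = {best} | (neighbors[best] & remaining)
        for i in members:
            assigned[i] = cid
        remaining -= members
        cid += 1
    return assigned


def auc_pair_counting(y_true, y_score) -> float:
    """AUC as the tie-averaged concordant-pair fraction."""
    pos = [s for t, s in zip(y_true, y_score) if t == 1]
    neg = [s for t, s in zip(y_true, y_score) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def spearman_rank_formula(x, y) -> float:
    """Spearman rho via Pearson on average ranks (independent of scipy)."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2.0 + 1.0
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
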