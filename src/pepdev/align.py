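"""Global pairwise alignment for sequence-identity clustering.

Needleman-Wunsch/Gotoh with affine gaps and fully documented scoring and
tie rules, so that an independent re-implementation reproduces the exact
alignment:

* match +10, mismatch 0 (integer-valued so score ties are exact)
* a gap of length L costs ``GAP_OPEN + (L - 1) * GAP_EXT``
* ties in the cell maximum are broken diagonal > gap-in-query > gap-in-target

Identity is matches / alignment length.  Coverage of a sequence is the
number of its residues lying between the first and the last paired
(residue-residue) column, divided by its length — both coverages must pass
the threshold (bidirectional coverage).
"""

from __future__ import annotations

from typing import List, Optional, Tuple

__all__ = ["pairwise_identity", "align_global", "MATCH", "MISMATCH", "GAP_OPEN", "GAP_EXT"]

MATCH = 10.0
MISMATCH = 0.0
GAP_OPEN = -7.0
GAP_EXT = -1.0

_NEG = float("-inf")


def align_global(a: str, b: str) -> List[Tuple[Optional[int], Optional[int]]]:
    """Return the optimal alignment as columns of (index-in-a, index-in-b).

    ``None`` marks a gap.  Deterministic under the documented tie rules.
    """
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        raise ValueError("empty sequence")
    # H: best overall; E: ends consuming b[j] against a gap (left move);
    # F: ends consuming a[i] against a gap (up move).
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[_NEG] * (n + 1) for _ in range(m + 1)]
    F = [[_NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(1, n + 1):
        E[0][j] = GAP_OPEN + (j - 1) * GAP_EXT
        H[0][j] = E[0][j]
    for i in range(1, m + 1):
        F[i][0] = GAP_OPEN + (i - 1) * GAP_EXT
        H[i][0] = F[i][0]
    for i in range(1, m + 1):
        ai = a[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            Ei[j] = max(Ei[j - 1] + GAP_EXT, Hi[j - 1] + GAP_OPEN)
            Fi[j] = max(Fi1[j] + GAP_EXT, Hi1[j] + GAP_OPEN)
            diag = Hi1[j - 1] + (MATCH if ai == b[j - 1] else MISMATCH)
            best = diag
            if Ei[j] > best:
                best = Ei[j]
            if Fi[j] > best:
                best = Fi[j]
            Hi[j] = best
    # Traceback with the same preference order: diagonal > E (left) > F (up).
    cols: List[Tuple[Optional[int], Optional[int]]] = []
    i, j = m, n
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0:
                diag = H[i - 1][j - 1] + (MATCH if a[i - 1] == b[j - 1] else MISMATCH)
                if H[i][j] == diag:
                    cols.append((i - 1, j - 1))
                    i -= 1
                    j -= 1
                    continue
            if j > 0 and H[i][j] == E[i][j]:
                state = "E"
                continue
            state = "F"
            continue
        if state == "E":
            cols.append((None, j - 1))
            from_h = H[i][j - 1] + GAP_OPEN
            if j > 1 and E[i][j] != from_h and E[i][j] == E[i][j - 1] + GAP_EXT:
                j -= 1
                continue
            j -= 1
            state = "H"
            continue
        # state == "F"
        cols.append((i - 1, None))
        from_h = H[i - 1][j] + GAP_OPEN
        if i > 1 and F[i][j] != from_h and F[i][j] == F[i - 1][j] + GAP_EXT:
            i -= 1
            continue
        i -= 1
        state = "H"
    cols.reverse()
    return cols


def pairwise_identity(a: str, b: str) -> Tuple[float, float, float]:
    """(identity, coverage_a, coverage_b) from one global alignment."""
    cols = align_global(a, b)
    matches = sum(
        1 for ia, ib in cols if ia is not None and ib is not None and a[ia] == b[ib]
    )
    identity = matches / len(cols)
    paired = [k for k, (ia, ib) in enumerate(cols) if ia is not None and ib is not None]
    if not paired:
        return identity, 0.0, 0.0
    lo, hi = paired[0], paired[-1]
    span_a = sum(1 for ia, _ in cols[lo : hi + 1] if ia is not None)
    span_b = sum(1 for _, ib in cols[lo : hi + 1] if ib is not None)
    return identity, span_a / len(a), span_b / len(b)
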