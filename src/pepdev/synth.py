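"""Seeded synthetic corpora emulating the statistical structure of every
task: imbalanced binary properties driven by physicochemical or positional
signals, bimodal continuous permeability around the -6.0 labeling boundary,
position-dependent peptide-protein affinity on the unified 4-12 scale, and
sparse log-normal half-life paired with a large stability corpus.

Every generator is bit-reproducible from its config seed and emits valid
records.  ``convert_to_smiles`` produces the SMILES twin of an AA corpus
(same ids) so split propagation and modality parity are testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np

from .affinity import AffinityPair, HalfLifeRecord
from .chem import KYTE_DOOLITTLE, net_charge, sequence_to_smiles
from .core import (
    AA_ALPHABET,
    Modality,
    PeptideRecord,
    PropertyDataset,
    get_task,
)

__all__ = [
    "SynthConfig",
    "gen_binary_corpus",
    "gen_permeability_corpus",
    "gen_affinity_pairs",
    "gen_halflife",
    "convert_to_smiles",
    "affinity_ground_truth",
    "MOTIF",
    "MOTIF_POSITION",
    "CLASS_BALANCE_PRESETS",
]

#: Positive-class fractions echoing the composition of the real corpora
#: (approximate ratios only; no claim of reproducing the actual data).
CLASS_BALANCE_PRESETS = {
    "hemolysis": 0.78,
    "non_fouling": 0.21,
    "toxicity": 0.50,
    "solubility": 0.48,
    "permeability_penetrance": 0.50,
}

MOTIF = "WKWK"
MOTIF_POSITION = 3


@dataclass(frozen=True)
class SynthConfig:
    n: int
    length_range: Tuple[int, int] = (10, 30)
    class_balance: float = 0.5
    effect_size: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.class_balance < 1):
            raise ValueError("class_balance must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n < 1 or self.length_range[0] < 2:
            raise ValueError("invalid size parameters")


def _random_sequences(rng: np.random.Generator, n: int, length_range) -> List[str]:
    lo, hi = length_range
    letters = np.array(list(AA_ALPHABET))
    out = []
    for _ in range(n):
        L = int(rng.integers(lo, hi + 1))
        out.append("".join(letters[rng.integers(0, 20, size=L)]))
    return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (np.tanh(0.5 * z) + 1.0)


def _calibrate_intercept(z: np.ndarray, balance: float) -> float:
    """Bisection for b such that mean(sigmoid(z + b)) == balance."""
    lo, hi = -50.0, 50.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _sigmoid(z + mid).mean() < balance:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_binary_corpus(cfg: SynthConfig, rule: str = "charge", task: str = "hemolysis") -> PropertyDataset:
    """Random sequences with labels from a logistic model of a planted signal.

    ``rule`` picks the signal: net charge at pH 7, mean hydropathy, or a
    fixed 4-mer motif planted at a fixed position (positives) versus a
    random other position (negatives), so that only position-aware heads
    can exceed pooled ones on the motif rule.
    """
    if rule not in ("charge", "hydropathy", "motif"):
        raise ValueError(f"unknown rule {rule!r}")
    rng = np.random.default_rng(cfg.seed)
    if rule == "motif":
        lo = max(cfg.length_range[0], MOTIF_POSITION + len(MOTIF) + 6)
        seqs = _random_sequences(rng, cfg.n, (lo, max(lo, cfg.length_range[1])))
        planted = rng.random(cfg.n) < cfg.class_balance
        out_seqs = []
        for seq, is_pos in zip(seqs, planted):
            if is_pos:
                pos = MOTIF_POSITION
            else:
                # decoy at a non-overlapping position: same composition signal
                pos = int(rng.integers(MOTIF_POSITION + len(MOTIF), len(seq) - len(MOTIF) + 1))
            out_seqs.append(seq[:pos] + MOTIF + seq[pos + len(MOTIF):])
        seqs = out_seqs
        signal = np.where(planted, 1.0, -1.0)
    else:
        seqs = _random_sequences(rng, cfg.n, cfg.length_range)
        if rule == "charge":
            raw = np.array([net_charge(s, 7.0) for s in seqs])
        else:
            raw = np.array(
                [sum(KYTE_DOOLITTLE[a] for a in s) / len(s) for s in seqs]
            )
        sd = raw.std() if raw.std() > 0 else 1.0
        signal = (raw - raw.mean()) / sd
    z = cfg.effect_size * signal + rng.normal(0.0, cfg.noise_sd, size=cfg.n)
    b = _calibrate_intercept(z, cfg.class_balance)
    labels = (rng.random(cfg.n) < _sigmoid(z + b)).astype(float)
    records = [
        PeptideRecord(
            id=f"s{i:06d}",
            modality=Modality.AA,
            payload=seq,
            labels={task: y},
            source=f"synth:{rule}:seed={cfg.seed}",
        )
        for i, (seq, y) in enumerate(zip(seqs, labels))
    ]
    return PropertyDataset(task=get_task(task), records=records)


def gen_permeability_corpus(
    cfg: SynthConfig,
    mixture_means: Tuple[float, float] = (-8.0, -5.0),
    mixture_sd: float = 0.8,
    threshold: float = -6.0,
    task: str = "permeability_pampa",
) -> PropertyDataset:
    """Bimodal log-permeability values straddling the labeling boundary.

    Values are drawn from a two-component normal mixture (the second
    component with weight ``class_balance``); each record carries the
    continuous value under ``task`` and the derived binary high/low label
    (value >= threshold) under ``"<task>_high"`` in its label map, so both
    the regression and the thresholded classification view are available.
    """
    rng = np.random.default_rng(cfg.seed)
    seqs = _random_sequences(rng, cfg.n, cfg.length_range)
    comp = rng.random(cfg.n) < cfg.class_balance
    means = np.where(comp, mixture_means[1], mixture_means[0])
    values = rng.normal(means, mixture_sd)
    records = [
        PeptideRecord(
            id=f"p{i:06d}",
            modality=Modality.AA,
            payload=seq,
            labels={task: float(v), f"{task}_high": float(v >= threshold)},
            source=f"synth:permeability:seed={cfg.seed}",
        )
        for i, (seq, v) in enumerate(zip(seqs, values))
    ]
    return PropertyDataset(task=get_task(task), records=records)


# -- affinity -----------------------------------------------------------

_AFFINITY_SALT = 7919


def affinity_ground_truth(
    seed: int, max_pep_len: int = 12, max_prot_len: int = 64
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """The planted interaction function behind :func:`gen_affinity_pairs`.

    Returns residue propensities ``u`` (peptide side) and ``v`` (protein
    side, both length 20) and position weights ``w`` (peptide positions)
    and ``a`` (protein positions).  The raw interaction is a factorized
    position-weighted residue compatibility::

        P = sum_i w[i] * u[pep[i]] / sqrt(len(pep))
        T = sum_j a[j] * v[prot[j]] / sqrt(len(prot))
        raw = P + T + 0.5 * P * T

    i.e. ``C[x, y] = u[x] * v[y]`` applied across all position pairs with
    independent per-position weights, plus single-sided marginals.  The
    peptide position weights are zero-mean-ish (N(0.3, 1)), so discarding
    peptide positional structure (pooling) destroys most of the
    peptide-side signal.  All arrays derive deterministically from
    ``(seed, salt)`` so an independent oracle can reproduce every score.
    """
    rng = np.random.default_rng([seed, _AFFINITY_SALT])
    u = rng.normal(0.0, 1.0, size=20)
    v = rng.normal(0.0, 1.0, size=20)
    w = rng.normal(0.3, 1.0, size=max_pep_len)
    a = rng.uniform(0.5, 1.5, size=max_prot_len)
    return u, v, w, a


def _raw_affinity(
    pep: str, prot: str, u: np.ndarray, v: np.ndarray, w: np.ndarray, a: np.ndarray
) -> float:
    idx = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    P = sum(w[i] * u[idx[x]] for i, x in enumerate(pep)) / math.sqrt(len(pep))
    T = sum(a[j] * v[idx[y]] for j, y in enumerate(prot)) / math.sqrt(len(prot))
    return P + T + 0.5 * P * T


def gen_affinity_pairs(
    cfg: SynthConfig,
    pep_length_range: Tuple[int, int] = (6, 10),
    prot_length_range: Tuple[int, int] = (25, 40),
    score_range: Tuple[float, float] = (4.0, 12.0),
) -> List[AffinityPair]:
    """Paired peptide-protein records with a position-dependent true score.

    The raw position-weighted residue-compatibility interaction is
    min-max rescaled to ``score_range`` across the corpus, then Gaussian
    noise (``noise_sd``) is added; classes follow the unified-scale rule.
    """
    rng = np.random.default_rng(cfg.seed)
    u, v, w, a = affinity_ground_truth(
        cfg.seed, max_pep_len=pep_length_range[1], max_prot_len=prot_length_range[1]
    )
    peps = _random_sequences(rng, cfg.n, pep_length_range)
    prots = _random_sequences(rng, cfg.n, prot_length_range)
    raw = np.array(
        [_raw_affinity(p, t, u, v, w, a) for p, t in zip(peps, prots)]
    )
    lo, hi = raw.min(), raw.max()
    span = hi - lo if hi > lo else 1.0
    scores = score_range[0] + (raw - lo) / span * (score_range[1] - score_range[0])
    scores = scores + rng.normal(0.0, cfg.noise_sd, size=cfg.n)
    pairs = []
    for i, (pep, prot, s) in enumerate(zip(peps, prots, scores)):
        rec = PeptideRecord(
            id=f"a{i:06d}",
            modality=Modality.AA,
            payload=pep,
            labels={"binding_affinity": float(s)},
            source=f"synth:affinity:seed={cfg.seed}",
        )
        pairs.append(AffinityPair(peptide=rec, protein_seq=prot, score=float(s)))
    return pairs


# -- half-life ----------------------------------------------------------

_HALFLIFE_SALT = 6101


def gen_halflife(
    cfg: SynthConfig,
    n_stability: int = 2000,
    hours_coef: float = 1.2,
    hours_intercept: float = 1.0,
    stability_noise_sd: float = 0.1,
) -> Tuple[List[HalfLifeRecord], PropertyDataset]:
    """Sparse half-life corpus plus a large stability corpus sharing its law.

    A latent per-peptide stability ``s`` (a hidden residue-composition
    score, standardized) drives both: the stability corpus exposes
    ``s + noise`` at large n, and ``hours = exp(a*s + b + noise)`` so
    log1p(hours) correlates with ``s``.  The half-life peptides are
    included in the stability corpus under the same ids.
    """
    if cfg.n > 500:
        raise ValueError("half-life corpora are capped at n = 500 (sparsity regime)")
    rng = np.random.default_rng(cfg.seed)
    rng_law = np.random.default_rng([cfg.seed, _HALFLIFE_SALT])
    u = rng_law.normal(0.0, 1.0, size=20)
    idx = {aa: i for i, aa in enumerate(AA_ALPHABET)}

    def latent(seq: str) -> float:
        return sum(u[idx[a]] for a in seq) / math.sqrt(len(seq))

    hl_seqs = _random_sequences(rng, cfg.n, cfg.length_range)
    extra = _random_sequences(rng, max(n_stability - cfg.n, 0), cfg.length_range)
    all_seqs = hl_seqs + extra
    s = np.array([latent(q) for q in all_seqs])
    s = (s - s.mean()) / (s.std() if s.std() > 0 else 1.0)
    stab_records = [
        PeptideRecord(
            id=f"h{i:06d}",
            modality=Modality.AA,
            payload=seq,
            labels={"stability": float(si + rng.normal(0.0, stability_noise_sd))},
            source=f"synth:stability:seed={cfg.seed}",
        )
        for i, (seq, si) in enumerate(zip(all_seqs, s))
    ]
    stability_ds = PropertyDataset(task=get_task("stability"), records=stab_records)
    hours = np.exp(
        hours_coef * s[: cfg.n] + hours_intercept + rng.normal(0.0, cfg.noise_sd, cfg.n)
    )
    hl_records = [
        HalfLifeRecord(
            peptide=PeptideRecord(
                id=f"h{i:06d}",
                modality=Modality.AA,
                payload=seq,
                labels={"half_life": float(h)},
                source=f"synth:halflife:seed={cfg.seed}",
            ),
            hours=float(h),
        )
        for i, (seq, h) in enumerate(zip(hl_seqs, hours[: cfg.n]))
    ]
    return hl_records, stability_ds


def convert_to_smiles(ds: PropertyDataset) -> PropertyDataset:
    """SMILES twin of an AA corpus: same ids and labels, converted payloads."""
    records = []
    for rec in ds.records:
        if rec.modality is not Modality.AA:
            raise ValueError(f"record {rec.id!r} is not AA modality")
        records.append(
            replace(
                rec,
                modality=Modality.SMILES,
                payload=sequence_to_smiles(rec.payload),
                source=rec.source + "+fasta2smi",
            )
        )
    return PropertyDataset(task=ds.task, records=records)
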