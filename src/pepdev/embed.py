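"""Pluggable featurization.

Baseline featurizers give deterministic position-resolved matrices for AA
sequences (one-hot + physicochemical + position channels) and SMILES
strings (per-atom invariants + a folded fingerprint block), so everything
downstream is testable without pretrained weights.  External pretrained
embedders plug in through :class:`ExternalAdapter` without shipping any
weights.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Dict, Optional

import numpy as np
from rdkit import Chem

from .chem import KYTE_DOOLITTLE, circular_fingerprint, net_charge
from .core import AA_ALPHABET, PeptideRecord, ValidationError

__all__ = [
    "EmbeddingMatrix",
    "EmbedderSpec",
    "ExternalAdapter",
    "embed",
    "mean_pool",
    "baseline_sequence_featurizer",
    "baseline_smiles_featurizer",
    "EmbeddingCache",
    "BASELINE_SEQ_DIM",
    "BASELINE_SMILES_DIM",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

# one-hot(20) + hydropathy + side-chain charge at pH 7 + sinusoidal position
BASELINE_SEQ_DIM = 20 + 3

_ELEMENT_PALETTE = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
_SMILES_FP_BITS = 64
# element one-hot (+1 "other") + degree + aromatic + formal charge + fp block
BASELINE_SMILES_DIM = len(_ELEMENT_PALETTE) + 1 + 3 + _SMILES_FP_BITS


@dataclass
class EmbeddingMatrix:
    """L x D matrix of positions x channels; pooled matrices have L = 1."""

    values: np.ndarray
    pooled: bool
    featurizer_id: str
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("embedding must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains non-finite entries")
        if self.pooled and self.values.shape[0] != 1:
            raise ValueError("pooled embedding must have exactly one row")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def D(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EmbedderSpec:
    name: str
    modality: str  # "AA", "SMILES" or "protein"
    dim: int
    kind: str  # "baseline_seq", "baseline_smiles" or "external_adapter"

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("embedding dim must be positive")


BASELINE_SEQ_SPEC = EmbedderSpec("baseline-seq", "AA", BASELINE_SEQ_DIM, "baseline_seq")
BASELINE_PROTEIN_SPEC = EmbedderSpec(
    "baseline-seq", "protein", BASELINE_SEQ_DIM, "baseline_seq"
)
BASELINE_SMILES_SPEC = EmbedderSpec(
    "baseline-smiles", "SMILES", BASELINE_SMILES_DIM, "baseline_smiles"
)


@dataclass
class ExternalAdapter:
    """Contract for a pretrained embedder supplied by the user.

    The adapter must return an L x ``spec.dim`` matrix with special tokens
    already stripped; whether its pooling included special tokens must be
    documented by the adapter itself.  No weights ship with this package.
    """

    spec: EmbedderSpec
    fn: Callable[[str], np.ndarray]

    def __call__(self, payload: str) -> np.ndarray:
        out = np.asarray(self.fn(payload), dtype=np.float64)
        if out.ndim != 2 or out.shape[1] != self.spec.dim:
            raise ValueError(
                f"adapter {self.spec.name!r} returned shape {out.shape}, "
                f"expected (L, {self.spec.dim})"
            )
        return out


_ADAPTERS: Dict[str, ExternalAdapter] = {}


def register_adapter(adapter: ExternalAdapter) -> None:
    _ADAPTERS[adapter.spec.name] = adapter


def baseline_sequence_featurizer(seq: str) -> EmbeddingMatrix:
    """Per-residue one-hot + hydropathy + charge-at-pH7 + sinusoidal position."""
    if not seq or set(seq) - set(AA_ALPHABET):
        raise ValidationError(f"non-canonical sequence {seq!r}")
    L = len(seq)
    out = np.zeros((L, BASELINE_SEQ_DIM))
    for i, aa in enumerate(seq):
        out[i, _AA_INDEX[aa]] = 1.0
        out[i, 20] = KYTE_DOOLITTLE[aa] / 4.5
        out[i, 21] = _SIDECHAIN_CHARGE[aa]
        out[i, 22] = np.sin(i / 10.0)
    return EmbeddingMatrix(out, pooled=False, featurizer_id="baseline-seq")


def _sidechain_charge_table() -> Dict[str, float]:
    table = {}
    for aa in AA_ALPHABET:
        # charge contribution of the side chain alone at pH 7
        q = net_charge(aa + aa, 7.0)  # dipeptide of aa
        ref = net_charge("GG", 7.0)
        table[aa] = (q - ref) / 2.0
    return table


_SIDECHAIN_CHARGE = _sidechain_charge_table()


def baseline_smiles_featurizer(smiles: str) -> EmbeddingMatrix:
    """Per-atom invariants plus a molecule-level folded-fingerprint block.

    The fingerprint block is broadcast onto every atom row so that pooled
    and unpooled variants stay mean-consistent.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES: {smiles!r}")
    fp = circular_fingerprint(smiles, radius=2, nbits=_SMILES_FP_BITS, chirality=True)
    n_atoms = mol.GetNumAtoms()
    out = np.zeros((n_atoms, BASELINE_SMILES_DIM))
    n_el = len(_ELEMENT_PALETTE)
    for i, atom in enumerate(mol.GetAtoms()):
        sym = atom.GetSymbol()
        col = _ELEMENT_PALETTE.index(sym) if sym in _ELEMENT_PALETTE else n_el
        out[i, col] = 1.0
        out[i, n_el + 1] = atom.GetDegree() / 4.0
        out[i, n_el + 2] = 1.0 if atom.GetIsAromatic() else 0.0
        out[i, n_el + 3] = float(atom.GetFormalCharge())
        out[i, n_el + 4 :] = fp.bits
    return EmbeddingMatrix(out, pooled=False, featurizer_id="baseline-smiles")


def mean_pool(m: EmbeddingMatrix) -> EmbeddingMatrix:
    """Column means; already-pooled input is returned unchanged (idempotent)."""
    if m.pooled:
        return m
    return EmbeddingMatrix(
        m.values.mean(axis=0, keepdims=True),
        pooled=True,
        featurizer_id=m.featurizer_id,
        source_id=m.source_id,
    )


def embed(rec, spec: EmbedderSpec, pooled: bool = False) -> EmbeddingMatrix:
    """Featurize one record (or raw protein string) under a spec.

    Deterministic for a fixed input and spec.  When unpooled, L equals the
    residue count (sequence featurizer) or heavy-atom count (SMILES
    featurizer).
    """
    if isinstance(rec, PeptideRecord):
        payload, source_id = rec.payload, rec.id
        rec_modality = rec.modality.value
        if spec.modality not in (rec_modality, "protein"):
            raise ValueError(
                f"modality mismatch: record is {rec_modality}, spec expects {spec.modality}"
            )
    else:
        payload, source_id = str(rec), ""
    if spec.kind == "baseline_seq":
        m = baseline_sequence_featurizer(payload)
    elif spec.kind == "baseline_smiles":
        m = baseline_smiles_featurizer(payload)
    elif spec.kind == "external_adapter":
        adapter = _ADAPTERS.get(spec.name)
        if adapter is None:
            raise ValueError(f"adapter {spec.name!r} is not registered")
        m = EmbeddingMatrix(adapter(payload), pooled=False, featurizer_id=spec.name)
    else:
        raise ValueError(f"unknown embedder kind {spec.kind!r}")
    m.source_id = source_id
    if pooled:
        m = mean_pool(m)
    return m


class EmbeddingCache:
    """Single-file embedding cache keyed by (featurizer_id, payload hash)."""

    def __init__(self, path: Optional[str] = None):
        self.path = path
        self._store: Dict[str, np.ndarray] = {}
        self._pooled: Dict[str, bool] = {}
        if path is not None:
            import os

            if os.path.exists(path):
                with np.load(path, allow_pickle=False) as z:
                    for key in z.files:
                        if key.endswith("::pooled"):
                            continue
                        self._store[key] = z[key]
                        self._pooled[key] = bool(z[key + "::pooled"][0])

    @staticmethod
    def key(featurizer_id: str, payload: str) -> str:
        h = hashlib.sha256(payload.encode()).hexdigest()[:24]
        return f"{featurizer_id}:{h}"

    def get(self, featurizer_id: str, payload: str) -> Optional[EmbeddingMatrix]:
        k = self.key(featurizer_id, payload)
        if k not in self._store:
            return None
        return EmbeddingMatrix(
            self._store[k], pooled=self._pooled[k], featurizer_id=featurizer_id
        )

    def put(self, payload: str, m: EmbeddingMatrix) -> None:
        k = self.key(m.featurizer_id, payload)
        self._store[k] = m.values
        self._pooled[k] = m.pooled

    def save(self) -> None:
        if self.path is None:
            raise ValueError("cache has no path")
        arrays = dict(self._store)
        for k, pooled in self._pooled.items():
            arrays[k + "::pooled"] = np.array([pooled])
        np.savez(self.path, **arrays)
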