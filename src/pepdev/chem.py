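"""Chemistry and physicochemistry.

Sequence -> SMILES assembly for linear canonical peptides, circular
(Morgan/ECFP) fingerprints with Tanimoto similarity, a physicochemical
profile with a tunable-pH charge model, and the low-complexity flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .core import AA_ALPHABET, ValidationError

__all__ = [
    "Fingerprint",
    "PhyschemProfile",
    "sequence_to_smiles",
    "circular_fingerprint",
    "tanimoto",
    "physchem_profile",
    "net_charge",
    "isoelectric_point",
    "low_complexity_flag",
    "KYTE_DOOLITTLE",
    "RESIDUE_MASS",
    "WATER_MASS",
]

# Average residue masses (free amino acid minus one water), Da.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Ionizable-group pKa values.  Default scale is EMBOSS-style; the scale is
# configurable because published scales differ by a few tenths of a pH unit.
PKA_SCALES = {
    "emboss": {
        "n_term": 8.6, "c_term": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
}
DEFAULT_PKA_SCALE = "emboss"

_POSITIVE_SIDE = ("K", "R", "H")
_NEGATIVE_SIDE = ("D", "E", "C", "Y")

# Backbone fragments: N-[CA](side)-C(=O), chained left to right; the final
# residue gets a free carboxylic acid by appending "O".  Ring-closure digits
# are reused because every ring closes within its own fragment.
_RESIDUE_FRAGMENT = {
    "G": "NCC(=O)",
    "A": "N[C@@H](C)C(=O)",
    "R": "N[C@@H](CCCNC(=N)N)C(=O)",
    "N": "N[C@@H](CC(N)=O)C(=O)",
    "D": "N[C@@H](CC(=O)O)C(=O)",
    "C": "N[C@@H](CS)C(=O)",
    "E": "N[C@@H](CCC(=O)O)C(=O)",
    "Q": "N[C@@H](CCC(N)=O)C(=O)",
    "H": "N[C@@H](Cc1c[nH]cn1)C(=O)",
    "I": "N[C@@H]([C@@H](C)CC)C(=O)",
    "L": "N[C@@H](CC(C)C)C(=O)",
    "K": "N[C@@H](CCCCN)C(=O)",
    "M": "N[C@@H](CCSC)C(=O)",
    "F": "N[C@@H](Cc1ccccc1)C(=O)",
    "P": "N1CCC[C@H]1C(=O)",
    "S": "N[C@@H](CO)C(=O)",
    "T": "N[C@@H]([C@H](O)C)C(=O)",
    "W": "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)",
    "Y": "N[C@@H](Cc1ccc(O)cc1)C(=O)",
    "V": "N[C@@H](C(C)C)C(=O)",
}


def sequence_to_smiles(seq: str) -> str:
    """Assemble the SMILES of a linear peptide with free termini.

    Residues are joined by amide bonds; the N-terminus is a free amine and
    the C-terminus a free carboxylic acid.  Only L-stereochemistry is
    emitted; noncanonical chemistry enters the framework as SMILES directly.
    """
    if not seq:
        raise ValidationError("empty sequence")
    bad = sorted(set(seq) - set(AA_ALPHABET))
    if bad:
        raise ValidationError(f"non-canonical letters {', '.join(bad)}")
    smiles = "".join(_RESIDUE_FRAGMENT[aa] for aa in seq) + "O"
    if Chem.MolFromSmiles(smiles) is None:  # pragma: no cover - template bug guard
        raise ValidationError(f"assembled SMILES failed to parse: {smiles}")
    return smiles


@dataclass(frozen=True)
class Fingerprint:
    """Binary circular fingerprint (hashed atom environments)."""

    bits: np.ndarray  # uint8 0/1 vector of length nbits
    radius: int = 2
    nbits: int = 2048
    chirality: bool = True

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())

    def same_params(self, other: "Fingerprint") -> bool:
        return (
            self.radius == other.radius
            and self.nbits == other.nbits
            and self.chirality == other.chirality
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return self.same_params(other) and bool(np.array_equal(self.bits, other.bits))


def circular_fingerprint(
    smiles: str, radius: int = 2, nbits: int = 2048, chirality: bool = True
) -> Fingerprint:
    """Morgan fingerprint of a SMILES string (binary bits, folded)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=nbits, includeChirality=chirality
    )
    fp = gen.GetFingerprintAsNumPy(mol)
    return Fingerprint(
        bits=np.asarray(fp, dtype=np.uint8), radius=radius, nbits=nbits, chirality=chirality
    )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a AND b| / |a OR b|; two all-zero fingerprints are defined as 1.0."""
    if not a.same_params(b):
        raise ValueError("fingerprint parameter mismatch")
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        return 1.0
    return inter / union


def _check_seq(seq: str) -> None:
    bad = sorted(set(seq) - set(AA_ALPHABET))
    if bad:
        raise ValidationError(f"non-canonical letters {', '.join(bad)}")


def net_charge(seq: str, pH: float = 7.0, pka_scale: str = DEFAULT_PKA_SCALE) -> float:
    """Henderson-Hasselbalch net charge over termini and ionizable side chains."""
    _check_seq(seq)
    if not (0.0 < pH < 14.0):
        raise ValidationError(f"pH {pH} outside (0, 14)")
    pka = PKA_SCALES[pka_scale]
    pos = 1.0 / (1.0 + 10.0 ** (pH - pka["n_term"]))
    neg = 1.0 / (1.0 + 10.0 ** (pka["c_term"] - pH))
    for aa in seq:
        if aa in _POSITIVE_SIDE:
            pos += 1.0 / (1.0 + 10.0 ** (pH - pka[aa]))
        elif aa in _NEGATIVE_SIDE:
            neg += 1.0 / (1.0 + 10.0 ** (pka[aa] - pH))
    return pos - neg


def isoelectric_point(
    seq: str, pka_scale: str = DEFAULT_PKA_SCALE, tol: float = 1e-4
) -> float:
    """pH of zero net charge, by bisection (net charge is decreasing in pH)."""
    lo, hi = 1e-6, 14.0 - 1e-6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid, pka_scale)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class PhyschemProfile:
    mw: float
    pI: float
    gravy: float
    net_charge: float
    pH: float
    length: int
    n_unique: int
    complexity_ratio: float


def physchem_profile(
    seq: str, pH: float = 7.0, pka_scale: str = DEFAULT_PKA_SCALE
) -> PhyschemProfile:
    """Molecular weight, pI, GRAVY, net charge at pH, and complexity stats."""
    _check_seq(seq)
    if len(seq) < 2:
        raise ValidationError("profile requires length >= 2")
    mw = sum(RESIDUE_MASS[aa] for aa in seq) + WATER_MASS
    gravy = sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq)
    n_unique = len(set(seq))
    return PhyschemProfile(
        mw=mw,
        pI=isoelectric_point(seq, pka_scale),
        gravy=gravy,
        net_charge=net_charge(seq, pH, pka_scale),
        pH=pH,
        length=len(seq),
        n_unique=n_unique,
        complexity_ratio=len(seq) / n_unique,
    )


def low_complexity_flag(seq: str) -> bool:
    """True iff length / n_unique > 5 (strict inequality)."""
    _check_seq(seq)
    return len(seq) / len(set(seq)) > 5.0
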