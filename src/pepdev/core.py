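"""Domain types shared by every stage: records, tasks, datasets.

A :class:`PeptideRecord` is one peptide in one representation modality
(canonical amino-acid string or SMILES) carrying any number of property
labels.  Datasets are thin views that select one task over a record
collection and enforce its label contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

__all__ = [
    "AA_ALPHABET",
    "Modality",
    "TaskType",
    "PeptideRecord",
    "PropertyTask",
    "PropertyDataset",
    "ValidationError",
    "validate_record",
    "dataset_summary",
    "TASK_REGISTRY",
    "get_task",
]

#: The 20 canonical residue letters.  U, O, B, Z, X are rejected on the AA
#: path; noncanonical chemistry enters through the SMILES modality.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

#: Minimum AA length: a single residue has no peptide bond.
MIN_AA_LENGTH = 2


class Modality(str, Enum):
    AA = "AA"
    SMILES = "SMILES"


class TaskType(str, Enum):
    BINARY = "binary"
    REGRESSION = "regression"
    PAIRED_REGRESSION = "paired_regression"


class ValidationError(ValueError):
    """Raised when a record or dataset violates a domain invariant."""


@dataclass
class PeptideRecord:
    """One peptide in one modality with its property labels.

    Parameters
    ----------
    id : str
        Opaque identifier, unique within a dataset.
    modality : Modality
        ``AA`` for canonical residue strings, ``SMILES`` otherwise.
    payload : str
        The sequence or SMILES string.
    labels : dict
        Property name -> value (0/1 for binary tasks, finite float for
        regression tasks).
    source : str
        Free-text provenance tag.
    cluster_id : int, optional
        Filled in by the clustering stage.
    """

    id: str
    modality: Modality
    payload: str
    labels: dict = field(default_factory=dict)
    source: str = ""
    cluster_id: Optional[int] = None

    def __post_init__(self) -> None:
        if isinstance(self.modality, str) and not isinstance(self.modality, Modality):
            self.modality = Modality(self.modality)

    def with_labels(self, **labels: float) -> "PeptideRecord":
        merged = dict(self.labels)
        merged.update(labels)
        return replace(self, labels=merged)


@dataclass(frozen=True)
class PropertyTask:
    """One prediction task: a named property with its type and modalities."""

    name: str
    task_type: TaskType
    modalities: frozenset = frozenset({Modality.AA, Modality.SMILES})
    positive_meaning: str = ""
    threshold: Optional[float] = None
    requires_protein: bool = False

    def __post_init__(self) -> None:
        if self.name not in KNOWN_TASK_NAMES:
            raise ValidationError(
                f"unknown task name {self.name!r}; known: {sorted(KNOWN_TASK_NAMES)}"
            )


KNOWN_TASK_NAMES = frozenset(
    {
        "hemolysis",
        "non_fouling",
        "toxicity",
        "solubility",
        "permeability_penetrance",
        "permeability_pampa",
        "permeability_caco2",
        "half_life",
        "stability",
        "binding_affinity",
    }
)

# The two permeability assays quantify different processes and are kept as
# distinct tasks end to end, never merged.
TASK_REGISTRY: dict = {
    "hemolysis": PropertyTask("hemolysis", TaskType.BINARY, positive_meaning="hemolytic"),
    "non_fouling": PropertyTask("non_fouling", TaskType.BINARY, positive_meaning="non-fouling"),
    "toxicity": PropertyTask(
        "toxicity",
        TaskType.BINARY,
        modalities=frozenset({Modality.SMILES}),
        positive_meaning="toxic",
    ),
    "solubility": PropertyTask(
        "solubility",
        TaskType.BINARY,
        modalities=frozenset({Modality.AA}),
        positive_meaning="soluble",
    ),
    "permeability_penetrance": PropertyTask(
        "permeability_penetrance",
        TaskType.BINARY,
        modalities=frozenset({Modality.AA}),
        positive_meaning="cell-penetrating",
    ),
    "permeability_pampa": PropertyTask(
        "permeability_pampa",
        TaskType.REGRESSION,
        modalities=frozenset({Modality.SMILES}),
        threshold=-6.0,
    ),
    "permeability_caco2": PropertyTask(
        "permeability_caco2",
        TaskType.REGRESSION,
        modalities=frozenset({Modality.SMILES}),
        threshold=-6.0,
    ),
    "half_life": PropertyTask("half_life", TaskType.REGRESSION),
    "stability": PropertyTask(
        "stability", TaskType.REGRESSION, modalities=frozenset({Modality.AA})
    ),
    "binding_affinity": PropertyTask(
        "binding_affinity", TaskType.PAIRED_REGRESSION, requires_protein=True
    ),
}


def get_task(name: str) -> PropertyTask:
    try:
        return TASK_REGISTRY[name]
    except KeyError:
        raise ValidationError(f"unknown task {name!r}") from None


def validate_record(rec: PeptideRecord) -> PeptideRecord:
    """Check all record invariants; return the record unchanged if valid.

    Idempotent: validating a validated record is a no-op.
    """
    if not rec.payload:
        raise ValidationError(f"record {rec.id!r}: empty payload")
    if rec.modality is Modality.AA:
        bad = sorted(set(rec.payload) - _AA_SET)
        if bad:
            raise ValidationError(
                f"record {rec.id!r}: non-canonical letters {', '.join(bad)}"
            )
        if len(rec.payload) < MIN_AA_LENGTH:
            raise ValidationError(
                f"record {rec.id!r}: AA payload shorter than {MIN_AA_LENGTH} residues"
            )
    for name, value in rec.labels.items():
        if value is None or not math.isfinite(float(value)):
            raise ValidationError(f"record {rec.id!r}: non-finite label {name}={value!r}")
    return rec


def _check_binary(value: float) -> bool:
    return float(value) in (0.0, 1.0)


@dataclass
class PropertyDataset:
    """A record collection viewed through one task."""

    task: PropertyTask
    records: list = field(default_factory=list)
    split: Optional[object] = None  # SplitAssignment, kept loose to avoid a cycle

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> "PropertyDataset":
        seen: set = set()
        for rec in self.records:
            validate_record(rec)
            if rec.id in seen:
                raise ValidationError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            if self.task.name not in rec.labels:
                raise ValidationError(
                    f"record {rec.id!r} has no label for task {self.task.name!r}"
                )
            if self.task.task_type is TaskType.BINARY and not _check_binary(
                rec.labels[self.task.name]
            ):
                raise ValidationError(
                    f"record {rec.id!r}: binary label must be 0 or 1, got "
                    f"{rec.labels[self.task.name]!r}"
                )
        return self

    def labels(self) -> list:
        return [float(r.labels[self.task.name]) for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def summary(self) -> dict:
        return dataset_summary(self)


def dataset_summary(ds: PropertyDataset) -> dict:
    """Per-class counts for binary tasks; n/min/max/mean for regression."""
    n = len(ds.records)
    if n == 0:
        return {"n": 0}
    values = ds.labels()
    if ds.task.task_type is TaskType.BINARY:
        c1 = sum(1 for v in values if v == 1.0)
        return {"n": n, "class0": n - c1, "class1": c1}
    return {
        "n": n,
        "min": min(values),
        "max": max(values),
        "mean": sum(values) / n,
    }
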