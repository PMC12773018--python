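"""Readers/writers: FASTA, tabular datasets, split manifests, model artifacts.

Dataset tables are UTF-8 CSV/TSV with an explicit ``modality`` column
(some SMILES strings are also valid residue strings, so modality is never
inferred).  Split manifests carry the clustering method, parameters and
seed so every split is reproducible and auditable.  Model artifacts embed
a probe input/output pair and a parameter checksum for load-time
self-verification.
"""

from __future__ import annotations

import hashlib
import json
import os
import pickle
import warnings
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .core import (
    Modality,
    PeptideRecord,
    PropertyDataset,
    PropertyTask,
    ValidationError,
    validate_record,
)
from .embed import EmbeddingMatrix
from .heads import TrainedHead, predict_head
from .split import PARTITIONS, SplitAssignment

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_dataset_table",
    "write_dataset_table",
    "read_split_manifest",
    "write_split_manifest",
    "save_model_artifact",
    "load_model_artifact",
    "ArtifactError",
]

ARTIFACT_VERSION = "1"


class ArtifactError(RuntimeError):
    pass


# -- FASTA --------------------------------------------------------------


def read_fasta(path: str) -> List[Tuple[str, str]]:
    """(id, uppercased sequence) pairs; id is the first header token."""
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if not stripped:
        warnings.warn(f"empty FASTA file {path}", stacklevel=2)
        return []
    if not stripped.startswith(">"):
        raise ValidationError(f"{path}: sequence data before the first FASTA header")
    out = []
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            out.append((header.split()[0] if header.split() else "", seq.upper()))
    return out


def write_fasta(records: Sequence[Tuple[str, str]], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- dataset tables -----------------------------------------------------

_BASE_COLUMNS = ("id", "input", "modality")


def _detect_sep(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def read_dataset_table(
    path: str, task: PropertyTask, permissive: bool = False
) -> PropertyDataset:
    """Load a dataset table into validated records for one task.

    Rows failing validation abort the load with their line number unless
    ``permissive`` is set, in which case they are reported and skipped.
    """
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "input": str, "modality": str})
    for col in _BASE_COLUMNS + (task.name,):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate record ids: {sorted(set(dupes))}")
    records, skipped = [], []
    for row_i, row in df.iterrows():
        line_no = row_i + 2  # header is line 1
        try:
            raw = row[task.name]
            try:
                label = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(f"unparseable label {raw!r}") from None
            rec = PeptideRecord(
                id=str(row["id"]),
                modality=Modality(str(row["modality"])),
                payload=str(row["input"]),
                labels={task.name: label},
                source=os.path.basename(path),
            )
            if "protein_target" in df.columns and not pd.isna(row["protein_target"]):
                rec.protein_target = str(row["protein_target"])  # type: ignore[attr-defined]
            validate_record(rec)
            records.append(rec)
        except (ValidationError, ValueError) as exc:
            if permissive:
                skipped.append((line_no, str(exc)))
            else:
                raise ValidationError(f"{path}:{line_no}: {exc}") from exc
    if skipped:
        warnings.warn(
            f"{path}: skipped {len(skipped)} invalid rows: "
            + "; ".join(f"line {ln}: {msg}" for ln, msg in skipped[:5]),
            stacklevel=2,
        )
    ds = PropertyDataset(task=task, records=records)
    ds.sep = sep  # record the detected delimiter
    return ds


def write_dataset_table(ds: PropertyDataset, path: str, sep: str = "\t") -> None:
    rows = []
    for rec in ds.records:
        row = {"id": rec.id, "input": rec.payload, "modality": rec.modality.value}
        row.update(rec.labels)
        prot = getattr(rec, "protein_target", None)
        if prot is not None:
            row["protein_target"] = prot
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# -- split manifests ----------------------------------------------------


def write_split_manifest(split: SplitAssignment, path: str) -> None:
    split.validate()
    with open(path, "w") as fh:
        fh.write(f"# method={split.method}\n")
        fh.write(f"# params={json.dumps(split.params, sort_keys=True)}\n")
        fh.write(f"# seed={split.seed}\n")
        fh.write(f"# train_frac={split.train_frac}\n")
        fh.write("record_id\tcluster_id\tpartition\n")
        for rid in sorted(split.cluster_of):
            cid = split.cluster_of[rid]
            fh.write(f"{rid}\t{cid}\t{split.partition_of[cid]}\n")


def read_split_manifest(path: str) -> SplitAssignment:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key] = value
                continue
            rows.append(line.split("\t"))
    if not rows or rows[0] != ["record_id", "cluster_id", "partition"]:
        raise ValidationError(f"{path}: missing or malformed manifest header")
    cluster_of, partition_of = {}, {}
    for rid, cid_s, part in rows[1:]:
        if part not in PARTITIONS:
            raise ValidationError(f"{path}: unknown partition token {part!r}")
        if rid in cluster_of:
            raise ValidationError(f"{path}: record {rid!r} appears more than once")
        cid = int(cid_s)
        if cid in partition_of and partition_of[cid] != part:
            raise ValidationError(f"{path}: cluster {cid} spans both partitions")
        cluster_of[rid] = cid
        partition_of[cid] = part
    seed_s = meta.get("seed", "")
    return SplitAssignment(
        cluster_of=cluster_of,
        partition_of=partition_of,
        train_frac=float(meta.get("train_frac", 0.8)),
        seed=int(seed_s) if seed_s not in ("", "None") else None,
        method=meta.get("method", "unknown"),
        params=json.loads(meta.get("params", "{}")),
    ).validate()


# -- model artifacts ----------------------------------------------------


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def save_model_artifact(head: TrainedHead, outdir: str, probe_X=None) -> None:
    """Persist a fitted head with metadata, checksum, and a probe pair.

    ``probe_X`` defaults to nothing — pass a small batch (2-8 inputs) of
    the head's input type; its predictions are stored and re-checked
    bit-exactly at load time.
    """
    os.makedirs(outdir, exist_ok=True)
    params_path = os.path.join(outdir, "params.pkl")
    with open(params_path, "wb") as fh:
        pickle.dump({"model": head.model, "y_scale": head.y_scale}, fh)
    probe_meta = None
    if probe_X is not None:
        mats = [
            m.values if isinstance(m, EmbeddingMatrix) else np.asarray(m, float)
            for m in probe_X
        ]
        out = predict_head(head, probe_X)
        arrays = {f"in_{i}": m for i, m in enumerate(mats)}
        arrays["out"] = out
        np.savez(os.path.join(outdir, "probe.npz"), **arrays)
        probe_meta = {"n": len(mats)}
    meta = {
        "artifact_version": ARTIFACT_VERSION,
        "family": head.spec.family,
        "task_type": head.spec.task_type,
        "hyperparams": list(head.spec.hyperparams),
        "input_mode": head.spec.input_mode,
        "loss": head.spec.loss,
        "huber_delta": head.spec.huber_delta,
        "seed": head.spec.seed,
        "featurizer_id": head.featurizer_id,
        "train_meta": head.train_meta,
        "metrics": head.metrics.to_dict() if head.metrics is not None else None,
        "params_sha256": _sha256(params_path),
        "probe": probe_meta,
    }
    with open(os.path.join(outdir, "metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def load_model_artifact(indir: str) -> TrainedHead:
    """Load a head, verifying version, checksum and probe predictions."""
    from .heads import HeadSpec
    from .metrics import MetricReport

    meta_path = os.path.join(indir, "metadata.json")
    if not os.path.exists(meta_path):
        raise ArtifactError(f"{indir}: no metadata.json (not a model artifact)")
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta.get("artifact_version") != ARTIFACT_VERSION:
        raise ArtifactError(
            f"{indir}: artifact version {meta.get('artifact_version')!r} != {ARTIFACT_VERSION!r}"
        )
    params_path = os.path.join(indir, "params.pkl")
    if _sha256(params_path) != meta["params_sha256"]:
        raise ArtifactError(f"{indir}: parameter file checksum mismatch")
    with open(params_path, "rb") as fh:
        payload = pickle.load(fh)
    spec = HeadSpec(
        family=meta["family"],
        task_type=meta["task_type"],
        hyperparams=dict(tuple(kv) for kv in meta["hyperparams"]),
        input_mode=meta["input_mode"],
        loss=meta["loss"],
        huber_delta=meta["huber_delta"],
        seed=meta["seed"],
    )
    metrics = MetricReport(**meta["metrics"]) if meta.get("metrics") else None
    head = TrainedHead(
        spec=spec,
        model=payload["model"],
        featurizer_id=meta.get("featurizer_id", ""),
        train_meta=meta.get("train_meta", {}),
        metrics=metrics,
        y_scale=tuple(payload["y_scale"]),
    )
    probe_path = os.path.join(indir, "probe.npz")
    if meta.get("probe") and os.path.exists(probe_path):
        with np.load(probe_path) as z:
            mats = [z[f"in_{i}"] for i in range(meta["probe"]["n"])]
            expected = z["out"]
        got = predict_head(head, mats)
        if not np.array_equal(got, expected):
            raise ArtifactError(f"{indir}: probe predictions differ after reload")
    return head
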