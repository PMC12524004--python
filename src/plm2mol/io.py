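"""Plain-text interchange: TSV pair/embedding/score tables, FASTA
sequences, JSON manifests, and decoder checkpoints."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .curation import InteractionPair, RawRecord
from .decoder import DecoderConfig, ParameterSet

__all__ = [
    "read_pairs",
    "write_pairs",
    "read_raw_records",
    "read_embeddings",
    "write_embeddings",
    "read_fasta",
    "read_scores",
    "write_scores",
    "save_checkpoint",
    "load_checkpoint",
    "file_checksum",
]


def read_raw_records(path: str | Path) -> list[RawRecord]:
    """Read a raw interaction table (TSV with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "smiles": str})
    required = {"protein_id", "smiles"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        if not isinstance(row.smiles, str) or not row.smiles:
            raise ValueError(f"{path}: line {line}: empty SMILES")
        records.append(
            RawRecord(
                protein_id=row.protein_id,
                smiles=row.smiles,
                affinity_nM=(
                    float(row.affinity_nM)
                    if "affinity_nM" in df.columns and pd.notna(row.affinity_nM)
                    else None
                ),
                assay_type=(
                    row.assay_type
                    if "assay_type" in df.columns and pd.notna(row.assay_type)
                    else None
                ),
                organism=(
                    row.organism
                    if "organism" in df.columns and pd.notna(row.organism)
                    else None
                ),
            )
        )
    return records


def read_pairs(path: str | Path) -> list[InteractionPair]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "smiles": str})
    missing = {"protein_id", "smiles"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        InteractionPair(
            protein_id=row.protein_id,
            smiles=row.smiles,
            affinity_nM=(
                float(row.affinity_nM)
                if "affinity_nM" in df.columns and pd.notna(row.affinity_nM)
                else None
            ),
        )
        for row in df.itertuples(index=False)
    ]


def write_pairs(pairs: Sequence[InteractionPair], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in pairs],
            "smiles": [p.smiles for p in pairs],
            "affinity_nM": [p.affinity_nM for p in pairs],
        }
    )
    if df["affinity_nM"].isna().all():
        df = df.drop(columns=["affinity_nM"])
    df.to_csv(path, sep="\t", index=False)


def read_embeddings(path: str | Path) -> dict[str, np.ndarray]:
    """Read a per-protein embedding table (id + d real columns, TSV).

    All rows must share one dimension; duplicate ids are an error.
    """
    out: dict[str, np.ndarray] = {}
    dim: Optional[int] = None
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise ValueError(f"{path}: line 1: expected header starting 'protein_id'")
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {line_no}: malformed row")
            pid, values = parts[0], parts[1:]
            if pid in out:
                raise ValueError(f"{path}: line {line_no}: duplicate id {pid!r}")
            vec = np.array([float(v) for v in values])
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise ValueError(
                    f"{path}: line {line_no}: dimension {vec.size} != {dim}"
                )
            out[pid] = vec
    return out


def write_embeddings(embeddings: dict[str, np.ndarray], path: str | Path) -> None:
    dims = {np.asarray(v).size for v in embeddings.values()}
    if len(dims) > 1:
        raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")
    d = dims.pop() if dims else 0
    with open(path, "w") as fh:
        fh.write("protein_id\t" + "\t".join(f"e{i}" for i in range(d)) + "\n")
        for pid, vec in embeddings.items():
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in vec) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a (protein_id, smiles, score) DTI score table."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "smiles": str})
    missing = {"protein_id", "smiles", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_scores(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def save_checkpoint(params: ParameterSet, path: str | Path) -> None:
    """Single-file checkpoint: config JSON plus named weight arrays."""
    arrays = dict(params.weights)
    arrays["__positional__"] = params.positional
    np.savez(
        path,
        __config__=np.frombuffer(
            json.dumps(params.config.to_dict()).encode(), dtype=np.uint8
        ),
        **arrays,
    )


def load_checkpoint(path: str | Path) -> ParameterSet:
    with np.load(path) as data:
        config = DecoderConfig.from_dict(
            json.loads(bytes(data["__config__"]).decode())
        )
        positional = data["__positional__"]
        weights = {
            k: data[k]
            for k in data.files
            if k not in ("__config__", "__positional__")
        }
    return ParameterSet(config=config, weights=weights, positional=positional)


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
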