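"""File-format interfaces: FASTA/FASTQ, JSON target specs, TSV tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .align import ReadClass
from .amplicon import AmpliconSpec, EditSpec
from .quantify import QuantResult

__all__ = [
    "amplicon_from_json",
    "amplicon_to_json",
    "classifications_to_tsv",
    "population_to_tsv",
    "quant_to_json",
    "quant_to_tsv",
    "read_fasta",
    "read_fastq",
    "write_fastq",
]

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> dict[str, str]:
    """Name -> uppercase sequence for every record in a FASTA file."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def read_fastq(path: PathLike) -> list[tuple[str, str]]:
    """(read_id, sequence) pairs from a FASTQ file."""
    return [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(
    records: Iterable[tuple[str, str, str]], path: PathLike
) -> None:
    """Write (read_id, sequence, quality) tuples as FASTQ."""
    with open(path, "w") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def amplicon_to_json(spec: AmpliconSpec, path: PathLike) -> None:
    payload = {
        "name": spec.name,
        "ref_seq": spec.ref_seq,
        "spacer": spec.spacer,
        "edit": asdict(spec.edit),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def amplicon_from_json(
    path: PathLike, ref_seq: str | None = None
) -> AmpliconSpec:
    """Load a target spec; ``ref_seq`` (e.g. from FASTA) overrides the JSON."""
    payload = json.loads(Path(path).read_text())
    edit = EditSpec(**payload["edit"])
    return AmpliconSpec.from_sequences(
        name=payload["name"],
        ref_seq=ref_seq or payload["ref_seq"],
        spacer=payload["spacer"],
        edit=edit,
    )


def classifications_to_tsv(
    read_ids: Sequence[str], classes: Sequence[ReadClass], path: PathLike
) -> pd.DataFrame:
    """Per-read TSV: read id, label and indel descriptor."""
    rows = []
    for rid, cls in zip(read_ids, classes):
        indel = ""
        if cls.indel is not None:
            indel = (
                f"{cls.indel.kind}:{cls.indel.ref_position}:"
                f"{cls.indel.length}:{cls.indel.inserted}"
            )
        rows.append(
            {
                "read_id": rid,
                "label": cls.label,
                "anchor_identity": round(cls.anchor_identity, 4),
                "filter_reason": cls.filter_reason or "",
                "indel": indel,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def quant_to_tsv(
    results: dict[str, QuantResult], path: PathLike
) -> pd.DataFrame:
    """Per-sample TSV of all quantification fields (percentages to 2 dp)."""
    rows = []
    for sample, q in results.items():
        row = {"sample": sample, **asdict(q)}
        for key in ("editing_pct", "indel_pct", "specificity"):
            row[key] = round(row[key], 2)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def quant_to_json(results: dict[str, QuantResult], path: PathLike) -> None:
    payload = {sample: asdict(q) for sample, q in results.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def population_to_tsv(cells: pd.DataFrame, path: PathLike) -> None:
    cells.to_csv(path, sep="\t", index=False)
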