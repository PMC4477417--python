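"""FASTA reading and writing, including gapped (aligned) FASTA pairs."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .align import AlignmentResult, SequenceRecord

_LINE_WIDTH = 60


def read_fasta(path) -> list[SequenceRecord]:
    """Read plain (ungapped) FASTA; records in file order, upper-cased.

    Multi-line sequences are concatenated.  Raises on an empty file and on
    gap characters (use :func:`read_aligned_pair` for aligned FASTA).
    """
    records = [
        SequenceRecord(rec.id, str(rec.seq), rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_fasta_pair(path_x, path_y=None) -> tuple[SequenceRecord, SequenceRecord]:
    """The sequence pair to align: two files, or the first two records of one."""
    if path_y is None:
        records = read_fasta(path_x)
        if len(records) < 2:
            raise ValueError(f"{path_x} must contain two records when used alone")
        return records[0], records[1]
    return read_fasta(path_x)[0], read_fasta(path_y)[0]


def _wrap(seq: str) -> str:
    return "\n".join(seq[i : i + _LINE_WIDTH] for i in range(0, len(seq), _LINE_WIDTH))


def format_fasta(records: Iterable[tuple[str, str]]) -> str:
    """Format (header, sequence) pairs as FASTA text."""
    chunks = []
    for header, seq in records:
        body = _wrap(seq) if seq else ""
        chunks.append(f">{header}\n{body}\n" if seq else f">{header}\n")
    return "".join(chunks)


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    Path(path).write_text(
        format_fasta(
            (rec.description if rec.description else rec.id, rec.residues)
            for rec in records
        )
    )


def write_aligned_pair(result: AlignmentResult, path) -> None:
    """Write the two gapped sequences of an alignment as aligned FASTA."""
    Path(path).write_text(
        format_fasta([(result.x_id, result.aligned_x), (result.y_id, result.aligned_y)])
    )


def read_aligned_pair(path) -> AlignmentResult:
    """Read an aligned FASTA file of exactly two equal-length gapped records."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path} must contain exactly two aligned records, found {len(records)}")
    ax, ay = (str(r.seq).upper() for r in records)
    return AlignmentResult(ax, ay, math.nan, "external", records[0].id, records[1].id)
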