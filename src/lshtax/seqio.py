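"""Thin FASTA/FASTQ readers (multi-record, gzip-transparent), via Biopython."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

__all__ = ["read_fasta", "read_fastq", "read_sequences"]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter(path: str | Path, fmt: str) -> Iterator[tuple[str, str]]:
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, fmt):
            yield record.id, str(record.seq)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    yield from _iter(path, "fasta")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    yield from _iter(path, "fastq")


def read_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Read records from FASTA or FASTQ, sniffing the format from the
    first non-blank character ('>' vs '@')."""
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                fmt = "fastq" if line.startswith("@") else "fasta"
                break
        else:
            return []
    return list(_iter(path, fmt))
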