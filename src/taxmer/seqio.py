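"""FASTA/FASTQ ingestion: gzip and format autodetection.

Compression is detected from the gzip magic bytes, format from the first
non-blank character of the decompressed text ('>' FASTA, '@' FASTQ).
Parsing is delegated to Biopython's lightweight iterators; sequences are
upper-cased on ingest.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class SeqFileError(ValueError):
    """Unreadable or unrecognisable sequence file."""


def open_text(path: str | Path) -> IO[str]:
    """Open a possibly gzip-compressed file as text."""
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            magic = fh.read(2)
    except OSError as e:
        raise SeqFileError(f"cannot read {path}: {e.strerror}") from e
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def sniff_format(path: str | Path) -> str:
    """Return 'fasta', 'fastq', or 'empty'."""
    with open_text(path) as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s[0] == ">":
                return "fasta"
            if s[0] == "@":
                return "fastq"
            raise SeqFileError(
                f"{path}: neither FASTA nor FASTQ (first record starts {s[0]!r})"
            )
    return "empty"


def read_seqs(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, upper-cased sequence) from a FASTA or FASTQ file."""
    fmt = sniff_format(path)
    if fmt == "empty":
        return
    with open_text(path) as fh:
        if fmt == "fasta":
            for title, seq in SimpleFastaParser(fh):
                yield title.split()[0] if title else "", seq.upper()
        else:
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield title.split()[0] if title else "", seq.upper()


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, seq, qual) from a FASTQ file (seq upper-cased)."""
    if sniff_format(path) == "empty":
        return
    with open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title, seq.upper(), qual


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", newline="\n") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
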