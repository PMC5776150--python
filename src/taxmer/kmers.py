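"""Canonical k-mer encoding, extraction and the KLIST text format.

A k-mer is packed into one unsigned 64-bit integer, two bits per base
(A=0, C=1, G=2, T=3) with the 5'-most base in the most significant bit
pair, so integer order on codes equals lexicographic order on the
strings.  The canonical form of a k-mer is the lexicographically smaller
of the k-mer and its reverse complement; every list, panel and report in
this package stores canonical codes only, so one entry represents both
strands.  k is capped at 32 so any code fits a single 64-bit word.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from . import seqio

MAX_K = 32

_BASES = "ACGT"
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


class KmerError(ValueError):
    """Invalid k-mer, k value or k-mer list."""


def _check_k(k: int) -> None:
    if not 1 <= k <= MAX_K:
        raise KmerError(f"k must be in 1..{MAX_K}, got {k}")


def encode(kmer: str) -> int:
    """Pack an ACGT string into its 2-bit code (no canonicalization)."""
    _check_k(len(kmer))
    code = 0
    for pos, base in enumerate(kmer):
        val = _ENC[ord(base)] if ord(base) < 256 else 255
        if val > 3:
            raise KmerError(f"non-ACGT character {base!r} at position {pos}")
        code = (code << 2) | int(val)
    return code


def decode(code: int, k: int) -> str:
    """Inverse of :func:`encode`."""
    _check_k(k)
    if not 0 <= code < 4**k:
        raise KmerError(f"code {code} out of range for k={k}")
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    """Code of the reverse complement of the k-mer with this code."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def canonicalize(kmer: str) -> int:
    """Canonical code: min of the k-mer's code and its reverse complement's.

    Because the 2-bit encoding preserves lexicographic order, this is the
    code of the lexicographically smaller of the two orientations.
    """
    code = encode(kmer)
    return min(code, revcomp_code(code, len(kmer)))


@dataclass
class KmerList:
    """Sorted canonical k-mer/count table — the pipeline's universal currency.

    ``codes`` is strictly ascending (uint64), ``counts`` positive int64 of
    the same length.  ``n_sources`` records how many input files (genomes
    or read sets) were aggregated; ``source_label`` is free text.
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray
    n_sources: int = 1
    source_label: str = ""

    def __post_init__(self) -> None:
        _check_k(self.k)
        self.codes = np.asarray(self.codes, dtype=np.uint64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.codes.shape != self.counts.shape or self.codes.ndim != 1:
            raise KmerError("codes and counts must be 1-D arrays of equal length")
        if len(self.codes) and not np.all(self.codes[1:] > self.codes[:-1]):
            raise KmerError("codes must be strictly ascending (sorted, unique)")
        if len(self.counts) and self.counts.min() < 1:
            raise KmerError("all counts must be >= 1")
        if self.n_sources < 1:
            raise KmerError("n_sources must be >= 1")

    def __len__(self) -> int:
        return len(self.codes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerList):
            return NotImplemented
        return (
            self.k == other.k
            and np.array_equal(self.codes, other.codes)
            and np.array_equal(self.counts, other.counts)
        )

    def total_count(self) -> int:
        return int(self.counts.sum())

    def entries(self) -> Iterator[tuple[int, int]]:
        """Yield (code, count) pairs in ascending code order."""
        for c, n in zip(self.codes.tolist(), self.counts.tolist()):
            yield c, n

    def kmer_strings(self) -> Iterator[str]:
        for c in self.codes.tolist():
            yield decode(c, self.k)

    @classmethod
    def empty(cls, k: int, source_label: str = "") -> "KmerList":
        return cls(
            k,
            np.empty(0, np.uint64),
            np.empty(0, np.int64),
            source_label=source_label,
        )

    @classmethod
    def from_counts(
        cls,
        k: int,
        mapping: dict[int, int] | Iterable[tuple[int, int]],
        n_sources: int = 1,
        source_label: str = "",
    ) -> "KmerList":
        items = sorted(dict(mapping).items())
        codes = np.array([c for c, _ in items], dtype=np.uint64)
        counts = np.array([n for _, n in items], dtype=np.int64)
        return cls(k, codes, counts, n_sources=n_sources, source_label=source_label)


# ---------------------------------------------------------------------------
# window extraction (vectorised)

def _seq_vals(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return _ENC[raw]


def window_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Codes of every valid length-k window of *seq*.

    Returns ``(starts, fwd, canon)``: 0-based start positions of windows
    containing only A/C/G/T (case-insensitive), their forward-strand codes
    and their canonical codes.  Windows touching any other symbol are
    skipped.
    """
    _check_k(k)
    vals = _seq_vals(seq)
    L = len(vals)
    if L < k:
        e = np.empty(0, np.int64)
        return e, np.empty(0, np.uint64), np.empty(0, np.uint64)
    bad = (vals > 3).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0  # per window start
    starts = np.nonzero(valid)[0].astype(np.int64)
    if len(starts) == 0:
        return starts, np.empty(0, np.uint64), np.empty(0, np.uint64)
    v = np.where(vals > 3, 0, vals).astype(np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(v, k)[starts]
    pw_f = (np.uint64(1) << (np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64)))
    fwd = (win * pw_f).sum(axis=1, dtype=np.uint64)
    pw_r = pw_f[::-1]
    rev = ((np.uint64(3) - win) * pw_r).sum(axis=1, dtype=np.uint64)
    canon = np.minimum(fwd, rev)
    return starts, fwd, canon


def extract_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical codes of every A/C/G/T-only window, in sequence order."""
    return window_codes(seq, k)[2]


def _aggregate(code_arrays: list[np.ndarray], k: int, **kw) -> KmerList:
    nonempty = [a for a in code_arrays if len(a)]
    if not nonempty:
        return KmerList(k, np.empty(0, np.uint64), np.empty(0, np.int64), **kw)
    allc = np.concatenate(nonempty)
    codes, counts = np.unique(allc, return_counts=True)
    return KmerList(k, codes, counts.astype(np.int64), **kw)


def count_seqs(seqs: Iterable[str], k: int, **kw) -> KmerList:
    """Aggregate canonical k-mer counts over an iterable of sequences."""
    chunks = [extract_kmers(s, k) for s in seqs]
    return _aggregate(chunks, k, **kw)


def build_list(
    paths: Sequence[str | Path] | str | Path,
    k: int,
    source_label: str | None = None,
) -> KmerList:
    """Canonical k-mer list aggregating every record of every given file.

    Accepts FASTA or FASTQ, plain or gzip-compressed (autodetected).
    Counts are total canonical occurrences across all records.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if not paths:
        raise KmerError("at least one input file required")
    _check_k(k)
    chunks: list[np.ndarray] = []
    for p in paths:
        for _rid, seq in seqio.read_seqs(p):
            chunks.append(extract_kmers(seq, k))
    label = source_label if source_label is not None else ",".join(
        Path(p).name for p in paths
    )
    return _aggregate(chunks, k, n_sources=len(paths), source_label=label)


# ---------------------------------------------------------------------------
# KLIST v1 text format

class KlistFormatError(ValueError):
    """Malformed KLIST file; message carries the offending line number."""


def write_klist(lst: KmerList, path: str | Path) -> None:
    """Write KLIST v1: a tab-separated header then one k-mer/count per line."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", newline="\n") as fh:
        fh.write(
            f"#KLIST\t1\tk={lst.k}\tn={len(lst)}\tsource={lst.source_label}\n"
        )
        for kmer, count in zip(lst.kmer_strings(), lst.counts.tolist()):
            fh.write(f"{kmer}\t{count}\n")


def read_klist(path: str | Path) -> KmerList:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline()
        fields = header.rstrip("\n").split("\t")
        if len(fields) < 4 or fields[0] != "#KLIST" or fields[1] != "1":
            raise KlistFormatError(f"{path}: line 1: not a KLIST v1 header")
        try:
            k = int(fields[2].removeprefix("k="))
            n = int(fields[3].removeprefix("n="))
        except ValueError:
            raise KlistFormatError(f"{path}: line 1: bad k=/n= header fields")
        source = fields[4].removeprefix("source=") if len(fields) > 4 else ""
        codes = np.empty(n, np.uint64)
        counts = np.empty(n, np.int64)
        i = 0
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            if i >= n:
                raise KlistFormatError(
                    f"{path}: line {lineno}: more than n={n} body lines"
                )
            try:
                kmer, cnt = line.split("\t")
                count = int(cnt)
            except ValueError:
                raise KlistFormatError(f"{path}: line {lineno}: malformed entry")
            if len(kmer) != k:
                raise KlistFormatError(
                    f"{path}: line {lineno}: k-mer length != k={k}"
                )
            try:
                code = encode(kmer)
            except KmerError as e:
                raise KlistFormatError(f"{path}: line {lineno}: {e}")
            if count < 1:
                raise KlistFormatError(f"{path}: line {lineno}: count < 1")
            if i and code <= codes[i - 1]:
                raise KlistFormatError(
                    f"{path}: line {lineno}: k-mers out of order or duplicated"
                )
            codes[i] = code
            counts[i] = count
            i += 1
        if i != n:
            raise KlistFormatError(
                f"{path}: header n={n} but body has {i} entries"
            )
    return KmerList(k, codes, counts, source_label=source)
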