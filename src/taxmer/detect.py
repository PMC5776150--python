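"""Panel detection in raw reads and deterministic FASTQ subsampling.

Detection scans each read once, counts every canonical window occurrence
of a panel k-mer (a k-mer appearing twice in one read counts twice, and
both strands count), and summarises the panel at a ladder of frequency
cutoffs.  Raw reads are used as-is: no quality filtering or trimming.

Subsampling keeps every s-th read (stride = floor(n_total / n_out),
starting at index 0) so that large FASTQ files are thinned evenly along
the file; records are copied verbatim.  A ``prefix`` mode (first n_out
reads) is also provided — every-Nth subsamples at different n_out are
not nested subsets of each other.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import seqio
from .kmers import KmerError, KmerList, extract_kmers

DEFAULT_CUTOFFS = (1, 2, 5, 10)
_BATCH_READS = 20_000


@dataclass(frozen=True)
class DetectionConfig:
    """Frequency cutoffs at which to summarise detection."""

    cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS

    def __post_init__(self) -> None:
        c = self.cutoffs
        if not c or any(x < 1 for x in c) or any(b <= a for a, b in zip(c, c[1:])):
            raise KmerError(
                f"cutoffs must be strictly ascending positive integers, got {c}"
            )


@dataclass
class DetectionReport:
    """Per-k-mer occurrence counts of a panel in a read set."""

    k: int
    panel_codes: np.ndarray
    counts: np.ndarray       # aligned with panel_codes
    n_reads: int
    read_files: list[str] = field(default_factory=list)

    @property
    def panel_size(self) -> int:
        return len(self.panel_codes)

    def detected(self, cutoff: int) -> int:
        """Number of panel k-mers with occurrence count >= cutoff."""
        return int((self.counts >= cutoff).sum())


def count_in_reads(
    panel: KmerList, reads: Sequence[str | Path] | str | Path
) -> DetectionReport:
    """Count canonical occurrences of every panel k-mer over all reads.

    Reads shorter than k contribute nothing; windows containing non-ACGT
    symbols are skipped; quality strings are ignored.
    """
    if len(panel) == 0:
        raise KmerError("panel is empty")
    if isinstance(reads, (str, Path)):
        reads = [reads]
    counts = np.zeros(len(panel), np.int64)
    n_reads = 0
    batch: list[str] = []

    def flush() -> None:
        nonlocal batch
        if not batch:
            return
        codes = np.concatenate([extract_kmers(s, panel.k) for s in batch])
        batch = []
        if len(codes) == 0:
            return
        idx = np.searchsorted(panel.codes, codes)
        idx_c = np.minimum(idx, len(panel) - 1)
        hit = (idx < len(panel)) & (panel.codes[idx_c] == codes)
        np.add.at(counts, idx_c[hit], 1)

    for path in reads:
        for _t, seq, _q in seqio.read_fastq(path):
            n_reads += 1
            batch.append(seq)
            if len(batch) >= _BATCH_READS:
                flush()
    flush()
    return DetectionReport(
        k=panel.k,
        panel_codes=panel.codes.copy(),
        counts=counts,
        n_reads=n_reads,
        read_files=[str(p) for p in reads],
    )


def detected_at_cutoffs(
    report: DetectionReport, cfg: DetectionConfig = DetectionConfig()
) -> Mapping[int, int]:
    """For each cutoff f, the number of panel k-mers with count >= f."""
    return {f: report.detected(f) for f in cfg.cutoffs}


def write_report(
    report: DetectionReport,
    path: str | Path,
    cfg: DetectionConfig = DetectionConfig(),
) -> None:
    """TSV report: a cutoff summary block, then per-k-mer counts."""
    from .kmers import decode

    with open(path, "w", newline="\n") as fh:
        fh.write(f"#panel_size\t{report.panel_size}\n")
        fh.write(f"#n_reads\t{report.n_reads}\n")
        for f, n in detected_at_cutoffs(report, cfg).items():
            fh.write(f"cutoff\t{f}\t{n}\n")
        for code, count in zip(report.panel_codes.tolist(), report.counts.tolist()):
            fh.write(f"{decode(code, report.k)}\t{count}\n")


# ---------------------------------------------------------------------------
# subsampling

def _fastq_records(path: str | Path) -> Iterable[list[str]]:
    """Raw 4-line FASTQ records, text preserved verbatim."""
    with seqio.open_text(path) as fh:
        while True:
            rec = [fh.readline() for _ in range(4)]
            if rec[0] == "":
                return
            if any(line == "" for line in rec[1:]):
                raise seqio.SeqFileError(f"{path}: truncated FASTQ record at EOF")
            yield rec


def count_fastq_reads(path: str | Path) -> int:
    return sum(1 for _ in _fastq_records(path))


def subsample_every_nth(
    in_path: str | Path,
    out_path: str | Path,
    n_out: int,
    mode: str = "every_nth",
) -> Path:
    """Write exactly *n_out* reads picked deterministically from a FASTQ.

    ``every_nth``: keeps reads at indices 0, s, 2s, ... with stride
    s = floor(n_total / n_out), truncated to n_out records.  ``prefix``:
    keeps the first n_out reads.  Records are copied byte-for-byte.
    """
    if mode not in ("every_nth", "prefix"):
        raise ValueError(f"unknown subsampling mode {mode!r}")
    if n_out < 1:
        raise ValueError(f"n_out must be >= 1, got {n_out}")
    out_path = Path(out_path)
    if mode == "every_nth":
        n_total = count_fastq_reads(in_path)
        if n_out > n_total:
            raise ValueError(
                f"requested {n_out} reads but file has only {n_total}"
            )
        stride = n_total // n_out
    else:
        stride = 1
    opener = gzip.open if out_path.suffix == ".gz" else open
    written = 0
    with opener(out_path, "wt", newline="") as out:
        for i, rec in enumerate(_fastq_records(in_path)):
            if written >= n_out:
                break
            if i % stride == 0:
                out.writelines(rec)
                written += 1
    if written < n_out:
        raise ValueError(f"requested {n_out} reads but file has only {written}")
    return out_path
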