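"""Map a specific-k-mer panel onto a reference and merge hits into
clustered taxon-specific regions.

Every reference window whose canonical code is in the panel yields one
hit at the window's forward coordinates, with the strand of the matching
orientation.  Hits whose k-length intervals overlap or touch (next start
within k of the previous start) are merged into one cluster, so a run of
n hits at consecutive start positions spans n + k - 1 bp.  Coordinates
are 0-based half-open (BED convention) everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from . import seqio
from .kmers import KmerError, KmerList, window_codes


class KmerHit(NamedTuple):
    ref_id: str
    start: int          # 0-based
    strand: str         # '+' or '-'
    code: int           # canonical code


@dataclass
class ClusterRegion:
    ref_id: str
    start: int          # 0-based inclusive
    end: int            # exclusive
    n_kmers: int        # hit positions inside the region

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class ClusterReport:
    k: int
    clusters: list[ClusterRegion]
    gaps: list[int]     # start(next) - end(previous), same reference only

    def spans(self) -> list[int]:
        return [c.span for c in self.clusters]


def locate(panel: KmerList, reference: str | Path) -> list[KmerHit]:
    """All panel-k-mer occurrences in the reference, sorted by (ref, start).

    Strand is '+' where the forward window equals its canonical form and
    '-' where the reverse complement does (palindromes report '+').
    """
    if len(panel) == 0:
        raise KmerError("panel is empty")
    records = list(seqio.read_seqs(reference))
    if not records or all(len(s) == 0 for _r, s in records):
        raise KmerError(f"empty reference: {reference}")
    hits: list[KmerHit] = []
    for rid, seq in records:
        starts, fwd, canon = window_codes(seq, panel.k)
        if len(starts) == 0:
            continue
        idx = np.searchsorted(panel.codes, canon)
        idx_c = np.minimum(idx, len(panel) - 1)
        mask = (idx < len(panel)) & (panel.codes[idx_c] == canon)
        for s, f, c in zip(
            starts[mask].tolist(), fwd[mask].tolist(), canon[mask].tolist()
        ):
            hits.append(KmerHit(rid, s, "+" if f == c else "-", c))
    hits.sort(key=lambda h: (h.ref_id, h.start))
    return hits


def cluster_hits(hits: Sequence[KmerHit], k: int) -> ClusterReport:
    """Merge sorted hits into maximal clusters of overlapping/adjacent k-mers."""
    if any(
        (a.ref_id, a.start) > (b.ref_id, b.start) for a, b in zip(hits, hits[1:])
    ):
        raise KmerError("hits must be sorted by (ref_id, start)")
    clusters: list[ClusterRegion] = []
    gaps: list[int] = []
    cur_ref: str | None = None
    cur_start = cur_last = -1
    cur_n = 0

    def close() -> None:
        nonlocal cur_n
        if cur_n:
            region = ClusterRegion(cur_ref, cur_start, cur_last + k, cur_n)
            if clusters and clusters[-1].ref_id == region.ref_id:
                gaps.append(region.start - clusters[-1].end)
            clusters.append(region)
            cur_n = 0

    for h in hits:
        if cur_n and h.ref_id == cur_ref and h.start <= cur_last + k:
            if h.start != cur_last:
                cur_n += 1
                cur_last = h.start
            # duplicate position (e.g. '+' and '-' hit at one start): one position
        else:
            close()
            cur_ref, cur_start, cur_last, cur_n = h.ref_id, h.start, h.start, 1
    close()
    return ClusterReport(k=k, clusters=clusters, gaps=gaps)


def write_bed(report: ClusterReport, path: str | Path) -> None:
    """BED6: ref, start, end, cluster id, n_kmers in score column."""
    with open(path, "w", newline="\n") as fh:
        for i, c in enumerate(report.clusters, start=1):
            fh.write(
                f"{c.ref_id}\t{c.start}\t{c.end}\tcluster_{i}\t{c.n_kmers}\t.\n"
            )


def write_gaps(report: ClusterReport, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gap_index\tgap_bp\n")
        for i, g in enumerate(report.gaps, start=1):
            fh.write(f"{i}\t{g}\n")
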