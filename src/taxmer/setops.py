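"""Set algebra over sorted canonical k-mer lists.

The universality union keeps k-mers present (count >= 1) in at least m
input lists — presence is binary per list (a list counts once no matter
the multiplicity), because the cutoff counts genomes, not copies.  The
count carried on a union entry is the sum of counts over all input
lists.  Intersection keeps the minimum of the two counts (the most
conservative shared multiplicity); subtraction removes by code only and
preserves the left operand's counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Sequence

import numpy as np

from .kmers import KmerError, KmerList


def _require_same_k(lists: Sequence[KmerList]) -> int:
    ks = {l.k for l in lists}
    if len(ks) != 1:
        raise KmerError(f"mixed k values: {sorted(ks)}")
    return ks.pop()


def _membership(sorted_codes: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Boolean mask: which queries occur in sorted_codes."""
    if len(sorted_codes) == 0 or len(queries) == 0:
        return np.zeros(len(queries), dtype=bool)
    idx = np.searchsorted(sorted_codes, queries)
    idx_c = np.minimum(idx, len(sorted_codes) - 1)
    return (idx < len(sorted_codes)) & (sorted_codes[idx_c] == queries)


@dataclass
class PresenceUnion:
    """Union of lists annotated with per-code presence breadth."""

    k: int
    codes: np.ndarray          # strictly ascending uint64
    total_counts: np.ndarray   # summed over all input lists
    n_lists_present: np.ndarray
    n_lists: int


def presence_union(lists: Sequence[KmerList]) -> PresenceUnion:
    if not lists:
        raise KmerError("presence_union of zero lists")
    k = _require_same_k(lists)
    nonempty = [l for l in lists if len(l)]
    if not nonempty:
        e = np.empty(0, np.int64)
        return PresenceUnion(k, np.empty(0, np.uint64), e, e.copy(), len(lists))
    allc = np.concatenate([l.codes for l in nonempty])
    allcnt = np.concatenate([l.counts for l in nonempty])
    codes, inv = np.unique(allc, return_inverse=True)
    totals = np.zeros(len(codes), np.int64)
    np.add.at(totals, inv, allcnt)
    present = np.zeros(len(codes), np.int64)
    np.add.at(present, inv, 1)  # each list contributes each code at most once
    return PresenceUnion(k, codes, totals, present, len(lists))


def union_min_presence(lists: Sequence[KmerList], m: int) -> KmerList:
    """k-mers present in at least *m* of the input lists.

    Returned counts are summed over all input lists (provenance only;
    downstream steps are presence-based).
    """
    pu = presence_union(lists)
    if not 1 <= m <= pu.n_lists:
        raise KmerError(f"min-presence m={m} out of range 1..{pu.n_lists}")
    keep = pu.n_lists_present >= m
    return KmerList(
        pu.k,
        pu.codes[keep],
        pu.total_counts[keep],
        n_sources=pu.n_lists,
        source_label=f"union(m>={m})",
    )


def subtract(a: KmerList, b: KmerList) -> KmerList:
    """Entries of *a* whose code is absent from *b*; a's counts preserved."""
    _require_same_k([a, b])
    keep = ~_membership(b.codes, a.codes)
    return KmerList(
        a.k, a.codes[keep], a.counts[keep],
        n_sources=a.n_sources, source_label=a.source_label,
    )


def intersect(a: KmerList, b: KmerList) -> KmerList:
    """Codes present in both lists, with the minimum of the two counts."""
    _require_same_k([a, b])
    mask_a = _membership(b.codes, a.codes)
    codes = a.codes[mask_a]
    idx_b = np.searchsorted(b.codes, codes)
    counts = np.minimum(a.counts[mask_a], b.counts[idx_b])
    return KmerList(a.k, codes, counts, source_label="intersect")


def intersect_many(lists: Sequence[KmerList]) -> KmerList:
    return reduce(intersect, lists)


def filter_min_count(a: KmerList, f: int) -> KmerList:
    """Entries with count >= f, counts preserved."""
    if f < 1:
        raise KmerError(f"min count must be >= 1, got {f}")
    keep = a.counts >= f
    return KmerList(
        a.k, a.codes[keep], a.counts[keep],
        n_sources=a.n_sources, source_label=a.source_label,
    )
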