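"""Naive pure-string reference implementations used to cross-check the
vectorised code.  Deliberately slow and independent: dictionaries of
k-mer strings, no bit packing, no numpy."""

from __future__ import annotations

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    kmer = kmer.upper()
    return min(kmer, revcomp(kmer))


def count_kmers(seqs, k: int) -> dict[str, int]:
    """Canonical k-mer counts over sequences; non-ACGT windows skipped."""
    counts: dict[str, int] = {}
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if any(b not in "ACGT" for b in w):
                continue
            c = canonical(w)
            counts[c] = counts.get(c, 0) + 1
    return counts


def union_min_presence(count_dicts, m: int) -> dict[str, int]:
    presence: dict[str, int] = {}
    totals: dict[str, int] = {}
    for d in count_dicts:
        for kmer, n in d.items():
            presence[kmer] = presence.get(kmer, 0) + 1
            totals[kmer] = totals.get(kmer, 0) + n
    return {km: totals[km] for km, p in presence.items() if p >= m}


def subtract(a: dict[str, int], b: dict[str, int]) -> dict[str, int]:
    return {km: n for km, n in a.items() if km not in b}


def intersect(a: dict[str, int], b: dict[str, int]) -> dict[str, int]:
    return {km: min(n, b[km]) for km, n in a.items() if km in b}


def locate_hits(panel_kmers: set[str], seq: str, k: int):
    """(start, strand) of every window whose canonical form is in the panel."""
    hits = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k].upper()
        if any(b not in "ACGT" for b in w):
            continue
        c = canonical(w)
        if c in panel_kmers:
            hits.append((i, "+" if c == w else "-"))
    return hits
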