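"""Synthetic plastome-like panels with ground truth, for end-to-end tests.

A panel emulates the data regime of chloroplast-based marker discovery:
an ancestral genome with the canonical plastome architecture — a large
single-copy region (LSC), an inverted repeat (IR_A), a small single-copy
region (SSC) and a second inverted repeat (IR_B) that is the exact
reverse complement of IR_A.  The IRs are highly conserved across plants,
so the generator never mutates them: both copies stay identical across
every genome, which is what empties them of specific k-mers.  Target
genomes share a set of planted target-private substitutions (the signal)
plus low-rate private substitutions (intra-taxon polymorphism); each
non-target genome diverges independently at a higher rate.  Mutations
are substitution-only so the exhaustive window oracle stays exact;
indels are a documented extension point.

The truth panel is computed by brute force on plain strings — every
window of every genome, canonicalised with min(s, revcomp(s)) — and is
deliberately independent of the vectorised counting code it validates.

Default scale is a 20 kb genome (11 kb LSC, 3.2 kb IRs, 2.6 kb SSC),
5 targets and 10 non-targets: seconds per full pipeline run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .kmers import KmerError, KmerList, MAX_K, encode

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PanelParams:
    """Generator knobs; defaults are the toy-scale study conditions."""

    seed: int = 0
    lsc_len: int = 11_000
    ssc_len: int = 2_600
    ir_len: int = 3_200
    n_targets: int = 5
    n_nontargets: int = 10
    target_intra_divergence: float = 5e-4
    nontarget_divergence: float = 1e-2
    n_private_variants: int = 5
    k: int = 32
    read_length: int = 100
    error_rate: float = 1e-3
    n_reads: int = 20_000

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise KmerError("all region lengths must be > 0")
        for rate in (self.target_intra_divergence, self.nontarget_divergence,
                     self.error_rate):
            if not 0 <= rate < 1:
                raise KmerError(f"rates must be in [0, 1), got {rate}")
        if self.n_targets < 1:
            raise KmerError("n_targets must be >= 1")
        if not 1 <= self.k <= MAX_K:
            raise KmerError(f"k must be in 1..{MAX_K}")

    @property
    def genome_len(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len

    def ir_intervals(self) -> list[tuple[int, int]]:
        """0-based half-open [start, end) of IR_A and IR_B."""
        a = (self.lsc_len, self.lsc_len + self.ir_len)
        b_start = self.lsc_len + self.ir_len + self.ssc_len
        return [a, (b_start, b_start + self.ir_len)]

    def single_copy_positions(self) -> np.ndarray:
        lsc = np.arange(self.lsc_len)
        ssc_start = self.lsc_len + self.ir_len
        ssc = np.arange(ssc_start, ssc_start + self.ssc_len)
        return np.concatenate([lsc, ssc])


@dataclass
class PanelTruth:
    """Generated genomes plus the exhaustively computed specific panel."""

    params: PanelParams
    target_seqs: list[str]
    nontarget_seqs: list[str]
    variant_positions: list[int]
    oracle_panel: KmerList


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, length)])


def _substitute(seq: list[str], pos: int, rng: np.random.Generator) -> None:
    alts = [b for b in _BASES if b != seq[pos]]
    seq[pos] = alts[rng.integers(0, 3)]


def _mutate(
    base: str,
    rate: float,
    allowed: np.ndarray,
    rng: np.random.Generator,
) -> str:
    """Substitutions at *rate* per allowed position."""
    seq = list(base)
    n_mut = rng.binomial(len(allowed), rate)
    for pos in rng.choice(allowed, size=n_mut, replace=False):
        _substitute(seq, int(pos), rng)
    return "".join(seq)


def canonical_kmer_counts(seq: str, k: int) -> dict[str, int]:
    """Naive per-window canonical counting on plain strings (the oracle)."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(b not in _BASES for b in w):
            continue
        canon = min(w, revcomp(w))
        counts[canon] = counts.get(canon, 0) + 1
    return counts


def oracle_specific_panel(
    target_seqs: Sequence[str],
    nontarget_seqs: Sequence[str],
    k: int,
    m: int,
    nontarget_read_seqs: Sequence[Sequence[str]] = (),
    min_freq: int = 10,
) -> KmerList:
    """Exhaustive-comparison truth panel.

    Keeps canonical k-mers present in >= m target genomes and absent
    from every non-target genome; optionally also removes k-mers seen
    with count >= min_freq in any non-target read collection.  Counts
    are summed over target genomes.
    """
    per_target = [canonical_kmer_counts(s, k) for s in target_seqs]
    presence: dict[str, int] = {}
    totals: dict[str, int] = {}
    for counts in per_target:
        for kmer, n in counts.items():
            presence[kmer] = presence.get(kmer, 0) + 1
            totals[kmer] = totals.get(kmer, 0) + n
    forbidden: set[str] = set()
    for s in nontarget_seqs:
        forbidden.update(canonical_kmer_counts(s, k))
    for read_seqs in nontarget_read_seqs:
        pooled: dict[str, int] = {}
        for r in read_seqs:
            for kmer, n in canonical_kmer_counts(r, k).items():
                pooled[kmer] = pooled.get(kmer, 0) + n
        forbidden.update(km for km, n in pooled.items() if n >= min_freq)
    keep = {
        encode(kmer): totals[kmer]
        for kmer, pres in presence.items()
        if pres >= m and kmer not in forbidden
    }
    return KmerList.from_counts(k, keep, source_label="oracle")


def generate_panel(params: PanelParams, m: int = 2) -> PanelTruth:
    """Build the genome panel and its brute-force truth panel.

    Private variants are placed in single-copy regions at least k-1 bp
    from region boundaries and at least 2k bp apart, so each variant's
    covering windows stay within one region and variants do not share
    windows; all other mutations are rate-driven.
    """
    rng = np.random.default_rng(params.seed)
    lsc = _random_seq(rng, params.lsc_len)
    ir_a = _random_seq(rng, params.ir_len)
    ssc = _random_seq(rng, params.ssc_len)
    ancestor = lsc + ir_a + ssc + revcomp(ir_a)
    sc = params.single_copy_positions()
    margin = params.k - 1

    # candidate positions comfortably inside LSC or SSC
    lsc_ok = np.arange(margin, params.lsc_len - margin)
    ssc_start = params.lsc_len + params.ir_len
    ssc_ok = np.arange(ssc_start + margin, ssc_start + params.ssc_len - margin)
    candidates = np.concatenate([lsc_ok, ssc_ok]) if len(ssc_ok) else lsc_ok
    variant_positions: list[int] = []
    rng.shuffle(candidates)
    for pos in candidates:
        if len(variant_positions) == params.n_private_variants:
            break
        if all(abs(int(pos) - v) >= 2 * params.k for v in variant_positions):
            variant_positions.append(int(pos))
    if len(variant_positions) < params.n_private_variants:
        raise KmerError(
            f"cannot place {params.n_private_variants} private variants in "
            f"the available single-copy positions"
        )
    variant_positions.sort()

    shared = list(ancestor)
    for pos in variant_positions:
        _substitute(shared, pos, rng)
    target_base = "".join(shared)

    target_seqs = [
        _mutate(target_base, params.target_intra_divergence, sc, rng)
        for _ in range(params.n_targets)
    ]
    nontarget_seqs = [
        _mutate(ancestor, params.nontarget_divergence, sc, rng)
        for _ in range(params.n_nontargets)
    ]
    oracle = oracle_specific_panel(target_seqs, nontarget_seqs, params.k, m)
    return PanelTruth(
        params=params,
        target_seqs=target_seqs,
        nontarget_seqs=nontarget_seqs,
        variant_positions=variant_positions,
        oracle_panel=oracle,
    )


def simulate_reads(
    genome: str,
    params: PanelParams,
    out_path: str | Path,
    seed: int | None = None,
    n_reads: int | None = None,
) -> Path:
    """Uniform-start single-end reads from either strand, substitution
    errors at ``error_rate``, constant quality, fixed-seed deterministic."""
    out_path = Path(out_path)
    L = len(genome)
    rl = params.read_length
    if rl > L:
        raise KmerError(f"read_length {rl} exceeds genome length {L}")
    n = params.n_reads if n_reads is None else n_reads
    rng = np.random.default_rng(params.seed if seed is None else seed)
    qual = "I" * rl
    with open(out_path, "w", newline="\n") as fh:
        for i in range(n):
            start = int(rng.integers(0, L - rl + 1))
            read = genome[start : start + rl]
            if rng.integers(0, 2):
                read = revcomp(read)
            if params.error_rate > 0:
                seq = list(read)
                n_err = rng.binomial(rl, params.error_rate)
                for pos in rng.choice(rl, size=n_err, replace=False):
                    _substitute(seq, int(pos), rng)
                read = "".join(seq)
            fh.write(f"@read_{i}\n{read}\n+\n{qual}\n")
    return out_path


def write_panel(truth: PanelTruth, outdir: str | Path, with_reads: bool = False) -> dict:
    """Write FASTA genomes, the truth KLIST and a parameter manifest.

    Returns a manifest dict mapping roles to file paths.
    """
    from . import seqio
    from .kmers import write_klist

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "params": asdict(truth.params),
        "variant_positions": truth.variant_positions,
        "targets": [],
        "nontargets": [],
        "reads": [],
    }
    for i, seq in enumerate(truth.target_seqs):
        p = outdir / f"target_{i}.fa"
        seqio.write_fasta([(f"target_{i}", seq)], p)
        manifest["targets"].append(str(p))
    for i, seq in enumerate(truth.nontarget_seqs):
        p = outdir / f"nontarget_{i}.fa"
        seqio.write_fasta([(f"nontarget_{i}", seq)], p)
        manifest["nontargets"].append(str(p))
    truth_path = outdir / "truth_panel.klist"
    write_klist(truth.oracle_panel, truth_path)
    manifest["truth_panel"] = str(truth_path)
    if with_reads:
        p = outdir / "target_0_reads.fq"
        simulate_reads(
            truth.target_seqs[0], truth.params, p, seed=truth.params.seed + 1
        )
        manifest["reads"].append(str(p))
    with open(outdir / "panel_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
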