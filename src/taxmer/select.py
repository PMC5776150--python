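"""Taxon-specific k-mer selection.

The pipeline: build one canonical k-mer list per target genome file,
keep k-mers present in at least ``min_targets`` of them (the
universality cutoff, which discards individual-specific k-mers), then
remove non-specific k-mers in two steps — first every k-mer occurring in
any non-target assembly, then every k-mer occurring with frequency at
least ``nontarget_read_min_freq`` in a non-target whole-genome read set.
The read-frequency cutoff treats low-count occurrences as sequencing
noise rather than genuine presence; read sets are filtered per file, not
pooled, so one deep sample cannot mask another's noise.

The default configuration mirrors the headline run: k=32, presence in at
least 2 target genomes, read-frequency cutoff 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import setops
from .kmers import KmerError, KmerList, MAX_K, build_list

logger = logging.getLogger(__name__)

DEFAULT_K_SWEEP = (8, 12, 16, 20, 24, 28, 32)


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the selection pipeline."""

    k: int = 32
    min_targets: int = 2
    nontarget_read_min_freq: int = 10

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise KmerError(f"k must be in 1..{MAX_K}, got {self.k}")
        if self.min_targets < 1:
            raise KmerError("min_targets must be >= 1")
        if self.nontarget_read_min_freq < 1:
            raise KmerError("nontarget_read_min_freq must be >= 1")


@dataclass
class SpecificKmerSet:
    """Final taxon-specific panel with its provenance and per-step log."""

    panel: KmerList
    config: SelectionConfig
    target_files: list[str]
    nontarget_assembly_files: list[str]
    nontarget_read_files: list[str]
    step_counts: dict[str, int] = field(default_factory=dict)


def select_specific(
    targets: Sequence[str | Path],
    nontarget_assemblies: Sequence[str | Path] = (),
    nontarget_readsets: Sequence[str | Path] = (),
    cfg: SelectionConfig = SelectionConfig(),
) -> SpecificKmerSet:
    """Run the full selection pipeline on genome and read files.

    Each target file is one genome (the unit of presence for the
    universality cutoff).  Deterministic for fixed inputs.
    """
    if not targets:
        raise KmerError("at least one target genome file is required")
    if cfg.min_targets > len(targets):
        raise KmerError(
            f"min_targets={cfg.min_targets} exceeds number of "
            f"target files ({len(targets)})"
        )
    target_lists = [build_list(p, cfg.k) for p in targets]
    if all(len(l) == 0 for l in target_lists):
        raise KmerError("all target k-mer lists are empty")
    steps: dict[str, int] = {}
    panel = setops.union_min_presence(target_lists, cfg.min_targets)
    steps["target_union_min_presence"] = len(panel)
    logger.info(
        "universality filter (m>=%d): %d k-mers", cfg.min_targets, len(panel)
    )

    for p in nontarget_assemblies:
        nt = build_list(p, cfg.k)
        panel = setops.subtract(panel, nt)
    steps["after_nontarget_assemblies"] = len(panel)
    logger.info(
        "after subtracting %d non-target assemblies: %d k-mers",
        len(nontarget_assemblies), len(panel),
    )

    for p in nontarget_readsets:
        reads = build_list(p, cfg.k)
        frequent = setops.filter_min_count(reads, cfg.nontarget_read_min_freq)
        panel = setops.subtract(panel, frequent)
    steps["after_nontarget_reads"] = len(panel)
    logger.info(
        "after subtracting %d non-target read sets (freq >= %d): %d k-mers",
        len(nontarget_readsets), cfg.nontarget_read_min_freq, len(panel),
    )

    panel.source_label = "specific"
    return SpecificKmerSet(
        panel=panel,
        config=cfg,
        target_files=[str(p) for p in targets],
        nontarget_assembly_files=[str(p) for p in nontarget_assemblies],
        nontarget_read_files=[str(p) for p in nontarget_readsets],
        step_counts=steps,
    )


def k_sweep(
    targets: Sequence[str | Path],
    nontarget_assemblies: Sequence[str | Path] = (),
    nontarget_readsets: Sequence[str | Path] = (),
    cfg_base: SelectionConfig = SelectionConfig(),
    ks: Sequence[int] = DEFAULT_K_SWEEP,
) -> Mapping[int, int]:
    """Panel size at each k-mer length; used to pick the most productive k."""
    sizes: dict[int, int] = {}
    for k in ks:
        cfg = SelectionConfig(
            k=k,
            min_targets=cfg_base.min_targets,
            nontarget_read_min_freq=cfg_base.nontarget_read_min_freq,
        )
        result = select_specific(targets, nontarget_assemblies, nontarget_readsets, cfg)
        sizes[k] = len(result.panel)
    return sizes
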