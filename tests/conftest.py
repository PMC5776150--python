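import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from taxmer import KmerList


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def klist_from_strings(mapping: dict[str, int], k: int) -> KmerList:
    """Build a KmerList from canonical k-mer strings -> counts."""
    from taxmer import encode

    return KmerList.from_counts(k, {encode(s): n for s, n in mapping.items()})


def klist_to_strings(lst: KmerList) -> dict[str, int]:
    return dict(zip(lst.kmer_strings(), lst.counts.tolist()))


@pytest.fixture
def rng():
    return np.random.default_rng(17)


@pytest.fixture
def write_fasta(tmp_path):
    counter = [0]

    def _write(seqs, name=None):
        counter[0] += 1
        p = tmp_path / (name or f"seqs_{counter[0]}.fa")
        with open(p, "w") as fh:
            for i, s in enumerate(seqs if not isinstance(seqs, str) else [seqs]):
                fh.write(f">rec_{i}\n{s}\n")
        return p

    return _write


@pytest.fixture
def write_fastq(tmp_path):
    counter = [0]

    def _write(seqs, name=None):
        counter[0] += 1
        p = tmp_path / (name or f"reads_{counter[0]}.fq")
        with open(p, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n")
        return p

    return _write
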