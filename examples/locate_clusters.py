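"""Map a specific-k-mer panel back onto a reference genome.

Locates every panel k-mer occurrence on a target genome, merges
overlapping/adjacent occurrences into clustered taxon-specific regions,
and prints per-cluster spans and the gaps between clusters.
"""

import tempfile
from pathlib import Path

from taxmer import PanelParams, cluster_hits, generate_panel, locate
from taxmer import seqio

truth = generate_panel(PanelParams(seed=7), m=2)
workdir = Path(tempfile.mkdtemp())
ref = workdir / "target_0.fa"
seqio.write_fasta([("target_0", truth.target_seqs[0])], ref)

hits = locate(truth.oracle_panel, ref)
report = cluster_hits(hits, truth.params.k)

spans = report.spans()
print(f"panel k-mers:   {len(truth.oracle_panel)}")
print(f"hits on ref:    {len(hits)}")
print(f"clusters:       {len(report.clusters)}")
print(f"spans (bp):     {min(spans)}-{max(spans)}  "
      f"mean {sum(spans)/len(spans):.1f}")
if report.gaps:
    print(f"gaps (bp):      {min(report.gaps)}-{max(report.gaps)}")
for i, c in enumerate(report.clusters, 1):
    print(f"  cluster_{i}: {c.ref_id}:{c.start}-{c.end}  "
          f"{c.n_kmers} k-mers, {c.span} bp")
# a cluster of n consecutive overlapping 32-mers spans n + 31 bp; clusters
# sit only in single-copy regions because the inverted repeats are
# identical across all genomes.
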