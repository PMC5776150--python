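# taxmer

Discover taxon-specific k-mers from assembled genomes and detect them
directly in raw sequencing reads — no alignment, no assembly.

## The problem

Identifying a species in a mixed or unlabelled DNA sample usually means
amplifying and sequencing a barcode locus, or aligning reads against
reference databases. An alternative is an exact-match panel: the set of
canonical k-mers (a k-mer and its reverse complement count as one) that
occur in the genomes of the target taxon but in no other known genome.
Such a panel can be matched against raw reads in a single streaming
pass, which makes it useful for screening metagenomics-style samples.
Chloroplast genomes are a natural substrate for plants: they are small
(115–165 kb), heavily sequenced, and their single-copy regions carry
enough substitutions to distinguish even congeneric species, while the
two inverted repeats (IRs) are too conserved to contribute markers.

## The method

Given FASTA files of target genomes (one genome per file), non-target
genomes, and optionally non-target whole-genome read sets:

1. **Count** — build a sorted canonical k-mer list per genome
   (k ≤ 32, 2-bit packed).
2. **Universality filter** — keep k-mers present in at least *m* target
   genomes (default m = 2), discarding individual-specific k-mers.
3. **Specificity filter, step 1** — remove every k-mer occurring in any
   non-target assembly.
4. **Specificity filter, step 2** — remove every k-mer occurring with
   frequency ≥ *f* (default 10) in a non-target read set; counts below
   the cutoff are treated as sequencing noise, not presence.

The surviving panel is *specific* (absent from all non-targets) and
*universal* (present in ≥ m targets). Detection in a read sample counts
canonical occurrences of every panel k-mer across all read windows and
reports how many panel k-mers reach each frequency cutoff (default
ladder 1, 2, 5, 10). Mapping the panel back to a reference merges
overlapping/adjacent occurrences into clustered taxon-specific regions:
a run of *n* consecutive k-mer starts spans *n* + *k* − 1 bp.

A synthetic-panel generator (`taxmer.simulate`) emulates the plastome
data regime — LSC + IR + SSC + IR architecture with identical IRs,
controlled divergence, planted target-private variants, error-bearing
reads — and computes the ground-truth panel by exhaustive window
comparison, so the whole pipeline is testable without any downloads.

## Worked example

`examples/select_panel.py` generates a synthetic panel (five targets,
ten non-targets, 20 kb genomes, five planted target-private variants)
and runs the full selection:

```
target genomes:        5
non-target genomes:    10
target_union_min_presence          16800 k-mers
after_nontarget_assemblies           160 k-mers
after_nontarget_reads                160 k-mers
truth panel (brute force):           160 k-mers
pipeline == truth: True
```

16,800 32-mers pass the universality filter; subtracting the non-target
assemblies leaves the 160 windows that cover the five planted variants
(32 windows each), exactly matching the brute-force truth panel.
`examples/detect_in_reads.py` then detects that panel in simulated
reads (0.5% error rate, 30,000 reads):

```
panel size: 160 specific 32-mers
cutoff   target reads   non-target reads
     1            160                 42
     2            160                  0
     5            160                  0
    10            160                  0
```

Target reads hit the whole panel at every cutoff; the 42 non-target
detections at cutoff 1 are sequencing-error artefacts and disappear at
cutoff 2. `examples/locate_clusters.py` maps the panel back onto a
target genome: 5 clusters of 32 k-mers, 63 bp each, all in single-copy
regions.

The same operations are available as a CLI:

```sh
taxmer list -k 32 -o genome.klist genome.fa
taxmer select-specific --k 32 --min-targets 2 --reads-min-freq 10 \
    --targets t1.fa --targets t2.fa \
    --nontarget-assemblies nt.fa -o panel.klist
taxmer detect --panel panel.klist --cutoffs 1,2,5,10 -o report.tsv reads.fq.gz
taxmer subsample -n 100000 -o sub.fq.gz reads.fq.gz
taxmer locate --panel panel.klist --reference ref.fa -o clusters.bed
taxmer simulate panel --seed 7 --out panel_dir/
```

Every command writes a JSON run manifest (inputs, digests, parameters)
next to its primary output.

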