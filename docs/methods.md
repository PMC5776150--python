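# Methods

## Canonical k-mer model

A k-mer is a length-k substring over {A, C, G, T}; its canonical form is
the lexicographically smaller of the k-mer and its reverse complement,
so one stored entry represents both strands. k-mers are packed two bits
per base (A=0, C=1, G=2, T=3, 5'-most base most significant), which
makes integer order identical to lexicographic order and caps k at 32
so any code fits one 64-bit word. Odd and even k are both allowed; an
even-k palindrome is its own canonical form and is counted once per
occurrence. Windows containing any non-ACGT symbol (N, IUPAC ambiguity
codes) are skipped entirely; lowercase input is upper-cased. Sequences
are treated as linear exactly as given — no wraparound windows across a
circular origin — which can shift counts by a small constant on truly
circular genomes.

All lists are exact sorted (code, count) tables; there are no
probabilistic or streaming counters. The on-disk KLIST v1 format is
plain text (header line, then `kmer<TAB>count` sorted ascending) and is
byte-deterministic, so identical inputs always produce identical files.

## Selection pipeline

Let T₁…Tₜ be target genome k-mer lists (one file = one genome = the
unit of presence) and N₁…Nₛ non-target lists. The panel is

    panel = { x : |{i : x ∈ Tᵢ}| ≥ m } \ ∪ⱼ Nⱼ \ ∪ᵣ { x : countᵣ(x) ≥ f }

where r ranges over non-target read sets. Presence in the universality
cutoff m is binary per genome (count ≥ 1), not multiplicity-weighted,
because m counts genomes. The union carries summed counts across lists
as provenance; downstream removal is presence-based, and intersection
(used in tests and the CLI) returns the minimum of the two counts as
the most conservative shared multiplicity. The removal order —
universality filter, then non-target assemblies, then frequency-
filtered non-target reads — matches the two-step structure the pipeline
logs; the result itself is order-independent. Non-target read sets are
filtered at frequency ≥ f per file rather than pooled, so one deep
sample cannot lift another sample's noise over the cutoff.

Parameters and defaults: k = 32 (the most productive length for
close-species discrimination; the `k_sweep` helper measures panel size
over k ∈ {8, 12, 16, 20, 24, 28, 32}), m = 2 (a marker must be shared
by at least two target individuals, excluding private polymorphism),
f = 10 reads (below this a non-target read-set occurrence is treated as
sequencing error, above it as genuine presence in the non-target
nuclear/organellar background).

## Detection in raw reads

Detection streams FASTQ (plain or gzip) once, counting every canonical
window occurrence of a panel k-mer — a k-mer appearing twice in one
read counts twice, matching per-occurrence k-mer-counter semantics.
No quality trimming or filtering is applied; paired files are
independent read streams. The report gives per-k-mer counts and, for a
strictly ascending cutoff ladder (default 1, 2, 5, 10), the number of
panel k-mers at or above each cutoff; detected(f) is non-increasing
in f by construction.

FASTQ subsampling to n_out reads keeps indices 0, s, 2s, … with stride
s = ⌊n_total / n_out⌋, truncated to exactly n_out records copied
byte-for-byte (even spacing along the file). Subsamples at different
n_out are therefore not nested; a `prefix` mode (first n_out reads) is
provided where nesting matters.

## Localization and clustering

Every reference window whose canonical code is in the panel yields a
hit at the window's forward coordinate with the strand of the matching
orientation. Hits whose k-length intervals overlap or touch
(next start ≤ previous start + k) merge into one cluster; a run of n
hits at consecutive starts spans n + k − 1 bp, and the gap between
adjacent clusters is start(next) − end(previous). The merge rule is
interval adjacency rather than any sequence-similarity criterion: it is
the operational rule that reproduces the span arithmetic of runs of
overlapping k-mers. All output coordinates are 0-based half-open (BED);
logs print 1-based inclusive only for human readers. A k-mer hitting
multiple reference positions contributes one hit per position.

## Synthetic panel generator

`generate_panel` builds an ancestral genome as LSC + IR_A + SSC + IR_B
with IR_B the exact reverse complement of IR_A. Defaults are a 20 kb
genome (11 kb LSC, 3.2 kb IRs, 2.6 kb SSC — real plastome proportions
scaled down for seconds-long runs), 5 targets and 10 non-targets. The
IRs are never mutated, so both copies stay identical within and across
every genome — the strong conservation that empties real IRs of
specific k-mers, taken to its limit. Target genomes share
`n_private_variants` planted substitutions (default 5), placed in
single-copy regions at least k−1 bp from region boundaries and 2k bp
apart so variants do not share windows; targets additionally diverge at
5×10⁻⁴ substitutions/bp (intra-species polymorphism) and each
non-target at 10⁻² (congeneric-species distance, about one substitution
per 100 bp). The mutation model is substitution-only, which keeps the
exhaustive window oracle exact; indels are an extension point.

Reads are uniform-start, single-end, either strand, with substitution
errors at 10⁻³ per base by default and a constant quality string —
deliberately not a platform error model. Linear-genome edge windows are
covered only by reads starting exactly at the ends, so read-set
saturation of all genome k-mers needs deep coverage (≈ L·ln L reads).

The ground-truth panel is computed by brute force on plain Python
strings (every window of every genome, canonicalised as
min(s, revcomp(s))), independent of the vectorised numpy path it
validates; the test suite carries a second, separate string oracle for
counting, set algebra, detection and localization.

What passing synthetic tests shows — and does not. They demonstrate
exact recovery of the planted signal, the IR-exclusion structure, and
the direction of the specificity/sensitivity trade-off under the
cutoff. They do not exercise indels, rearrangements, repeat families in
single-copy regions, platform-specific error profiles, or database-
scale non-target breadth (thousands of genomes), so panel sizes on real
data will differ from the toy scale.

## Numerical and design notes

- Counting, set algebra and detection are numpy-vectorised
  (sliding-window encoding, `np.unique` aggregation, `searchsorted`
  membership); results are exact integers throughout, no tolerances.
- Problem sizes in the tests (genomes ≤ 20 kb, ≤ 16 genomes, ≤ 5×10⁴
  reads, 100+ randomized oracle trials) keep the default suite around
  a minute while covering k ∈ {4, 8, 16, 31, 32}.
- Degenerate inputs: empty FASTA yields an empty list; reads shorter
  than k contribute nothing; an all-empty target set, m exceeding the
  number of target files, or a cutoff < 1 are errors, not silent
  defaults.
- Every CLI run writes a JSON manifest (resolved parameters, input
  SHA-256 digests, version, timestamp) next to its primary output;
  primary outputs are pure functions of inputs plus declared seeds.

## Known limitations

- Exact-match semantics only: a single substitution or sequencing error
  in a read window defeats that window's match (no 1-mismatch
  neighbourhood).
- Panel counts quantify nothing biologically: organelle copy number
  varies per cell, so detection is presence/frequency, not abundance.
- Circular genomes are handled linearly; wraparound k-mers are not
  counted.
- No fetching from sequence databases; assembling the input genome and
  read files is the user's responsibility.
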