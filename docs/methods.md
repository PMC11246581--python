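# Methods

## Model

`varmin` treats read alignment as seed–chain–align against a minimizer
hash index of a linear reference, and asks how far known population
variation can be folded into the *index* without touching the aligner.
The index stores, for each canonical minimizer hash, the list of its
reference occurrences; augmentation inserts additional occurrences
whose k-mers contain known alternate alleles, at the reference
coordinates where a variant-carrying read should be placed. Added
entries are indistinguishable from reference minimizers at query time;
provenance lives only in index metadata and the modification report.

### Minimizers

A k-mer is encoded in 2 bits per base (A=0, C=1, G=2, T=3, leftmost
base most significant), which caps k at 31 for a 64-bit word; k = 32
is rejected at parameter validation, as is k < 3. The canonical hash
of a k-mer is the smaller of the hashes of the k-mer and of its
reverse complement, with the originating strand. Two schemes exist:

* `invertible64` (default): the MurmurHash3 64-bit finalizer applied
  to the encoding. Being a bijection, equal hashes imply equal k-mers,
  so hash collisions cannot create false seed matches.
* `lexicographic`: the raw encoding, so hash order equals sequence
  order; used in worked examples and tests where readability matters.

Winnowing emits, for every window of `w` consecutive valid k-mers,
every k-mer achieving the window minimum (dense at ties), deduplicated
by position. Maximal runs of valid k-mers are winnowed independently
with window size `min(w, run length)`; a sequence shorter than
`k+w−1` but at least `k` long therefore still yields the minimizers of
its single shorter window. K-mers containing a non-ACGT base are
invalid and restart the run. Palindromic (strand-symmetric) k-mers,
which have no canonical strand, are treated the same way; they exist
only for even k and never for the default k = 21. All positions are
0-based; a k-mer occupies `[pos, pos+k)`.

### The variant window and its length

For each accepted variant a reference window of fixed length
`2·(k+w)−1` is centred on the variant (focal REF start at offset
`k+w−1`, clipped at contig ends). The length is exactly sufficient in
the following sense, which the test suite checks as its central
property: a k-mer overlapping a variant at position p starts within
`[p−k+1, p]`; any winnowing window of `w` consecutive k-mers containing
such a k-mer spans at most bases `[p−(k+w−2), p+k+w−2]`, which lies
strictly inside the centred window. Minimizers recomputed on the
window that overlap the variant therefore coincide with minimizers of
the whole mutated chromosome — for isolated SNVs the added set equals
the variant-overlapping set difference between the mutated and
reference full-sequence minimizer sets, exactly.

### Haplotypes and coordinate mapping

Variants are read from VCF 4.x (plain or bgzipped) via pysam;
multiallelic records are split per ALT, alleles are trimmed to a
minimal representation with a shared anchor base, and each allele is
validated against the reference. Filters: allele frequency strictly
greater than `af_min` (default 0.05; INFO/AF first, then AF derived
from GT counts, else frequency-unknown and kept only when `af_min` is
None), and net indel length strictly less than k — longer indels shift
minimizer positions too far to be represented in a linear index.
htslib returns AF as float32; values are rounded back to six decimals
so strict thresholds behave as printed in the file.

Within a window, fully phased genotypes restrict enumeration to the
allele patterns observed on sample haplotypes that carry the focal ALT
(bounded by twice the sample count); any unphased or missing genotype
falls back to combinatorial mode: the focal ALT fixed, every subset of
the neighbouring variants applied (`2^n` haplotypes). Windows with
more than ten combinable neighbours are skipped, as are windows where
an indel's REF span overlaps an SNV, and windows clipped below k bases.
Combinations with internally overlapping REF intervals are dropped.
The focal variant is always in ALT state — focal-REF combinations
produce only minimizers the plain index already has.

Each haplotype carries a per-position coordinate map back to the
reference: SNVs preserve positions; deleted bases are skipped, so
positions right of a deletion shift by the deleted length; inserted
bases map to the reference position of the base immediately to their
left (left anchoring). Left anchoring keeps anchor diagonals
consistent for chaining, which is what lets indel-carrying reads chain
and align at the correct locus. An added minimizer is kept only if its
k-mer actually contains an edit: the substituted base for SNVs, at
least one inserted base for insertions, or both junction bases for
deletions (k-mers touching only a deletion's anchor base are plain
reference sequence). Insertion is idempotent on
`(hash, contig, pos, strand)`, so overlapping windows and repeated
runs add nothing twice, and the plain table is always a subset of the
modified table.

### Occurrence filter and its adjustment

Seeds whose hash occurs more than `filter_n` times (strictly) are
ignored at query time; the table keeps all entries, so one index file
serves any threshold. Augmentation grows the table, which changes the
ignored fraction; the adjusted threshold for a modified index is the
candidate `t ≥ plain filter_n` whose ignored-occurrence fraction is
closest to the plain index's, ties preferring the threshold nearest
the plain one. Candidates below the plain threshold are excluded:
augmentation only adds occurrences, so a lower threshold would
suppress seeds the plain index kept. When the plain index ignores
nothing, the plain threshold is returned unchanged (an exact-fraction
match is impossible anyway with discrete counts, and equality of
behaviour on shared hashes is the property that matters).

### Aligner

The demonstration mapper is intentionally plain:

* **Seeding**: the read's minimizers are computed with the index's own
  parameters and looked up post-filter; reverse-strand matches are
  expressed in the coordinates of the reverse-complemented read so
  each relative strand chains in one coordinate system.
* **Chaining**: per (contig, strand),
  `score(j) = max(k, score(i) + min(k, dq, dr) − gap_weight·|dq−dr|)`
  over predecessors with positive gaps bounded by `max_gap` (1000);
  `gap_weight` = 0.5 per bp of diagonal difference. Ties prefer the
  nearest predecessor so collinear anchors stay in one chain. Chains
  are extracted best-first without anchor reuse; chains whose
  reference span overlaps an already-extracted chain by more than half
  are alternate paths through the same locus and are dropped, so the
  surviving list enumerates genuinely distinct placements. The minimum
  chain score is k (a single anchor suffices).
* **Extension**: affine-gap global alignment (match 2, mismatch −4, a
  gap of length L costing 6 + 2L) of the read against a padded
  reference window, with reference end gaps free (they only shift the
  position) and read end gaps free and reported as soft clips. The
  common single-diagonal case short-circuits to direct comparison when
  it yields at most 5 mismatches. The dynamic program itself is
  Biopython's `PairwiseAligner`; CIGAR, NM and AS are derived in
  package code by walking the aligned blocks, and the suite checks
  them against an independent pure-Python Needleman–Wunsch oracle.
* **MAPQ**: `round(60·(1 − second/best))` over chain scores, 60 when
  no second chain survives, clamped to [0, 60].
* **Multi-mapping**: a read with at least two surviving chains within
  95% of the best score is tagged `ZM:i:1`; the evaluator counts these
  as multi-mapped. (The criterion is a package definition; upstream
  tools do not publish theirs.)
* Paired input is accepted with mates aligned independently; there is
  no insert-size rescue. Output order follows input order.

### Synthetic data and what a green test establishes

The generator emulates, at desk scale, the ingredients of a
variant-aware alignment benchmark: a uniform random reference with
planted repeat families (identical copies of random units), a donor
carrying non-overlapping SNVs and 1–5 bp indels, a VCF with AF and a
single-sample genotype (phased separator for a configurable fraction
of records), and substitution-error reads sampled uniformly from both
donor haplotypes on both strands with a truth table of reference
placements. Everything is bit-deterministic given seeds.

The standard fixture is 100 kb, six repeat families (three of 8
identical 400 bp copies, three of 3), 500 SNVs + 50 indels at AF 0.5
with a homozygous-ALT donor, 30× of 150 bp reads at 0.1% error, and
k=21, w=11 with `filter_n` = 4. The filter between the two copy
numbers puts the fixture in both regimes in which known variants
rescue placement: inside high-copy repeats every plain seed is
filtered (reads unmapped without the variant seed), and inside
low-copy repeats plain seeds survive but are ambiguous among copies
(reads multi-mapped until the variant seed breaks the tie). The donor
is homozygous ALT so every locus-spanning read carries the variant;
heterozygous mode exists for haplotype-logic experiments.

What the fixture does *not* model: sequencing indel errors and
quality-dependent errors (substitution-only, by design, so placement
failures are attributable to donor variants), divergent repeat copies,
structural variants, GC bias, and paired-end constraints. A green
end-to-end test therefore establishes the direction and mechanism of
the effect — variant-aware seeds strictly improve placement of
variant-overlapping reads and reduce multi-mapping while leaving
variant-free reads bit-identical — not any genome-scale effect size.

### Numerical and representational choices

* Placement tolerance 20 bp in evaluation: absorbs soft-clip and
  near-junction ambiguity at read ends; configurable.
* Index files are canonical JSON (sorted keys, fixed separators) with
  magic string, format version, parameters and a SHA-256 digest of the
  source FASTA; serialisation is deterministic (re-saving a loaded
  index is byte-identical) and the digest is checked before any use of
  an index against a reference.
* Alignment tie-breaking is delegated to the deterministic traceback
  of the pairwise aligner; test fixtures that assert exact CIGARs are
  constructed so the optimum is unique (e.g. a deleted dinucleotide
  differing from both flanking bases).
* Degenerate inputs: contigs shorter than k index nothing; reads
  shorter than k, or without surviving chains, yield unmapped records;
  empty variant lists make modification the identity.

### Known limitations

* Indels with net length ≥ k are filtered out; representing them would
  require a different index structure.
* One seeding round and a single occurrence-filter integer; the
  second-round re-seeding of production mappers is out of scope.
* The mapper is a demonstration vehicle: no BAM/CRAM, no base-quality
  awareness, no spliced or long-read modes, no paired-end rescue, and
  no claim of production chaining heuristics. Whether a production
  aligner would report all-match CIGARs for indel reads against a
  modified index depends on its extension heuristics; this package's
  Needleman–Wunsch extension reports the indel in the CIGAR and makes
  no all-match promise.
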