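"""Build a minimizer index of a reference and inspect it.

A minimizer is the k-mer with the smallest canonical hash among w
consecutive k-mers; indexing only minimizers keeps the seed table small
while any long-enough exact match still shares a seed with the index.
"""

from varmin import Contig, IndexParams, build_index, compute_minimizers, decode_kmer

# Worked 4-mer example with lexicographic hashing (hash order = sequence
# order): the three k-mers of TAGCAT are TAGC, AGCA, GCAT; canonically
# GCTA/AGCA/ATGC, of which AGCA is smallest -> the window's minimizer.
toy = Contig("toy", "TAGCAT")
params = IndexParams(k=4, w=3, hash_scheme="lexicographic")
for m in compute_minimizers(toy, params):
    print(f"minimizer {decode_kmer(m.hash, 4)} at position {m.pos}, strand {m.strand:+d}")

# A realistic index: random 50 kb reference, short-read defaults k=21, w=11.
from varmin.simulate import simulate_reference

reference = simulate_reference(length=50_000, seed=42)
index = build_index(reference, IndexParams(k=21, w=11))
stats = index.stats()
print(f"\nindexed {stats.total_occurrences} minimizer occurrences "
      f"({stats.distinct_hashes} distinct hashes) on {reference[0].name}")
print(f"density ~ {stats.total_occurrences / reference[0].length:.3f} per base "
      f"(theory for w=11: 2/(w+1) ~ 0.167)")
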