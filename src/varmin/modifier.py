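"""Index augmentation with variant-containing minimizers.

For every acceptable variant window and every enumerated haplotype,
minimizers are recomputed on the alternate window sequence, those whose
k-mer actually contains the variant are mapped back to reference
coordinates (deletions shift downstream positions by the deleted
length; insertions anchor to the base on their left), and the result is
inserted into the hash table.  Added entries are indistinguishable from
reference minimizers at query time, so alignment proceeds unmodified;
provenance is preserved in the index metadata and the modification
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .index import MinimizerIndex
from .minimizers import Contig, IndexParams, Minimizer, compute_minimizers
from .variants import (
    SKIP_EDGE,
    WINDOW_OK,
    Haplotype,
    VariantWindow,
    apply_haplotype,
    enumerate_haplotypes,
)

__all__ = ["ModifyReport", "variant_minimizers", "modify_index", "apply_haplotype"]


@dataclass
class ModifyReport:
    """Accounting of one modification run."""

    windows_total: int = 0
    windows_processed: int = 0
    windows_skipped: Dict[str, int] = field(default_factory=dict)
    haplotypes: int = 0
    minimizers_added: int = 0
    minimizers_duplicate: int = 0

    def skip(self, reason: str) -> None:
        self.windows_skipped[reason] = self.windows_skipped.get(reason, 0) + 1


def _overlaps_variant(kmer_start: int, k: int, span: Tuple[int, int, str]) -> bool:
    """Does the k-mer at ``[kmer_start, kmer_start+k)`` contain the edit?

    SNVs: the substituted base must lie in the k-mer.  Insertions: at
    least one inserted base (positions after the anchor) must lie in the
    k-mer.  Deletions: the k-mer must span the deletion junction, i.e.
    cover the anchor base and the base following it; k-mers touching
    only the anchor are plain reference sequence.
    """
    a, b, vclass = span
    kmer_end = kmer_start + k
    if vclass == "SNV":
        return kmer_start <= a < kmer_end
    if vclass == "INS":
        return kmer_start < b and kmer_end > a + 1
    # DEL: alt span is the anchor alone; require anchor and next base
    return kmer_start <= a and kmer_end >= a + 2


def variant_minimizers(
    hap: Haplotype, params: IndexParams, contig_id: int
) -> List[Minimizer]:
    """Minimizers of a haplotype window that contain an applied variant,
    reported at reference coordinates via the haplotype's coordinate map."""
    if len(hap.alt_seq) < params.k:
        return []
    out = []
    for m in compute_minimizers(Contig("hap", hap.alt_seq), params):
        if any(_overlaps_variant(m.pos, params.k, s) for s in hap.applied_spans):
            out.append(
                Minimizer(m.hash, contig_id, hap.coord_map[m.pos], m.strand)
            )
    return out


def modify_index(
    index: MinimizerIndex,
    windows: Sequence[VariantWindow],
    reference: Sequence[Contig],
    max_unphased: int = 10,
) -> Tuple[MinimizerIndex, ModifyReport]:
    """Insert variant minimizers for every acceptable window.

    Insertion is idempotent on ``(hash, contig, pos, strand)``: running
    the same modification twice adds nothing the second time, and the
    plain table is always a subset of the modified one.  The input index
    is left untouched; a modified copy is returned with its report.
    """
    index.check_reference(list(reference))
    by_name = {c.name: c for c in reference}
    name_to_id = {n: i for i, n in enumerate(index.contig_names)}

    table = {h: list(occs) for h, occs in index.table.items()}
    report = ModifyReport(windows_total=len(windows))
    added = 0
    for win in windows:
        if win.status != WINDOW_OK:
            report.skip(win.status)
            continue
        if win.win_end - win.win_start < index.params.k:
            report.skip(SKIP_EDGE)
            continue
        cid = name_to_id[win.focal.contig]
        contig_seq = by_name[win.focal.contig].sequence
        haps = enumerate_haplotypes(win, contig_seq, max_unphased=max_unphased)
        report.haplotypes += len(haps)
        report.windows_processed += 1
        for hap in haps:
            for m in variant_minimizers(hap, index.params, cid):
                occ = (m.contig_id, m.pos, m.strand)
                occs = table.setdefault(m.hash, [])
                if occ in occs:
                    report.minimizers_duplicate += 1
                else:
                    occs.append(occ)
                    added += 1
    for occs in table.values():
        occs.sort()
    report.minimizers_added = added
    modified = MinimizerIndex(
        params=index.params,
        reference_digest=index.reference_digest,
        contig_names=index.contig_names,
        contig_lengths=index.contig_lengths,
        table=table,
        provenance="modified",
        n_added=index.n_added + added,
    )
    return modified, report
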