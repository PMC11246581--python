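"""VCF ingestion, variant windows, and haplotype enumeration.

For every accepted variant a reference window of fixed length
``2*(k+w) - 1`` is centred on the variant (the focal variant's REF start
sits at offset ``k+w-1``, clipped at contig ends).  That length is
exactly sufficient: every winnowing window of ``w`` consecutive k-mers
that can select a variant-overlapping k-mer lies entirely inside it, so
minimizers recomputed on the window agree with minimizers of the whole
mutated chromosome.

Windows are skipped when they would explode or become ambiguous:

* more than ten neighbouring variants requiring combinatorial
  expansion around an unphased focal variant;
* an indel whose REF span overlaps another SNV;
* windows clipped so hard at a contig edge that no k-mer fits.

Haplotype enumeration is phase-aware: with fully phased genotypes only
allele patterns observed together on a sample haplotype are generated;
otherwise every subset of neighbouring variants is combined with the
focal ALT (``2^n`` combinations), since any of them may co-occur.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pysam

from .minimizers import Contig, IndexParams

__all__ = [
    "Variant",
    "VariantWindow",
    "Haplotype",
    "RejectedRecord",
    "load_variants",
    "build_windows",
    "apply_haplotype",
    "enumerate_haplotypes",
    "WINDOW_OK",
    "SKIP_TOO_MANY",
    "SKIP_INDEL_OVER_SNV",
    "SKIP_INDEL_TOO_LONG",
    "SKIP_EDGE",
]

WINDOW_OK = "ok"
SKIP_TOO_MANY = "skipped_too_many_variants"
SKIP_INDEL_OVER_SNV = "skipped_indel_overlaps_snv"
SKIP_INDEL_TOO_LONG = "skipped_indel_too_long"
SKIP_EDGE = "skipped_edge_degenerate"

MAX_UNPHASED = 10  # combinatorial windows with more variants are skipped

# per-sample genotype: (allele indices, phased flag)
Genotype = Tuple[Tuple[Optional[int], ...], bool]


@dataclass(frozen=True)
class Variant:
    """One alternate allele of one VCF record, normalised.

    Alleles are trimmed to a minimal representation (common suffix then
    common prefix removed, indels keeping one shared anchor base), and
    ``alt_index`` remembers which ALT of the source record this is so
    genotypes can be interpreted after multiallelic splitting.
    """

    contig: str
    pos0: int
    ref_allele: str
    alt_allele: str
    vclass: str  # "SNV", "INS" or "DEL"
    af: Optional[float] = None
    alt_index: int = 1
    genotypes: Optional[Tuple[Genotype, ...]] = None

    @property
    def end0(self) -> int:
        """End (exclusive) of the REF interval."""
        return self.pos0 + len(self.ref_allele)

    @property
    def net(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    @property
    def is_indel(self) -> bool:
        return self.vclass in ("INS", "DEL")

    def key(self) -> Tuple[str, int, str, str]:
        return (self.contig, self.pos0, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class RejectedRecord:
    contig: str
    pos0: int
    ref_allele: str
    alt_allele: str
    reason: str


@dataclass
class VariantWindow:
    """Fixed-length reference window centred on a focal variant."""

    focal: Variant
    win_start: int
    win_end: int
    neighbors: Tuple[Variant, ...]
    status: str = WINDOW_OK

    @property
    def variants(self) -> Tuple[Variant, ...]:
        return tuple(sorted((self.focal, *self.neighbors), key=lambda v: v.pos0))


@dataclass(frozen=True)
class Haplotype:
    """A window sequence with a subset of variants applied.

    ``coord_map[i]`` is the 0-based reference position of alt position
    ``i``; bases inserted relative to the reference map to the position
    of the base immediately to their left (left anchoring), so the map
    is non-decreasing.  ``applied_spans`` records, per applied variant,
    its half-open interval in alt coordinates and its class.
    """

    alt_seq: str
    coord_map: Tuple[int, ...]
    applied: Tuple[Variant, ...]
    applied_spans: Tuple[Tuple[int, int, str], ...]  # (alt_start, alt_end, vclass)


def _normalise(pos0: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Trim shared suffix then prefix, keeping at least one base each."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    return pos0, ref, alt


def _classify(ref: str, alt: str) -> Optional[str]:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) > len(alt) and len(alt) == 1 and ref[0] == alt[0]:
        return "DEL"
    if len(alt) > len(ref) and len(ref) == 1 and ref[0] == alt[0]:
        return "INS"
    return None  # MNV / complex: rejected


def _genotypes_of(rec: "pysam.VariantRecord") -> Optional[Tuple[Genotype, ...]]:
    if not rec.samples:
        return None
    out = []
    for s in rec.samples.values():
        gt = s.get("GT")
        if gt is None or all(a is None for a in gt):
            return None
        out.append((tuple(gt), bool(s.phased)))
    return tuple(out)


def _af_of(rec: "pysam.VariantRecord", alt_index: int, gts) -> Optional[float]:
    af = rec.info.get("AF")
    if af is not None:
        if not isinstance(af, (tuple, list)):
            af = (af,)
        if len(af) >= alt_index and af[alt_index - 1] is not None:
            # htslib parses the decimal text as float32; round back to the
            # printed precision so strict thresholds behave as written
            return round(float(af[alt_index - 1]), 6)
    if gts:
        alleles = [a for gt, _ in gts for a in gt if a is not None]
        if alleles:
            return sum(1 for a in alleles if a == alt_index) / len(alleles)
    return None


def load_variants(
    vcf_path: Union[str, Path],
    reference: Sequence[Contig],
    af_min: Optional[float] = 0.05,
    k: int = 21,
) -> Tuple[List[Variant], List[RejectedRecord]]:
    """Read SNVs and short indels from a VCF, filtering and validating.

    A variant is kept iff its allele frequency is strictly greater than
    ``af_min`` (records without a derivable AF are kept only when
    ``af_min`` is None), its REF matches the reference sequence, and its
    net indel length is shorter than the k-mer length ``k``.  Every
    input allele is accounted for: accepted, or returned in the
    rejection log with a reason.
    """
    by_name = {c.name: c for c in reference}
    accepted: List[Variant] = []
    rejected: List[RejectedRecord] = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            if rec.chrom not in by_name:
                raise ValueError(
                    f"VCF contig {rec.chrom!r} not present in the reference"
                )
            seq = by_name[rec.chrom].sequence
            gts = _genotypes_of(rec)
            for ai, alt in enumerate(rec.alts or (), start=1):

                def reject(reason: str) -> None:
                    rejected.append(
                        RejectedRecord(rec.chrom, rec.start, rec.ref, alt, reason)
                    )

                if alt is None or "<" in alt or ">" in alt or "*" in alt:
                    reject("symbolic_allele")
                    continue
                if seq[rec.start : rec.start + len(rec.ref)] != rec.ref.upper():
                    reject("ref_mismatch")
                    continue
                pos0, ref_a, alt_a = _normalise(rec.start, rec.ref.upper(), alt.upper())
                vclass = _classify(ref_a, alt_a)
                if vclass is None:
                    reject("complex_allele")
                    continue
                if vclass != "SNV" and abs(len(ref_a) - len(alt_a)) >= k:
                    reject("indel_too_long")
                    continue
                af = _af_of(rec, ai, gts)
                if af_min is not None:
                    if af is None:
                        reject("no_af")
                        continue
                    if not af > af_min:  # strictly greater-than threshold
                        reject("low_af")
                        continue
                accepted.append(
                    Variant(
                        contig=rec.chrom,
                        pos0=pos0,
                        ref_allele=ref_a,
                        alt_allele=alt_a,
                        vclass=vclass,
                        af=af,
                        alt_index=ai,
                        genotypes=gts,
                    )
                )
    return accepted, rejected


def _fully_phased(variants: Sequence[Variant]) -> bool:
    for v in variants:
        if v.genotypes is None:
            return False
        for gt, phased in v.genotypes:
            if not phased or any(a is None for a in gt):
                return False
    return True


def build_windows(
    variants: Sequence[Variant],
    params: IndexParams,
    contig_lengths: Dict[str, int],
) -> List[VariantWindow]:
    """One fixed-length window per accepted focal variant, with status."""
    half = params.k + params.w - 1
    by_contig: Dict[str, List[Variant]] = {}
    for v in variants:
        by_contig.setdefault(v.contig, []).append(v)
    for vs in by_contig.values():
        vs.sort(key=lambda v: v.pos0)

    windows: List[VariantWindow] = []
    for focal in variants:
        clen = contig_lengths[focal.contig]
        ws = max(0, focal.pos0 - half)
        we = min(clen, focal.pos0 + half + 1)
        neighbors = tuple(
            v
            for v in by_contig[focal.contig]
            if v is not focal and v.pos0 < we and v.end0 > ws
        )
        win = VariantWindow(focal, ws, we, neighbors)
        allv = win.variants
        if we - ws < params.k:
            win.status = SKIP_EDGE
        elif any(
            a.is_indel and not b.is_indel and a.pos0 < b.end0 and b.pos0 < a.end0
            for a in allv
            for b in allv
            if a is not b
        ):
            win.status = SKIP_INDEL_OVER_SNV
        elif len(neighbors) > MAX_UNPHASED and not _fully_phased(allv):
            # the cap counts the nearby variants that would be expanded
            # combinatorially around the focal one
            win.status = SKIP_TOO_MANY
        windows.append(win)
    return windows


def apply_haplotype(
    ref_window: str,
    win_start: int,
    applied: Sequence[Variant],
) -> Haplotype:
    """Apply non-overlapping edits to a reference window, left to right.

    Returns the alternate sequence together with the per-position map
    back to reference coordinates.  SNVs keep positions unchanged;
    deleted bases are skipped (so downstream positions shift by the
    deleted length); inserted bases are anchored to the reference
    position of the base immediately left of them.
    """
    win_end = win_start + len(ref_window)
    applied = tuple(sorted(applied, key=lambda v: v.pos0))
    prev_end = None
    for v in applied:
        if v.pos0 < win_start or v.end0 > win_end:
            raise ValueError(f"variant at {v.pos0} lies outside the window")
        if prev_end is not None and v.pos0 < prev_end:
            raise ValueError("overlapping REF intervals in applied variants")
        prev_end = v.end0
    parts: List[str] = []
    coord: List[int] = []
    spans: List[Tuple[int, int, str]] = []
    cur = win_start
    for v in applied:
        parts.append(ref_window[cur - win_start : v.pos0 - win_start])
        coord.extend(range(cur, v.pos0))
        alt_start = len(coord)
        parts.append(v.alt_allele)
        coord.append(v.pos0)
        coord.extend([v.pos0] * (len(v.alt_allele) - 1))
        spans.append((alt_start, len(coord), v.vclass))
        cur = v.end0
    parts.append(ref_window[cur - win_start :])
    coord.extend(range(cur, win_end))
    return Haplotype("".join(parts), tuple(coord), applied, tuple(spans))


def _pattern_haplotypes(
    window: VariantWindow, ref_window: str, patterns: Sequence[Tuple[Variant, ...]]
) -> List[Haplotype]:
    out: List[Haplotype] = []
    seen_seq = set()
    for pat in patterns:
        try:
            hap = apply_haplotype(ref_window, window.win_start, pat)
        except ValueError:
            continue  # internally inconsistent combination: dropped
        if hap.alt_seq not in seen_seq:
            seen_seq.add(hap.alt_seq)
            out.append(hap)
    return out


def enumerate_haplotypes(
    window: VariantWindow,
    contig_seq: str,
    max_unphased: int = MAX_UNPHASED,
) -> List[Haplotype]:
    """All haplotypes of a window that carry the focal ALT allele.

    Combinations where the focal variant is in REF state are omitted:
    their minimizers are exactly the plain index's.  Output order is
    deterministic (sorted by the applied variant positions).
    """
    if window.status != WINDOW_OK:
        raise ValueError(f"cannot enumerate a window with status {window.status!r}")
    ref_window = contig_seq[window.win_start : window.win_end]
    allv = window.variants
    focal = window.focal

    if _fully_phased(allv) and focal.genotypes is not None:
        n_samples = len(focal.genotypes)
        ploidy = len(focal.genotypes[0][0])
        patterns = []
        seen = set()
        for s in range(n_samples):
            for h in range(ploidy):
                carried = tuple(
                    v for v in allv if v.genotypes[s][0][h] == v.alt_index
                )
                if focal not in carried:
                    continue
                key = tuple(v.key() for v in carried)
                if key not in seen:
                    seen.add(key)
                    patterns.append(carried)
    else:
        neighbors = sorted(window.neighbors, key=lambda v: v.pos0)
        if len(neighbors) > max_unphased:
            raise ValueError(
                f"{len(neighbors)} unphased neighbours exceed max_unphased="
                f"{max_unphased}"
            )
        patterns = []
        for mask in range(1 << len(neighbors)):
            subset = [neighbors[i] for i in range(len(neighbors)) if mask >> i & 1]
            patterns.append(tuple(sorted((focal, *subset), key=lambda v: v.pos0)))

    patterns.sort(key=lambda pat: tuple(v.key() for v in pat))
    return _pattern_haplotypes(window, ref_window, patterns)
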