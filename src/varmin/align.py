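"""Seed-chain-align short-read mapper over a minimizer index.

This is a deliberately simple demonstration mapper: it consumes plain
and variant-modified indexes identically, which is the point — the
index augmentation needs no change to the alignment algorithm.

Pipeline per read: compute the read's minimizers with the index's
parameters; look each up in the hash table (honouring the occurrence
filter) to form *anchors*; chain collinear anchors per (contig, strand)
with a gap-penalised dynamic program; align the best chain's region
against the reference with affine-gap Needleman-Wunsch (free end gaps on
the reference side, soft clips on the read side) and emit a
SAM-conformant record with CIGAR, MAPQ, NM and AS.

Mapping quality is ``60 * (1 - second/best)`` over chain scores, capped
at 60 for unique chains; reads with two or more chains within 95% of the
best score carry the custom ``ZM:i:1`` tag and are counted multi-mapped
by the evaluator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple, Union

import pysam
from Bio import Align

from .index import MinimizerIndex
from .minimizers import Contig, Minimizer, compute_minimizers, reverse_complement

__all__ = [
    "Anchor",
    "Chain",
    "AlignerConfig",
    "AlignmentRecord",
    "seed",
    "chain",
    "extend_align",
    "mapq",
    "align_read",
    "align_fastq",
    "write_sam",
]

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100


class Anchor(NamedTuple):
    """Exact seed match between read and reference.

    ``read_pos`` is the k-mer start on the read for forward matches and
    on the reverse-complemented read for reverse matches, so that within
    one relative strand anchors are chained in a single coordinate
    system.
    """

    read_pos: int
    contig_id: int
    ref_pos: int
    strand: int  # relative orientation: +1 forward, -1 reverse
    hash: int


@dataclass
class Chain:
    anchors: List[Anchor]
    score: float
    contig_id: int
    strand: int


@dataclass(frozen=True)
class AlignerConfig:
    """Scoring and heuristics; defaults follow common short-read presets.

    A gap of length L costs ``-(gap_open + L * gap_extend)`` in the
    base-level alignment; ``gap_weight`` is the per-base chaining cost of
    diagonal differences between consecutive anchors.
    """

    match: int = 2
    mismatch: int = -4
    gap_open: int = 6
    gap_extend: int = 2
    max_gap: int = 1000
    gap_weight: float = 0.5
    min_chain_score: Optional[float] = None  # default: k
    multimap_ratio: float = 0.95
    mapq_cap: int = 60
    max_fast_path_mismatches: int = 5


@dataclass
class AlignmentRecord:
    """SAM-conformant placement of one read."""

    qname: str
    flag: int
    rname: Optional[str]
    pos0: int  # 0-based leftmost reference position (-1 if unmapped)
    mapq: int
    cigar: Optional[str]
    seq: str
    qual: str
    tags: Dict[str, int] = field(default_factory=dict)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def pos1(self) -> int:
        return self.pos0 + 1


def seed(
    read_seq: str,
    index: MinimizerIndex,
    filter_n: Union[int, None, str] = "params",
) -> List[Anchor]:
    """Anchors between a read's minimizers and the index occurrences."""
    k = index.params.k
    read_len = len(read_seq)
    anchors: List[Anchor] = []
    for m in compute_minimizers(Contig("read", read_seq), index.params):
        for cid, pos, strand in index.query(m.hash, filter_n):
            rel = m.strand * strand
            rpos = m.pos if rel > 0 else read_len - k - m.pos
            anchors.append(Anchor(rpos, cid, pos, rel, m.hash))
    anchors.sort()
    return anchors


def chain(
    anchors: Sequence[Anchor], k: int, cfg: AlignerConfig = AlignerConfig()
) -> List[Chain]:
    """Collinear chains of anchors, best score first.

    Per (contig, strand), ``score(j) = max(k, score(i) + min(k, dq, dr)
    - gap_weight * |dq - dr|)`` over predecessors ``i`` with positive
    read/reference gaps ``dq``, ``dr`` bounded by ``max_gap``.  Chains
    are extracted best-first; anchors already consumed by a better chain
    are not reused, and chains whose reference span largely overlaps an
    already-extracted chain on the same contig are dropped — they are
    alternate paths through the same locus, not alternative placements.
    """
    min_score = cfg.min_chain_score if cfg.min_chain_score is not None else float(k)
    groups: Dict[Tuple[int, int], List[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.contig_id, a.strand), []).append(a)

    chains: List[Chain] = []
    for (cid, strand), grp in groups.items():
        grp.sort(key=lambda a: (a.ref_pos, a.read_pos))
        n = len(grp)
        score = [float(k)] * n
        back = [-1] * n
        for j in range(n):
            aj = grp[j]
            for i in range(j):
                ai = grp[i]
                dq = aj.read_pos - ai.read_pos
                dr = aj.ref_pos - ai.ref_pos
                if dq <= 0 or dr <= 0 or dq > cfg.max_gap or dr > cfg.max_gap:
                    continue
                s = score[i] + min(k, dq, dr) - cfg.gap_weight * abs(dq - dr)
                if s >= score[j]:  # ties prefer the nearest predecessor
                    score[j] = s
                    back[j] = i
        consumed = [False] * n
        for j in sorted(range(n), key=lambda j: -score[j]):
            if consumed[j] or score[j] < min_score:
                continue
            members = []
            i = j
            while i != -1 and not consumed[i]:
                members.append(i)
                i = back[i]
            for i in members:
                consumed[i] = True
            members.reverse()
            chains.append(Chain([grp[i] for i in members], score[j], cid, strand))
    chains.sort(
        key=lambda c: (
            -c.score,
            c.contig_id,
            c.anchors[0].ref_pos,
            -c.strand,
        )
    )
    kept: List[Chain] = []
    spans: List[Tuple[int, int, int]] = []  # (contig_id, start, end)
    for c in chains:
        start = c.anchors[0].ref_pos
        end = c.anchors[-1].ref_pos + k
        redundant = False
        for cid, s, e in spans:
            if cid != c.contig_id:
                continue
            overlap = min(end, e) - max(start, s)
            if overlap > 0.5 * min(end - start, e - s):
                redundant = True
                break
        if not redundant:
            kept.append(c)
            spans.append((c.contig_id, start, end))
    return kept


def mapq(best_score: float, second_score: Optional[float], cap: int = 60) -> int:
    """Mapping quality from the two best chain scores."""
    if second_score is None:
        return cap
    if best_score <= 0:
        return 0
    q = round(cap * (1.0 - second_score / best_score))
    return max(0, min(cap, q))


def _nw_aligner(cfg: AlignerConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = cfg.match
    aligner.mismatch_score = cfg.mismatch
    # Biopython charges open_gap_score for the first gap base, so a gap
    # of length L costs open + (L-1)*extend there; shift to make it
    # -(gap_open + L*gap_extend) as used throughout this package.
    aligner.open_gap_score = -(cfg.gap_open + cfg.gap_extend)
    aligner.extend_gap_score = -cfg.gap_extend
    # free end gaps on both sides: reference overhang only shifts the
    # position, read overhang becomes a soft clip
    try:
        aligner.end_deletion_score = 0.0
        aligner.end_insertion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _cigar_str(ops: List[Tuple[str, int]]) -> str:
    merged: List[Tuple[str, int]] = []
    for op, ln in ops:
        if ln <= 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return "".join(f"{ln}{op}" for op, ln in merged)


def _score_cigar(
    ops: List[Tuple[str, int]], read: str, ref: str, pos0: int, cfg: AlignerConfig
) -> Tuple[int, int]:
    """(NM, AS) computed by walking the CIGAR against both sequences."""
    nm = 0
    score = 0
    qi, ri = 0, pos0
    for op, ln in ops:
        if op == "M":
            mm = sum(1 for a, b in zip(read[qi : qi + ln], ref[ri : ri + ln]) if a != b)
            nm += mm
            score += cfg.match * (ln - mm) + cfg.mismatch * mm
            qi += ln
            ri += ln
        elif op == "I":
            nm += ln
            score -= cfg.gap_open + cfg.gap_extend * ln
            qi += ln
        elif op == "D":
            nm += ln
            score -= cfg.gap_open + cfg.gap_extend * ln
            ri += ln
        elif op == "S":
            qi += ln
    return nm, score


def extend_align(
    oriented_read: str,
    contig: Contig,
    chn: Chain,
    k: int,
    cfg: AlignerConfig = AlignerConfig(),
) -> Optional[Tuple[int, List[Tuple[str, int]], int, int]]:
    """Base-level alignment of a chained read region.

    Returns ``(pos0, cigar ops, NM, AS)`` on the chain's contig, or None
    when no aligned region survives.  ``oriented_read`` must already be
    reverse-complemented for reverse-strand chains.

    A fast path handles the common case of a single-diagonal chain whose
    implied reference segment fits the read with few mismatches; all
    other cases go through affine-gap Needleman-Wunsch over a padded
    reference window, with reference end gaps free (they only shift the
    position) and read end gaps reported as soft clips.
    """
    read_len = len(oriented_read)
    first, last = chn.anchors[0], chn.anchors[-1]
    diags = {a.ref_pos - a.read_pos for a in chn.anchors}

    if len(diags) == 1:
        start = first.ref_pos - first.read_pos
        if 0 <= start and start + read_len <= contig.length:
            segment = contig.sequence[start : start + read_len]
            mm = sum(1 for a, b in zip(oriented_read, segment) if a != b)
            if mm <= cfg.max_fast_path_mismatches:
                ops = [("M", read_len)]
                nm, as_score = _score_cigar(ops, oriented_read, contig.sequence, start, cfg)
                return start, ops, nm, as_score

    pad = 16 + (max(diags) - min(diags))
    rs = max(0, first.ref_pos - first.read_pos - pad)
    re_ = min(contig.length, last.ref_pos + k + (read_len - last.read_pos - k) + pad)
    window = contig.sequence[rs:re_]
    if not window:
        return None
    aln = _nw_aligner(cfg).align(window, oriented_read)[0]
    tblocks, qblocks = aln.aligned
    if len(tblocks) == 0:
        return None
    ops: List[Tuple[str, int]] = []
    pos0 = rs + int(tblocks[0][0])
    q_prev = int(qblocks[0][0])
    t_prev = int(tblocks[0][0])
    if q_prev > 0:
        ops.append(("S", q_prev))
    for (ts, te), (qs, qe) in zip(tblocks.tolist(), qblocks.tolist()):
        if qs > q_prev:
            ops.append(("I", qs - q_prev))
        if ts > t_prev:
            ops.append(("D", ts - t_prev))
        ops.append(("M", te - ts))
        q_prev, t_prev = qe, te
    if read_len - q_prev > 0:
        ops.append(("S", read_len - q_prev))
    nm, as_score = _score_cigar(ops, oriented_read, contig.sequence, pos0, cfg)
    return pos0, ops, nm, as_score


def _unmapped(qname: str, seq: str, qual: str) -> AlignmentRecord:
    return AlignmentRecord(qname, FLAG_UNMAPPED, None, -1, 0, None, seq, qual)


def align_read(
    qname: str,
    seq: str,
    qual: str,
    index: MinimizerIndex,
    reference: Sequence[Contig],
    cfg: AlignerConfig = AlignerConfig(),
    filter_n: Union[int, None, str] = "params",
) -> List[AlignmentRecord]:
    """Full seed-chain-align of one read; primary record first."""
    seq = seq.upper()
    k = index.params.k
    if len(seq) < k:
        return [_unmapped(qname, seq, qual)]
    anchors = seed(seq, index, filter_n)
    if not anchors:
        return [_unmapped(qname, seq, qual)]
    chains = chain(anchors, k, cfg)
    if not chains:
        return [_unmapped(qname, seq, qual)]
    best = chains[0]
    second = chains[1].score if len(chains) > 1 else None
    q = mapq(best.score, second, cfg.mapq_cap)
    n_close = sum(1 for c in chains if c.score >= cfg.multimap_ratio * best.score)

    flag = 0
    if best.strand < 0:
        flag |= FLAG_REVERSE
        oriented, oqual = reverse_complement(seq), qual[::-1]
    else:
        oriented, oqual = seq, qual
    contig = reference[best.contig_id]
    result = extend_align(oriented, contig, best, k, cfg)
    if result is None:
        return [_unmapped(qname, seq, qual)]
    pos0, ops, nm, as_score = result
    tags = {"NM": nm, "AS": as_score}
    if n_close >= 2:
        tags["ZM"] = 1
    rec = AlignmentRecord(
        qname, flag, contig.name, pos0, q, _cigar_str(ops), oriented, oqual, tags
    )
    return [rec]


def _sam_header(reference: Sequence[Contig]) -> pysam.AlignmentHeader:
    from . import __version__

    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": c.name, "LN": c.length} for c in reference],
            "PG": [{"ID": "varmin", "PN": "varmin", "VN": __version__}],
        }
    )


def write_sam(
    records: Sequence[AlignmentRecord],
    reference: Sequence[Contig],
    path: Union[str, Path],
) -> None:
    header = _sam_header(reference)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(header)
            a.query_name = r.qname
            a.flag = r.flag
            if not r.is_unmapped:
                a.reference_id = header.get_tid(r.rname)
                a.reference_start = r.pos0
                a.mapping_quality = r.mapq
                a.cigarstring = r.cigar
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array(r.qual)
            a.set_tags(sorted(r.tags.items()))
            out.write(a)


def align_fastq(
    index: MinimizerIndex,
    reference: Sequence[Contig],
    fastq_paths: Sequence[Union[str, Path]],
    out_sam: Union[str, Path],
    cfg: AlignerConfig = AlignerConfig(),
    filter_n: Union[int, None, str] = "params",
) -> Dict[str, int]:
    """Align one or two FASTQ files (mates treated independently) to SAM."""
    from .io import read_fastq

    index.check_reference(list(reference))
    stats = {"reads": 0, "mapped": 0, "unmapped": 0}
    records: List[AlignmentRecord] = []
    for path in fastq_paths:
        for name, seq, qual in read_fastq(path):
            recs = align_read(name, seq, qual, index, reference, cfg, filter_n)
            records.extend(recs)
            stats["reads"] += 1
            stats["mapped" if not recs[0].is_unmapped else "unmapped"] += 1
    write_sam(records, reference, out_sam)
    return stats
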