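"""Synthetic data: reference, donor variants, VCF, reads with truth.

A desk-scale stand-in for a real benchmark: a random reference genome
(optionally with planted interspersed repeat families), a donor genome
carrying known SNVs and short indels, a population-style VCF with AF and
genotype fields, and error-bearing short reads sampled from the donor
with a truth table of their reference placements.

Everything is bit-deterministic for a fixed seed.  Sequencing errors
are substitution-only so that placement failures are attributable to
donor variants rather than simulated read indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam

from .minimizers import Contig, IndexParams, reverse_complement
from .variants import Variant, apply_haplotype

__all__ = [
    "RepeatSpec",
    "SimVariant",
    "SimulatedVariants",
    "simulate_reference",
    "simulate_variants",
    "simulate_reads",
    "write_truth",
    "read_truth",
    "standard_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RepeatSpec:
    """Planted interspersed repeats: identical copies of random units.

    ``families`` lists ``(unit_length, copies)`` per family.  The default
    mixes copy numbers around a typical occurrence-filter threshold so a
    fixture exercises both repeat regimes of a real genome: high-copy
    families whose seeds the filter suppresses entirely (reads inside
    them have no plain seeds) and low-copy families whose seeds survive
    (reads inside them are ambiguous among the copies).
    """

    families: Tuple[Tuple[int, int], ...] = (
        (400, 8),
        (400, 8),
        (400, 8),
        (400, 3),
        (400, 3),
        (400, 3),
    )


@dataclass(frozen=True)
class SimVariant:
    contig: str
    pos0: int
    ref_allele: str
    alt_allele: str
    vclass: str
    af: float
    gt: Tuple[int, int]
    phased: bool

    @property
    def end0(self) -> int:
        return self.pos0 + len(self.ref_allele)

    def as_variant(self) -> Variant:
        return Variant(
            self.contig, self.pos0, self.ref_allele, self.alt_allele, self.vclass, self.af
        )


@dataclass
class SimulatedVariants:
    """Donor variant set plus the two donor haplotype sequences."""

    reference: List[Contig]
    records: List[SimVariant]
    donor_seqs: Dict[Tuple[str, int], str]  # (contig, hap) -> sequence
    donor_maps: Dict[Tuple[str, int], Tuple[int, ...]]  # donor pos -> ref pos

    def write_vcf(self, path: Union[str, Path]) -> None:
        header = pysam.VariantHeader()
        for c in self.reference:
            header.contigs.add(c.name, length=c.length)
        header.info.add("AF", "A", "Float", "Allele frequency")
        header.formats.add("GT", 1, "String", "Genotype")
        header.add_sample("DONOR")
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for v in sorted(self.records, key=lambda v: (v.contig, v.pos0)):
                rec = vf.new_record(
                    contig=v.contig,
                    start=v.pos0,
                    alleles=(v.ref_allele, v.alt_allele),
                )
                rec.info["AF"] = (v.af,)
                rec.samples["DONOR"]["GT"] = v.gt
                rec.samples["DONOR"].phased = v.phased
                vf.write(rec)


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def simulate_reference(
    length: int = 100_000,
    n_contigs: int = 1,
    seed: int = 0,
    repeat_spec: Optional[RepeatSpec] = None,
) -> List[Contig]:
    """Uniform random reference with optional planted repeat families.

    Repeat families are assigned to contigs round-robin; each family's
    unit is a fresh random sequence pasted at non-overlapping positions
    as exact copies (so copies are distinguishable only by context).
    """
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    rng = np.random.default_rng(seed)
    per = length // n_contigs
    contigs = []
    codes_list = []
    for i in range(n_contigs):
        clen = per if i < n_contigs - 1 else length - per * (n_contigs - 1)
        codes_list.append(_random_codes(rng, clen))
    if repeat_spec is not None:
        taken_per_contig: List[List[Tuple[int, int]]] = [[] for _ in codes_list]
        for fam, (unit_length, copies) in enumerate(repeat_spec.families):
            ci = fam % n_contigs
            codes = codes_list[ci]
            taken = taken_per_contig[ci]
            unit = _random_codes(rng, unit_length)
            placed = 0
            attempts = 0
            while placed < copies and attempts < 10_000:
                attempts += 1
                p = int(rng.integers(0, len(codes) - unit_length))
                q = p + unit_length
                if any(p < e and q > s for s, e in taken):
                    continue
                codes[p:q] = unit
                taken.append((p, q))
                placed += 1
            if placed < copies:
                raise ValueError("could not place all repeat copies")
    for i, codes in enumerate(codes_list):
        seq = _BASES[codes].tobytes().decode("ascii")
        contigs.append(Contig(f"chr{i + 1}", seq))
    return contigs


def simulate_variants(
    reference: Sequence[Contig],
    snv_count: int = 500,
    indel_count: int = 50,
    indel_len_range: Tuple[int, int] = (1, 5),
    phased_fraction: float = 0.5,
    af: float = 0.5,
    het_fraction: float = 0.0,
    seed: int = 0,
    min_gap: int = 12,
    edge_margin: int = 200,
) -> SimulatedVariants:
    """Place non-overlapping SNVs and short indels; build the donor.

    The donor is homozygous ALT by default (``het_fraction=0``) so every
    read spanning a variant locus carries the variant; a fraction of
    records can be made heterozygous (ALT on one random haplotype) for
    haplotype-logic experiments.  ``phased_fraction`` of the records get
    a phased ("|") genotype separator in the VCF, the rest "/".
    """
    rng = np.random.default_rng(seed)
    total_len = sum(c.length for c in reference)
    records: List[SimVariant] = []
    lo, hi = indel_len_range
    for contig in reference:
        share = contig.length / total_len
        n_snv = int(round(snv_count * share))
        n_indel = int(round(indel_count * share))
        occupied: List[Tuple[int, int]] = []
        seq = contig.sequence

        def place(span: int) -> Optional[int]:
            for _ in range(20_000):
                p = int(rng.integers(edge_margin, contig.length - edge_margin - span))
                if not any(p - min_gap < e and p + span + min_gap > s for s, e in occupied):
                    occupied.append((p, p + span))
                    return p
            raise ValueError("variant density infeasible for this reference")

        specs = [("SNV", 1)] * n_snv + [
            ("INDEL", int(rng.integers(lo, hi + 1))) for _ in range(n_indel)
        ]
        for kind, ln in specs:
            if kind == "SNV":
                p = place(1)
                ref_a = seq[p]
                alt_a = "ACGT".replace(ref_a, "")[int(rng.integers(0, 3))]
                vclass = "SNV"
            else:
                if rng.random() < 0.5:  # deletion of ln bases
                    p = place(1 + ln)
                    ref_a = seq[p : p + 1 + ln]
                    alt_a = seq[p]
                    vclass = "DEL"
                else:  # insertion of ln bases
                    p = place(1)
                    ref_a = seq[p]
                    alt_a = ref_a + _BASES[_random_codes(rng, ln)].tobytes().decode()
                    vclass = "INS"
            if het_fraction > 0 and rng.random() < het_fraction:
                gt = (0, 1) if rng.random() < 0.5 else (1, 0)
            else:
                gt = (1, 1)
            phased = bool(rng.random() < phased_fraction)
            records.append(
                SimVariant(contig.name, p, ref_a, alt_a, vclass, af, gt, phased)
            )

    donor_seqs: Dict[Tuple[str, int], str] = {}
    donor_maps: Dict[Tuple[str, int], Tuple[int, ...]] = {}
    for contig in reference:
        for hap in (0, 1):
            carried = [
                v.as_variant()
                for v in records
                if v.contig == contig.name and v.gt[hap] == 1
            ]
            h = apply_haplotype(contig.sequence, 0, carried)
            donor_seqs[(contig.name, hap)] = h.alt_seq
            donor_maps[(contig.name, hap)] = h.coord_map
    return SimulatedVariants(list(reference), records, donor_seqs, donor_maps)


def simulate_reads(
    sim: SimulatedVariants,
    read_length: int = 150,
    coverage: float = 30.0,
    error_rate: float = 0.001,
    seed: int = 0,
    quality_char: str = "I",
) -> Tuple[List[Tuple[str, str, str]], pd.DataFrame]:
    """Sample error-bearing reads from the donor with a truth table.

    Fragments are drawn uniformly from both donor haplotypes, half on
    each strand; bases are copied with iid substitution errors at
    ``error_rate``.  Truth coordinates are reference coordinates via the
    donor-to-reference map, together with the donor variants overlapped
    by each fragment.
    """
    rng = np.random.default_rng(seed)
    total_len = sum(c.length for c in sim.reference)
    n_reads = int(round(coverage * total_len / read_length))
    by_contig: Dict[str, List[SimVariant]] = {}
    for v in sim.records:
        by_contig.setdefault(v.contig, []).append(v)
    for vs in by_contig.values():
        vs.sort(key=lambda v: v.pos0)

    reads: List[Tuple[str, str, str]] = []
    rows = []
    qual = quality_char * read_length
    contig_names = [c.name for c in sim.reference]
    weights = np.array([c.length for c in sim.reference], dtype=float)
    weights /= weights.sum()
    for i in range(n_reads):
        cname = contig_names[int(rng.choice(len(contig_names), p=weights))]
        hap = int(rng.integers(0, 2))
        dseq = sim.donor_seqs[(cname, hap)]
        dmap = sim.donor_maps[(cname, hap)]
        start = int(rng.integers(0, len(dseq) - read_length + 1))
        frag = dseq[start : start + read_length]
        ref_start = dmap[start]
        ref_end = dmap[start + read_length - 1] + 1
        overlapped = [
            v
            for v in by_contig.get(cname, [])
            if v.pos0 < ref_end and v.end0 > ref_start and v.gt[hap] == 1
        ]
        n_err = rng.binomial(read_length, error_rate)
        if n_err:
            frag_arr = bytearray(frag, "ascii")
            for p in rng.choice(read_length, size=n_err, replace=False):
                cur = chr(frag_arr[p])
                if cur not in "ACGT":
                    continue
                frag_arr[p] = ord("ACGT".replace(cur, "")[int(rng.integers(0, 3))])
            frag = frag_arr.decode("ascii")
        strand = "-" if rng.random() < 0.5 else "+"
        out_seq = reverse_complement(frag) if strand == "-" else frag
        name = f"r{i:06d}"
        reads.append((name, out_seq, qual))
        rows.append(
            {
                "read_id": name,
                "contig": cname,
                "ref_start": ref_start,
                "ref_end": ref_end,
                "hap": hap,
                "strand": strand,
                "n_snv": sum(1 for v in overlapped if v.vclass == "SNV"),
                "n_indel": sum(1 for v in overlapped if v.vclass != "SNV"),
                "variants": ";".join(
                    f"{v.pos0}:{v.ref_allele}>{v.alt_allele}" for v in overlapped
                ),
            }
        )
    return reads, pd.DataFrame(rows)


def write_truth(truth: pd.DataFrame, path: Union[str, Path]) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def standard_dataset(seed: int = 7) -> Dict[str, object]:
    """The package's standard end-to-end fixture.

    100 kb reference with six planted repeat families (400 bp units;
    three families of 8 identical copies, three of 3), 500 SNVs + 50
    indels of length 1-5 at AF 0.5, homozygous-ALT donor, 150 bp
    single-end reads at 30x with 0.1% substitution error; index
    parameters k=21, w=11 and occurrence filter n=4.  The filter sits
    between the two repeat copy numbers, so high-copy repeat seeds are
    suppressed (reads inside them have no plain seeds) while low-copy
    repeat seeds survive (reads inside them are ambiguous among copies)
    — the two regimes in which known variants can rescue placement.
    """
    reference = simulate_reference(
        length=100_000, n_contigs=1, seed=seed, repeat_spec=RepeatSpec()
    )
    sim = simulate_variants(
        reference,
        snv_count=500,
        indel_count=50,
        indel_len_range=(1, 5),
        phased_fraction=0.5,
        af=0.5,
        het_fraction=0.0,
        seed=seed + 1,
    )
    reads, truth = simulate_reads(
        sim, read_length=150, coverage=30.0, error_rate=0.001, seed=seed + 2
    )
    return {
        "reference": reference,
        "sim": sim,
        "reads": reads,
        "truth": truth,
        "params": IndexParams(k=21, w=11, filter_n=4),
    }
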