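"""Helper for writing small VCF fixtures programmatically."""

from typing import Optional, Sequence, Tuple

import pysam


def write_vcf(
    path,
    contigs: Sequence[Tuple[str, int]],
    rows: Sequence[dict],
    samples: Sequence[str] = (),
) -> str:
    """rows: dicts with contig, pos0, ref, alts, optional af (tuple),
    optional gts: per-sample (allele tuple, phased)."""
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(name, length=length)
    header.info.add("AF", "A", "Float", "Allele frequency")
    if samples:
        header.formats.add("GT", 1, "String", "Genotype")
        for s in samples:
            header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for row in rows:
            rec = vf.new_record(
                contig=row["contig"],
                start=row["pos0"],
                alleles=(row["ref"], *row["alts"]),
            )
            if row.get("af") is not None:
                rec.info["AF"] = tuple(row["af"])
            for sname, (gt, phased) in zip(samples, row.get("gts", ())):
                rec.samples[sname]["GT"] = gt
                rec.samples[sname].phased = phased
            vf.write(rec)
    return str(path)
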