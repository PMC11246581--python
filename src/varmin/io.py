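"""FASTA and FASTQ file handling.

Thin wrappers around Biopython's SeqIO that normalise sequences into the
package's :class:`~varmin.minimizers.Contig` container: soft-masked
lowercase is uppercased and IUPAC ambiguity codes other than N are
mapped to N.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator, List, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .minimizers import Contig

_NON_ACGT = re.compile(r"[^ACGTN]")


def read_fasta(path: Union[str, Path]) -> List[Contig]:
    """Read a (multi-contig, line-wrapped) FASTA file."""
    contigs = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _NON_ACGT.sub("N", str(rec.seq).upper())
        contigs.append(Contig(rec.id, seq))
    if not contigs:
        raise ValueError(f"no sequences found in {path}")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: Union[str, Path]) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.name, description="") for c in contigs]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: Union[str, Path]) -> Iterator[Tuple[str, str, str]]:
    """Yield (name, sequence, quality string) tuples from a FASTQ file."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence.upper(), entry.quality or "I" * len(
                entry.sequence
            )


def write_fastq(
    reads: Iterable[Tuple[str, str, str]], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
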