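"""Read-placement evaluation of a SAM file against a truth table.

A read is *correctly placed* iff it is mapped to its true contig with a
leftmost position within ``tolerance_bp`` (default 20) of the true
reference start; the tolerance absorbs soft-clip and short-indel
ambiguity at read ends.  Results are stratified by the truth record's
variant overlap: none / SNV / indel (a read overlapping both strata
counts as indel).  Multi-mapped reads are those the aligner tagged
``ZM`` (two or more chains within 95% of the best chain score).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Union

import pandas as pd
import pysam

__all__ = ["EvalReport", "evaluate"]

STRATA = ("none", "snv", "indel")


@dataclass
class EvalReport:
    total: int = 0
    mapped: int = 0
    unmapped: int = 0
    multimapped: int = 0
    correct: int = 0
    incorrect: int = 0
    tolerance_bp: int = 20
    strata: Dict[str, Dict[str, int]] = field(
        default_factory=lambda: {
            s: {"total": 0, "correct": 0, "incorrect": 0, "unmapped": 0}
            for s in STRATA
        }
    )

    def as_dict(self) -> Dict[str, object]:
        return {
            "total": self.total,
            "mapped": self.mapped,
            "unmapped": self.unmapped,
            "multimapped": self.multimapped,
            "correct": self.correct,
            "incorrect": self.incorrect,
            "tolerance_bp": self.tolerance_bp,
            "strata": self.strata,
        }

    def summary(self) -> str:
        lines = [
            f"reads {self.total}  mapped {self.mapped}  unmapped {self.unmapped}"
            f"  multi-mapped {self.multimapped}",
            f"correct {self.correct}  incorrect {self.incorrect}"
            f"  (tolerance {self.tolerance_bp} bp)",
        ]
        for s in STRATA:
            d = self.strata[s]
            lines.append(
                f"  {s:>5}: total {d['total']:6d}  correct {d['correct']:6d}"
                f"  incorrect {d['incorrect']:5d}  unmapped {d['unmapped']:5d}"
            )
        return "\n".join(lines)


def _stratum(row) -> str:
    if row["n_indel"] > 0:
        return "indel"
    if row["n_snv"] > 0:
        return "snv"
    return "none"


def evaluate(
    sam_path: Union[str, Path],
    truth: Union[pd.DataFrame, str, Path],
    tolerance_bp: int = 20,
) -> EvalReport:
    """Score primary alignments against the truth table (order-invariant)."""
    if not isinstance(truth, pd.DataFrame):
        from .simulate import read_truth

        truth = read_truth(truth)
    truth_by_id = truth.set_index("read_id")

    placements: Dict[str, tuple] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_name not in truth_by_id.index:
                raise ValueError(
                    f"read {rec.query_name!r} in SAM but absent from truth"
                )
            multi = rec.has_tag("ZM") and rec.get_tag("ZM") == 1
            if rec.is_unmapped:
                placements[rec.query_name] = (False, None, None, multi)
            else:
                placements[rec.query_name] = (
                    True,
                    rec.reference_name,
                    rec.reference_start,
                    multi,
                )

    report = EvalReport(tolerance_bp=tolerance_bp)
    for read_id, row in truth_by_id.iterrows():
        stratum = _stratum(row)
        report.total += 1
        report.strata[stratum]["total"] += 1
        placed = placements.get(read_id)
        if placed is None or not placed[0]:
            report.unmapped += 1
            report.strata[stratum]["unmapped"] += 1
            if placed is not None and placed[3]:
                report.multimapped += 1
            continue
        _, contig, pos, multi = placed
        report.mapped += 1
        if multi:
            report.multimapped += 1
        ok = contig == row["contig"] and abs(pos - row["ref_start"]) <= tolerance_bp
        if ok:
            report.correct += 1
            report.strata[stratum]["correct"] += 1
        else:
            report.incorrect += 1
            report.strata[stratum]["incorrect"] += 1
    return report
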