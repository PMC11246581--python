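"""High-level wiring of the five capabilities with run manifests.

These functions are the package's operational entry points — index a
reference, modify the index with a VCF, align reads, simulate a
dataset, evaluate placements — each validating its parameters before
any computation and writing a machine-readable manifest (tool version,
parameters, input digests) beside every file it produces, so any output
is reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

from .align import AlignerConfig, align_fastq
from .evaluate import EvalReport, evaluate
from .index import (
    MinimizerIndex,
    adjust_filter_threshold,
    build_index,
    load_index,
    save_index,
)
from .io import read_fasta, write_fasta, write_fastq
from .minimizers import IndexParams
from .modifier import modify_index
from .simulate import (
    standard_dataset,
    write_truth,
)
from .variants import build_windows, load_variants

__all__ = [
    "RunConfig",
    "write_manifest",
    "index_reference",
    "modify_with_vcf",
    "align_reads",
    "simulate_dataset",
    "evaluate_alignments",
    "run_standard_experiment",
]


@dataclass(frozen=True)
class RunConfig:
    """Validated run parameters shared across the pipeline steps."""

    k: int = 21
    w: int = 11
    filter_n: Optional[int] = None
    min_af: Optional[float] = 0.05
    seed: int = 0
    tolerance_bp: int = 20
    aligner: AlignerConfig = field(default_factory=AlignerConfig)

    def __post_init__(self) -> None:
        IndexParams(self.k, self.w, filter_n=self.filter_n)  # validates ranges
        if self.min_af is not None and not (0.0 <= self.min_af <= 1.0):
            raise ValueError("min_af must lie in [0, 1]")
        if self.tolerance_bp < 0:
            raise ValueError("tolerance_bp must be non-negative")

    @property
    def index_params(self) -> IndexParams:
        return IndexParams(self.k, self.w, filter_n=self.filter_n)


def _digest_file(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(
    out_path: Union[str, Path],
    params: Dict[str, object],
    inputs: Sequence[Union[str, Path]],
) -> Path:
    """Write ``<out_path>.manifest.json`` describing how the file was made."""
    from . import __version__

    manifest = {
        "tool": "varmin",
        "version": __version__,
        "output": str(Path(out_path).name),
        "params": params,
        "inputs": {str(Path(p).name): _digest_file(p) for p in inputs},
    }
    mpath = Path(str(out_path) + ".manifest.json")
    mpath.write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return mpath


def index_reference(
    fasta_path: Union[str, Path],
    config: RunConfig = RunConfig(),
    out_path: Optional[Union[str, Path]] = None,
) -> MinimizerIndex:
    reference = read_fasta(fasta_path)
    index = build_index(reference, config.index_params)
    if out_path is not None:
        save_index(index, out_path)
        write_manifest(out_path, dataclasses.asdict(config), [fasta_path])
    return index


def modify_with_vcf(
    index: Union[MinimizerIndex, str, Path],
    vcf_path: Union[str, Path],
    fasta_path: Union[str, Path],
    config: RunConfig = RunConfig(),
    out_path: Optional[Union[str, Path]] = None,
):
    """Augment an index with a VCF's variants; returns (index, report)."""
    if not isinstance(index, MinimizerIndex):
        index = load_index(index)
    reference = read_fasta(fasta_path)
    index.check_reference(reference)
    variants, _rejected = load_variants(
        vcf_path, reference, af_min=config.min_af, k=index.params.k
    )
    lengths = {c.name: c.length for c in reference}
    windows = build_windows(variants, index.params, lengths)
    modified, report = modify_index(index, windows, reference)
    if out_path is not None:
        save_index(modified, out_path)
        write_manifest(
            out_path, dataclasses.asdict(config), [vcf_path, fasta_path]
        )
    return modified, report


def align_reads(
    index: Union[MinimizerIndex, str, Path],
    fasta_path: Union[str, Path],
    fastq_paths: Sequence[Union[str, Path]],
    out_sam: Union[str, Path],
    config: RunConfig = RunConfig(),
    filter_n: Union[int, None, str] = "params",
) -> Dict[str, int]:
    if not isinstance(index, MinimizerIndex):
        index = load_index(index)
    reference = read_fasta(fasta_path)
    stats = align_fastq(
        index, reference, fastq_paths, out_sam, config.aligner, filter_n
    )
    write_manifest(out_sam, dataclasses.asdict(config), [fasta_path, *fastq_paths])
    return stats


def simulate_dataset(
    out_dir: Union[str, Path], seed: int = 7
) -> Dict[str, Path]:
    """Materialise the standard fixture as files in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = standard_dataset(seed)
    paths = {
        "fasta": out / "reference.fa",
        "vcf": out / "variants.vcf",
        "fastq": out / "reads.fq",
        "truth": out / "truth.tsv",
    }
    write_fasta(data["reference"], paths["fasta"])
    data["sim"].write_vcf(paths["vcf"])
    write_fastq(data["reads"], paths["fastq"])
    write_truth(data["truth"], paths["truth"])
    for p in paths.values():
        write_manifest(p, {"seed": seed, "fixture": "standard"}, [])
    return paths


def evaluate_alignments(
    sam_path: Union[str, Path],
    truth_path: Union[str, Path],
    tolerance_bp: int = 20,
) -> EvalReport:
    return evaluate(sam_path, truth_path, tolerance_bp)


def run_standard_experiment(
    seed: int = 7,
    work_dir: Optional[Union[str, Path]] = None,
) -> Dict[str, object]:
    """Simulate, index, modify, align with both indexes, and evaluate.

    The headline comparison: the variant-modified index versus the plain
    index on reads from a donor genome carrying known variants.  Returns
    both evaluation reports plus the modification report and the
    adjusted occurrence-filter threshold used for the modified index.
    """
    if work_dir is None:
        tmp = tempfile.TemporaryDirectory(prefix="varmin_")
        work = Path(tmp.name)
    else:
        tmp = None
        work = Path(work_dir)
        work.mkdir(parents=True, exist_ok=True)
    try:
        paths = simulate_dataset(work, seed=seed)
        config = RunConfig(k=21, w=11, filter_n=4, min_af=0.05, seed=seed)
        reference = read_fasta(paths["fasta"])
        plain = build_index(reference, config.index_params)
        modified, mod_report = modify_with_vcf(
            plain, paths["vcf"], paths["fasta"], config
        )
        adjusted_n = adjust_filter_threshold(
            plain.stats(), modified.stats("params"), config.filter_n
        )
        modified.params = dataclasses.replace(modified.params, filter_n=adjusted_n)

        sam_plain = work / "plain.sam"
        sam_modified = work / "modified.sam"
        align_reads(plain, paths["fasta"], [paths["fastq"]], sam_plain, config)
        align_reads(modified, paths["fasta"], [paths["fastq"]], sam_modified, config)
        report_plain = evaluate(sam_plain, paths["truth"], config.tolerance_bp)
        report_modified = evaluate(sam_modified, paths["truth"], config.tolerance_bp)
        return {
            "plain": report_plain,
            "modified": report_modified,
            "modify_report": mod_report,
            "adjusted_filter_n": adjusted_n,
            "seed": seed,
            "paths": paths if work_dir is not None else None,
        }
    finally:
        if tmp is not None:
            tmp.cleanup()
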