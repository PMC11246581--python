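"""Minimizer hash-table index: build, query, filter, serialise, compare.

The index maps each canonical minimizer hash to the sorted list of its
occurrences ``(contig_id, pos, strand)`` on the reference.  Highly
repetitive seeds (hashes occurring more than ``filter_n`` times) are
suppressed at *query* time, so one index file serves any threshold.

Serialisation is a deterministic, versioned canonical-JSON container
(sorted keys, fixed separators): saving the same index twice produces
byte-identical files, and the stored reference digest binds the index
to the FASTA it was built from.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

from .minimizers import Contig, IndexParams, Minimizer, compute_minimizers, reference_digest

__all__ = [
    "IndexStats",
    "MinimizerIndex",
    "build_index",
    "adjust_filter_threshold",
    "save_index",
    "load_index",
]

_FORMAT_MAGIC = "VARMIN_INDEX"
_FORMAT_VERSION = 1

Occurrence = Tuple[int, int, int]  # (contig_id, pos, strand)


@dataclass(frozen=True)
class IndexStats:
    """Occurrence statistics of an index under a given filter threshold."""

    total_occurrences: int
    distinct_hashes: int
    ignored_occurrences: int
    count_histogram: Dict[int, int]  # occurrence count -> number of hashes

    def ignored_at(self, filter_n: Optional[int]) -> int:
        """Occurrences suppressed by a hypothetical threshold."""
        if filter_n is None:
            return 0
        return sum(c * n for c, n in self.count_histogram.items() if c > filter_n)

    def ignored_fraction(self, filter_n: Optional[int]) -> float:
        if self.total_occurrences == 0:
            raise ValueError("empty index has no ignored fraction")
        return self.ignored_at(filter_n) / self.total_occurrences


@dataclass
class MinimizerIndex:
    """Hash table from minimizer hash to reference occurrences."""

    params: IndexParams
    reference_digest: str
    contig_names: Tuple[str, ...]
    contig_lengths: Tuple[int, ...]
    table: Dict[int, List[Occurrence]]
    provenance: str = "plain"  # "plain" or "modified"
    n_added: int = 0

    def query(self, hash_: int, filter_n: Union[int, None, str] = "params") -> List[Occurrence]:
        """Occurrence list for a hash, honouring the occurrence filter.

        Hashes occurring strictly more than ``filter_n`` times return an
        empty list.  ``filter_n="params"`` (default) uses the index's own
        threshold; pass ``None`` to disable filtering.
        """
        occs = self.table.get(hash_)
        if not occs:
            return []
        n = self.params.filter_n if filter_n == "params" else filter_n
        if n is not None and len(occs) > n:
            return []
        return occs

    def stats(self, filter_n: Union[int, None, str] = "params") -> IndexStats:
        """Recount occurrence statistics directly from the table."""
        n = self.params.filter_n if filter_n == "params" else filter_n
        hist: Counter = Counter(len(v) for v in self.table.values())
        total = sum(c * m for c, m in hist.items())
        ignored = (
            0 if n is None else sum(c * m for c, m in hist.items() if c > n)
        )
        return IndexStats(total, len(self.table), ignored, dict(hist))

    def contig_id(self, name: str) -> int:
        return self.contig_names.index(name)

    def check_reference(self, reference: List[Contig]) -> None:
        if reference_digest(reference) != self.reference_digest:
            raise ValueError(
                "reference digest mismatch: this index was built from a "
                "different FASTA"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MinimizerIndex):
            return NotImplemented
        return (
            self.params == other.params
            and self.reference_digest == other.reference_digest
            and self.contig_names == other.contig_names
            and self.contig_lengths == other.contig_lengths
            and self.provenance == other.provenance
            and self.n_added == other.n_added
            and self.table == other.table
        )


def build_index(reference: List[Contig], params: IndexParams) -> MinimizerIndex:
    """Index every minimizer of every contig of a reference."""
    if not reference:
        raise ValueError("reference must contain at least one contig")
    names = [c.name for c in reference]
    if len(set(names)) != len(names):
        raise ValueError("duplicate contig names in reference")
    table: Dict[int, List[Occurrence]] = {}
    for cid, contig in enumerate(reference):
        for m in compute_minimizers(contig, params, contig_id=cid):
            table.setdefault(m.hash, []).append((m.contig_id, m.pos, m.strand))
    for occs in table.values():
        occs.sort()
    return MinimizerIndex(
        params=params,
        reference_digest=reference_digest(reference),
        contig_names=tuple(names),
        contig_lengths=tuple(c.length for c in reference),
        table=table,
    )


def adjust_filter_threshold(
    plain_stats: IndexStats, modified_stats: IndexStats, plain_filter_n: int
) -> int:
    """Occurrence-filter threshold for a modified index.

    Adding variant minimizers changes the occurrence spectrum, so reusing
    the plain threshold would ignore a different fraction of seeds.  This
    returns the threshold for the modified index whose ignored-occurrence
    fraction is closest to the plain index's; exact equality is generally
    unattainable with discrete counts.  Ties prefer the threshold nearest
    the plain one.  Candidates never go below the plain threshold:
    augmentation only adds occurrences, so lowering the threshold would
    suppress seeds the plain index kept.  When the plain index ignores
    nothing, the plain threshold is returned unchanged.
    """
    if plain_stats.total_occurrences == 0 or modified_stats.total_occurrences == 0:
        raise ValueError("cannot adjust filter threshold for an empty index")
    target = plain_stats.ignored_fraction(plain_filter_n)
    if target == 0.0:
        return plain_filter_n
    max_count = max(modified_stats.count_histogram)
    best = None
    for t in range(plain_filter_n, max(max_count, plain_filter_n) + 1):
        diff = abs(modified_stats.ignored_fraction(t) - target)
        key = (diff, abs(t - plain_filter_n), t)
        if best is None or key < best[0]:
            best = (key, t)
    return best[1]


def save_index(index: MinimizerIndex, path: Union[str, Path]) -> None:
    """Write a deterministic, versioned canonical-JSON index file."""
    obj = {
        "magic": _FORMAT_MAGIC,
        "version": _FORMAT_VERSION,
        "params": {
            "k": index.params.k,
            "w": index.params.w,
            "hash_scheme": index.params.hash_scheme,
            "filter_n": index.params.filter_n,
        },
        "reference_digest": index.reference_digest,
        "contig_names": list(index.contig_names),
        "contig_lengths": list(index.contig_lengths),
        "provenance": index.provenance,
        "n_added": index.n_added,
        "table": {
            str(h): [list(o) for o in occs] for h, occs in index.table.items()
        },
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(obj, sort_keys=True, separators=(",", ":")))
        fh.write("\n")


def load_index(path: Union[str, Path]) -> MinimizerIndex:
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupt or truncated index file {path}: {exc}") from exc
    if not isinstance(obj, dict) or obj.get("magic") != _FORMAT_MAGIC:
        raise ValueError(f"{path} is not a varmin index file")
    if obj.get("version") != _FORMAT_VERSION:
        raise ValueError(
            f"unsupported index format version {obj.get('version')} "
            f"(expected {_FORMAT_VERSION})"
        )
    p = obj["params"]
    params = IndexParams(
        k=p["k"], w=p["w"], hash_scheme=p["hash_scheme"], filter_n=p["filter_n"]
    )
    table = {
        int(h): [tuple(o) for o in occs] for h, occs in obj["table"].items()
    }
    return MinimizerIndex(
        params=params,
        reference_digest=obj["reference_digest"],
        contig_names=tuple(obj["contig_names"]),
        contig_lengths=tuple(obj["contig_lengths"]),
        table=table,
        provenance=obj["provenance"],
        n_added=obj["n_added"],
    )
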