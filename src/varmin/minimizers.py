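"""Canonical k-mer hashing and sliding-window minimizer computation.

A *minimizer* is the k-mer with the smallest canonical hash among ``w``
consecutive k-mers of a sequence.  Sampling minimizers instead of every
k-mer keeps seed indexes small while guaranteeing that any sufficiently
long exact match between two sequences shares at least one seed (the
window-coverage property).  This module provides:

* 2-bit k-mer encoding (A=0, C=1, G=2, T=3, leftmost base most
  significant) and its inverse;
* canonical hashing: the k-mer and its reverse complement are hashed and
  the smaller value wins, together with the originating strand, so that a
  read and its reverse complement select the same seeds;
* vectorised winnowing over all windows of ``w`` consecutive valid
  k-mers, emitting every k-mer that achieves its window minimum (dense
  at ties, deduplicated by position).

Conventions
-----------
All coordinates are 0-based; a k-mer occupies ``[pos, pos + k)``.
k-mers containing an ambiguous base (anything outside ACGT) are invalid
and restart the window, as do palindromic (strand-symmetric) k-mers,
which have no defined strand; the latter can only occur for even ``k``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Tuple

import numpy as np

__all__ = [
    "FORWARD",
    "REVERSE",
    "AmbiguousBaseError",
    "Contig",
    "IndexParams",
    "Minimizer",
    "encode_kmer",
    "decode_kmer",
    "reverse_complement",
    "revcomp_code",
    "mix64",
    "canonical_hash",
    "compute_minimizers",
    "reference_digest",
]

FORWARD = 1
REVERSE = -1

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte -> 2-bit code; 4 marks an ambiguous base
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _BASE_CODE[ord(_c)] = _i

_U2 = np.uint64(2)
_U33 = np.uint64(33)
_MIX1 = np.uint64(0xFF51AFD7ED558CCD)
_MIX2 = np.uint64(0xC4CEB9FE1A85EC53)
_MASK64 = (1 << 64) - 1


class AmbiguousBaseError(ValueError):
    """Raised when a k-mer contains a base outside {A, C, G, T}."""


@dataclass(frozen=True)
class Contig:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("contig name must be non-empty")
        seq = self.sequence.upper()
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"contig {self.name!r}: invalid characters {bad}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IndexParams:
    """Winnowing parameters of a minimizer index.

    Parameters
    ----------
    k
        k-mer length, 3..31.  31 is a hard ceiling: 32 overflows a 2-bit
        packed 64-bit word.
    w
        window size in consecutive k-mers (>= 1).
    hash_scheme
        ``"invertible64"`` (default) mixes the 2-bit encoding through a
        64-bit invertible finalizer so hash order is pseudo-random;
        ``"lexicographic"`` uses the raw encoding, making hash order
        equal lexicographic order (useful for worked examples).
    filter_n
        occurrence-filter threshold: seeds whose hash occurs more than
        ``filter_n`` times in the index are ignored at query time.
        ``None`` disables filtering.
    """

    k: int = 21
    w: int = 11
    hash_scheme: str = "invertible64"
    filter_n: Optional[int] = None

    def __post_init__(self) -> None:
        if not (3 <= self.k <= 31):
            raise ValueError(f"k must be in [3, 31], got {self.k}")
        if self.w < 1:
            raise ValueError(f"w must be >= 1, got {self.w}")
        if self.hash_scheme not in ("invertible64", "lexicographic"):
            raise ValueError(f"unknown hash scheme {self.hash_scheme!r}")
        if self.filter_n is not None and self.filter_n < 1:
            raise ValueError("filter_n must be a positive integer or None")

    @property
    def window_span(self) -> int:
        """Length in bases of a full window of w consecutive k-mers."""
        return self.k + self.w - 1


class Minimizer(NamedTuple):
    """One selected k-mer occurrence."""

    hash: int
    contig_id: int
    pos: int
    strand: int  # FORWARD (+1) or REVERSE (-1)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_kmer(seq: str) -> int:
    """Encode an ACGT string as a base-4 integer (A=0..T=3, big-endian)."""
    code = 0
    for ch in seq:
        b = int(_BASE_CODE[ord(ch)])
        if b == 4:
            raise AmbiguousBaseError(f"ambiguous base {ch!r} in k-mer {seq!r}")
        code = (code << 2) | b
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer` for fixed k."""
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append("ACGT"[(code >> shift) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    """Encoding of the reverse complement of an encoded k-mer."""
    rc = 0
    for j in range(k):
        rc |= (3 - ((code >> (2 * (k - 1 - j))) & 3)) << (2 * j)
    # note: base at offset j (significance 4^(k-1-j)) complements to
    # offset k-1-j of the reverse complement (significance 4^j)
    return rc


def mix64(x: int) -> int:
    """64-bit invertible mix (the MurmurHash3 finalizer)."""
    x &= _MASK64
    x ^= x >> 33
    x = (x * 0xFF51AFD7ED558CCD) & _MASK64
    x ^= x >> 33
    x = (x * 0xC4CEB9FE1A85EC53) & _MASK64
    x ^= x >> 33
    return x


def canonical_hash(
    code: int, k: int, scheme: str = "invertible64"
) -> Optional[Tuple[int, int]]:
    """Canonical hash and strand of an encoded k-mer.

    Returns ``(hash, strand)`` where the hash is the smaller of the
    k-mer's and its reverse complement's hashes, or ``None`` for a
    palindromic (strand-symmetric) k-mer, which has no canonical strand
    and is skipped.
    """
    rc = revcomp_code(code, k)
    if scheme == "lexicographic":
        hf, hr = code, rc
    else:
        hf, hr = mix64(code), mix64(rc)
    if hf == hr:
        return None
    return (hf, FORWARD) if hf < hr else (hr, REVERSE)


def _mix64_arr(x: np.ndarray) -> np.ndarray:
    x = x.copy()
    x ^= x >> _U33
    x = x * _MIX1
    x ^= x >> _U33
    x = x * _MIX2
    x ^= x >> _U33
    return x


def _kmer_hashes(
    seq: str, k: int, scheme: str
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-start-position canonical hash, strand and validity arrays."""
    b = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(b)
    m = n - k + 1
    if m <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return empty, empty.astype(np.int8), np.empty(0, dtype=bool)
    bb = b.astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    valid = np.ones(m, dtype=bool)
    for j in range(k):
        col = bb[j : j + m]
        ok = col != 4
        valid &= ok
        safe = np.where(ok, col, 0)
        fwd = (fwd << _U2) | safe
        rev = rev | ((np.uint64(3) - safe) << np.uint64(2 * j))
    if scheme == "lexicographic":
        hf, hr = fwd, rev
    else:
        hf, hr = _mix64_arr(fwd), _mix64_arr(rev)
    # palindromes have no canonical strand: treat like invalid k-mers
    valid &= hf != hr
    strand = np.where(hf < hr, np.int8(FORWARD), np.int8(REVERSE))
    h = np.minimum(hf, hr)
    return h, strand, valid


def _winnow_run(h: np.ndarray, w: int) -> np.ndarray:
    """Indices within ``h`` selected by winnowing with window size w.

    A position is selected iff it achieves the minimum of at least one
    window of ``min(w, len(h))`` consecutive k-mers containing it.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    length = len(h)
    ww = min(w, length)
    wmin = sliding_window_view(h, ww).min(axis=1)
    if ww == 1:
        return np.arange(length)
    # m2[t] = max over windows containing t of that window's minimum;
    # t is selected iff h[t] equals it.  Zero-padding is neutral for max.
    pad = np.zeros(ww - 1, dtype=h.dtype)
    m2 = sliding_window_view(np.concatenate([pad, wmin, pad]), ww).max(axis=1)
    return np.nonzero(h == m2)[0]


def compute_minimizers(
    contig: Contig, params: IndexParams, contig_id: int = 0
) -> List[Minimizer]:
    """All minimizers of a contig, sorted by position.

    Every maximal run of consecutive valid k-mers is winnowed
    independently with window size ``min(w, run length)``; runs are
    broken by ambiguous bases (and palindromic k-mers, see module
    docstring).  Sequences shorter than ``k`` yield an empty list.
    """
    h, strand, valid = _kmer_hashes(contig.sequence, params.k, params.hash_scheme)
    out: List[Minimizer] = []
    m = len(h)
    i = 0
    while i < m:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < m and valid[j]:
            j += 1
        sel = _winnow_run(h[i:j], params.w)
        for s in sel:
            p = i + int(s)
            out.append(Minimizer(int(h[p]), contig_id, p, int(strand[p])))
        i = j
    return out


def reference_digest(reference: List[Contig]) -> str:
    """SHA-256 digest binding an index to the reference it was built from."""
    hasher = hashlib.sha256()
    for c in reference:
        hasher.update(f">{c.name}\n".encode())
        hasher.update(c.sequence.encode())
        hasher.update(b"\n")
    return hasher.hexdigest()
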