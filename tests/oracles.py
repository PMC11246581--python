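"""Independent reference implementations used only to check the package.

Everything here is deliberately naive and string-based: windows are
materialised explicitly, alignments are scored with a hand-rolled
dynamic program, chains are found by subset enumeration.  None of it
shares code with the package paths it validates.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_MASK = (1 << 64) - 1


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _mix(x: int) -> int:
    x &= _MASK
    x ^= x >> 33
    x = (x * 0xFF51AFD7ED558CCD) & _MASK
    x ^= x >> 33
    x = (x * 0xC4CEB9FE1A85EC53) & _MASK
    x ^= x >> 33
    return x


def _encode(s: str) -> int:
    v = 0
    for ch in s:
        v = v * 4 + _CODE[ch]
    return v


def _canonical(kmer: str, scheme: str) -> Optional[Tuple[int, int]]:
    rc = revcomp(kmer)
    if scheme == "lexicographic":
        hf, hr = _encode(kmer), _encode(rc)
    else:
        hf, hr = _mix(_encode(kmer)), _mix(_encode(rc))
    if hf == hr:
        return None
    return (hf, 1) if hf < hr else (hr, -1)


def naive_minimizers(
    seq: str, k: int, w: int, scheme: str = "invertible64"
) -> List[Tuple[int, int, int]]:
    """Window-enumeration winnowing oracle: (hash, pos, strand) sorted by pos.

    Valid k-mers are ACGT-only and non-palindromic; maximal runs of
    valid k-mers are winnowed independently with window size
    min(w, run length), emitting every arg-min of every window once.
    """
    n = len(seq)
    per_pos: List[Optional[Tuple[int, int]]] = []
    for p in range(max(0, n - k + 1)):
        kmer = seq[p : p + k]
        per_pos.append(_canonical(kmer, scheme) if set(kmer) <= set("ACGT") else None)
    selected: Dict[int, Tuple[int, int]] = {}
    run: List[int] = []

    def flush(run: List[int]) -> None:
        if not run:
            return
        ww = min(w, len(run))
        for s in range(len(run) - ww + 1):
            window = run[s : s + ww]
            lo = min(per_pos[p][0] for p in window)
            for p in window:
                if per_pos[p][0] == lo:
                    selected[p] = per_pos[p]

    for p, item in enumerate(per_pos):
        if item is None:
            flush(run)
            run = []
        else:
            run.append(p)
    flush(run)
    return [(h, p, s) for p, (h, s) in sorted(selected.items())]


def nw_affine(
    query: str,
    target: str,
    match: int = 2,
    mismatch: int = -4,
    gap_open: int = 6,
    gap_extend: int = 2,
) -> Tuple[int, str]:
    """Global affine-gap Needleman-Wunsch; gap of length L costs open+L*ext.

    Traceback prefers M, then D (gap in query / target consumed), then I,
    on equal score.  Returns (score, CIGAR over M/I/D).
    """
    n, m = len(query), len(target)
    NEG = float("-inf")
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (I: query consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (D: target consumed)
    H[0][0] = 0
    for i in range(1, n + 1):
        E[i][0] = -(gap_open + gap_extend * i)
        H[i][0] = E[i][0]
    for j in range(1, m + 1):
        F[0][j] = -(gap_open + gap_extend * j)
        H[0][j] = F[0][j]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                H[i - 1][j] - gap_open - gap_extend, E[i - 1][j] - gap_extend
            )
            F[i][j] = max(
                H[i][j - 1] - gap_open - gap_extend, F[i][j - 1] - gap_extend
            )
            diag = H[i - 1][j - 1] + (match if query[i - 1] == target[j - 1] else mismatch)
            H[i][j] = max(diag, E[i][j], F[i][j])
    # traceback from H[n][m], preferring M, then D, then I on ties
    ops: List[str] = []
    i, j, state = n, m, "H"
    while i > 0 or j > 0:
        if state == "H":
            diag = (
                H[i - 1][j - 1] + (match if query[i - 1] == target[j - 1] else mismatch)
                if i > 0 and j > 0
                else NEG
            )
            if i > 0 and j > 0 and H[i][j] == diag:
                ops.append("M")
                i, j = i - 1, j - 1
            elif j > 0 and H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            ops.append("D")
            came_open = j >= 1 and H[i][j - 1] - gap_open - gap_extend == F[i][j]
            came_ext = j >= 2 and F[i][j - 1] - gap_extend == F[i][j]
            j -= 1
            state = "H" if came_open or not came_ext else "F"
        else:  # E
            ops.append("I")
            came_open = i >= 1 and H[i - 1][j] - gap_open - gap_extend == E[i][j]
            came_ext = i >= 2 and E[i - 1][j] - gap_extend == E[i][j]
            i -= 1
            state = "H" if came_open or not came_ext else "E"
    ops.reverse()
    cigar = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1][1] += 1
        else:
            cigar.append([op, 1])
    return int(H[n][m]), "".join(f"{ln}{op}" for op, ln in cigar)


def brute_force_best_chain_score(
    anchors: Sequence[Tuple[int, int, int, int]],
    k: int,
    max_gap: int = 1000,
    gap_weight: float = 0.5,
) -> float:
    """Exhaustive best chain score over anchors (read_pos, cid, ref_pos, strand).

    A chain is any subset, ordered by position, strictly increasing in
    both coordinates within one (contig, strand), gaps bounded by
    max_gap; its score is k plus, per consecutive pair,
    min(k, dq, dr) - gap_weight*|dq - dr|.
    """
    best = 0.0 if not anchors else float(k)
    groups: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}
    for rp, cid, refp, strand in anchors:
        groups.setdefault((cid, strand), []).append((rp, refp))
    for grp in groups.values():
        grp.sort(key=lambda a: (a[1], a[0]))
        n = len(grp)
        for size in range(1, n + 1):
            for combo in combinations(range(n), size):
                ok = True
                score = float(k)
                for a, b in zip(combo, combo[1:]):
                    dq = grp[b][0] - grp[a][0]
                    dr = grp[b][1] - grp[a][1]
                    if dq <= 0 or dr <= 0 or dq > max_gap or dr > max_gap:
                        ok = False
                        break
                    score += min(k, dq, dr) - gap_weight * abs(dq - dr)
                if ok:
                    best = max(best, score)
    return best


def exhaustive_adjusted_threshold(
    plain_hist: Dict[int, int], modified_hist: Dict[int, int], plain_n: int
) -> int:
    """Exhaustive-scan oracle for the filter-ratio adjustment."""

    def frac(hist: Dict[int, int], t: int) -> float:
        total = sum(c * m for c, m in hist.items())
        return sum(c * m for c, m in hist.items() if c > t) / total

    target = frac(plain_hist, plain_n)
    if target == 0.0:
        return plain_n
    hi = max(max(modified_hist), plain_n)
    return min(
        range(plain_n, hi + 1),
        key=lambda t: (abs(frac(modified_hist, t) - target), abs(t - plain_n), t),
    )
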