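"""SD/anti-SD complementarity scanning and D_toStart.

The anti-SD sequence is the 3' tail of the mature 16S rRNA (5'->3', length
L).  A Shine-Dalgarno match is a maximal contiguous antiparallel
Watson-Crick duplex of length >= 4 between a gene's upstream window
(positions -W..-1, -1 abutting the start codon) and the tail.  Window
position p pairs tail position t_hi, p+1 pairs t_hi - 1, and so on.

D_toStart measures where the duplex places the ribosome: the number of mRNA
nucleotides from the projected position of the tail's 3'-terminal base to
the base immediately upstream of the start codon, inclusive,

    D_toStart = |p| + (L - t_hi).

Because the tail's 3' end is the physical reference point, different SD
motifs pairing different tail segments can share the same D_toStart; a gene
is SD-facilitated when some match places D_toStart inside the species'
optimal range.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._alphabet import encode, to_rna, validate_rna


@dataclass(frozen=True)
class SDMatch:
    """One maximal SD/anti-SD duplex.

    ``p..q`` is the window-side interval (negative positions, -1 abuts the
    start codon); ``t_lo..t_hi`` the tail-side interval (1-based, 5'->3').
    ``seq`` is the window-side (mRNA) sequence of the duplex.
    """

    gene_id: str
    p: int
    q: int
    t_lo: int
    t_hi: int
    match_len: int
    seq: str
    d_to_start: int


@dataclass(frozen=True)
class GeneSDClass:
    gene_id: str
    label: str  # "SD-facilitated" | "SD-independent"
    best_match: SDMatch | None
    optimal_range: tuple[int, int]


SD_FACILITATED = "SD-facilitated"
SD_INDEPENDENT = "SD-independent"


def compute_d_to_start(p: int, t_hi: int, tail_len: int) -> int:
    """D_toStart for a duplex whose 5'-most window base is at position p
    (negative) pairing tail position t_hi (1-based)."""
    return abs(p) + (tail_len - t_hi)


def find_sd_matches(
    window: str,
    tail: str,
    min_len: int = 4,
    gene_id: str = "",
    wobble: bool = False,
) -> list[SDMatch]:
    """Enumerate every maximal antiparallel complementary duplex >= min_len.

    All (window offset x tail offset) alignments are examined; a match is
    maximal when it cannot be extended on either side.  Pairs are strict
    Watson-Crick (A:U, G:C) unless ``wobble`` also admits G:U.
    """
    wseq = to_rna(window)
    tseq = to_rna(tail)
    validate_rna(wseq)
    validate_rna(tseq)
    W, L = len(wseq), len(tseq)
    if W < min_len or L < min_len:
        return []
    w = encode(wseq)
    t = encode(tseq)
    out: list[SDMatch] = []
    # Antiparallel duplexes run along anti-diagonals c = i + j of the
    # complementarity matrix (i: window index, j: tail index, both 0-based):
    # pairing (i, j) extends to (i+1, j-1), which preserves i + j.
    for c in range(W + L - 1):
        i_lo = max(0, c - L + 1)
        i_hi = min(W - 1, c)
        run_start = None
        for i in range(i_lo, i_hi + 2):
            ok = False
            if i <= i_hi:
                s = int(w[i]) + int(t[c - i])
                ok = s == 3 or (wobble and s == 5)
            if ok and run_start is None:
                run_start = i
            elif not ok and run_start is not None:
                length = i - run_start
                if length >= min_len:
                    ia, ib = run_start, i - 1
                    p, q = ia - W, ib - W
                    t_hi, t_lo = c - ia + 1, c - ib + 1
                    out.append(
                        SDMatch(
                            gene_id=gene_id,
                            p=p,
                            q=q,
                            t_lo=t_lo,
                            t_hi=t_hi,
                            match_len=length,
                            seq=wseq[ia : ib + 1],
                            d_to_start=compute_d_to_start(p, t_hi, L),
                        )
                    )
                run_start = None
    out.sort(key=lambda m: (m.p, m.t_hi))
    return out


def classify_gene(
    gene_id: str,
    matches: list[SDMatch],
    optimal_range: tuple[int, int],
) -> GeneSDClass:
    """SD-facilitated iff any match has D_toStart inside ``optimal_range``.

    The representative ``best_match`` is the in-range match of greatest
    length (tie -> smallest D_toStart); for SD-independent genes, the
    longest match overall, or None when the gene has no match at all.
    """
    lo, hi = optimal_range
    if lo > hi:
        raise ValueError("empty optimal_range")
    in_range = [m for m in matches if lo <= m.d_to_start <= hi]
    if in_range:
        best = min(in_range, key=lambda m: (-m.match_len, m.d_to_start))
        return GeneSDClass(gene_id, SD_FACILITATED, best, optimal_range)
    best = min(matches, key=lambda m: (-m.match_len, m.d_to_start)) if matches else None
    return GeneSDClass(gene_id, SD_INDEPENDENT, best, optimal_range)


def propose_optimal_range(d_values: list[int], mass: float = 0.6) -> tuple[int, int]:
    """Shortest contiguous integer interval holding >= ``mass`` of the values.

    A helper for eyeballing where the D_toStart peak sits; classification
    always uses an explicitly configured range.  Ties go to the interval
    with the smaller left end.
    """
    if not d_values:
        raise ValueError("d_values is empty")
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    v = sorted(d_values)
    n = len(v)
    m = math.ceil(mass * n)
    best = None
    for i in range(n - m + 1):
        lo, hi = v[i], v[i + m - 1]
        width = hi - lo
        if best is None or width < best[0] or (width == best[0] and lo < best[1]):
            best = (width, lo, hi)
    return best[1], best[2]


def motif_usage(
    matches: list[SDMatch],
    optimal_range: tuple[int, int] | None = None,
) -> pd.Series:
    """Relative frequency of each distinct matched SD (window-side) string.

    With ``optimal_range`` given, only matches whose D_toStart falls inside
    it are tabulated (SD usage at optimal spacing); proportions sum to 1.
    """
    if optimal_range is not None:
        lo, hi = optimal_range
        matches = [m for m in matches if lo <= m.d_to_start <= hi]
    counts = Counter(m.seq for m in matches)
    if not counts:
        return pd.Series(dtype=float, name="proportion")
    total = sum(counts.values())
    ser = pd.Series({k: v / total for k, v in counts.items()}, name="proportion")
    return ser.sort_values(ascending=False)


def scan_genes(
    windows,
    tail: str,
    min_len: int = 4,
    wobble: bool = False,
) -> dict[str, list[SDMatch]]:
    """find_sd_matches over a collection of UpstreamWindow objects."""
    return {
        w.gene_id: find_sd_matches(w.seq, tail, min_len=min_len, gene_id=w.gene_id, wobble=wobble)
        for w in windows
    }


def matches_to_tsv(matches: list[SDMatch], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tp\tq\tt_lo\tt_hi\tmatch_len\tmatch_seq\td_to_start\n")
        for m in matches:
            fh.write(
                f"{m.gene_id}\t{m.p}\t{m.q}\t{m.t_lo}\t{m.t_hi}\t"
                f"{m.match_len}\t{m.seq}\t{m.d_to_start}\n"
            )


def classes_to_tsv(classes: list[GeneSDClass], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlabel\tbest_match_seq\tbest_d_to_start\n")
        for c in classes:
            seq = c.best_match.seq if c.best_match else ""
            d = c.best_match.d_to_start if c.best_match else ""
            fh.write(f"{c.gene_id}\t{c.label}\t{seq}\t{d}\n")


# ---------------------------------------------------------------------------
# Vectorized batch path (used by the shuffle-based null of anti_sd_preference
# and by large simulation experiments; must agree exactly with
# find_sd_matches -- see tests).


def site_coverage_batch(
    windows: np.ndarray, tail: np.ndarray, min_len: int = 4
) -> np.ndarray:
    """Per-window tail-site coverage counts from maximal duplexes >= min_len.

    ``windows`` is an (N, W) int8 array of encoded window sequences, ``tail``
    an (L,) int8 array.  Returns an (N, L) int32 array whose [n, j] entry is
    the number of maximal matches of window n that pair tail site j+1
    (a site paired by two distinct maximal matches counts twice, matching
    tabulate_observed_usage on find_sd_matches output).
    """
    windows = np.ascontiguousarray(windows, dtype=np.int8)
    tail = np.asarray(tail, dtype=np.int8)
    N, W = windows.shape
    L = tail.shape[0]
    diff = np.zeros((N, L + 1), dtype=np.int32)
    for c in range(W + L - 1):
        i_lo = max(0, c - L + 1)
        i_hi = min(W - 1, c)
        idx = np.arange(i_lo, i_hi + 1)
        if idx.size < min_len:
            continue
        B = (windows[:, idx] + tail[c - idx]) == 3  # (N, m)
        m = idx.size
        run = np.zeros(N, dtype=np.int16)
        for k in range(m):
            run = np.where(B[:, k], run + 1, 0)
            is_end = B[:, k] & ((k == m - 1) | ~B[:, min(k + 1, m - 1)]) if m > 1 else B[:, k]
            hit = is_end & (run >= min_len)
            if hit.any():
                rows = np.nonzero(hit)[0]
                r = run[rows].astype(np.int32)
                i_b = idx[k]
                j_lo = c - i_b          # 0-based tail index of 3'-most... (lowest index)
                j_hi = j_lo + r - 1     # varies per row
                diff[rows, j_lo] += 1
                diff[rows, j_hi + 1] -= 1
    return np.cumsum(diff[:, :L], axis=1)
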