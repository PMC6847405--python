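"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive every quantity from first principles
(exhaustive enumeration over offsets / permutations / rank assignments) so
they share no code path with the implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from sdscan._alphabet import to_rna

TAIL_S_SP = "GAUCACCUCCUUU"  # Synechocystis-style anti-SD tail

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def brute_force_matches(window: str, tail: str, min_len: int = 4):
    """All maximal antiparallel WC duplexes, by exhaustive offset scan.

    Returns a set of (p, q, t_lo, t_hi) tuples.  A duplex pairs window
    position p + k with tail position t_hi - k; maximality is checked by
    attempting to extend one step on each side.
    """
    w = to_rna(window)
    t = to_rna(tail)
    W, L = len(w), len(t)

    def paired(i: int, j: int) -> bool:  # i: 0-based window, j: 0-based tail
        if not (0 <= i < W and 0 <= j < L):
            return False
        return _COMP[w[i]] == t[j]

    out = set()
    for i0 in range(W):          # window start (0-based)
        for j0 in range(L):      # tail index paired with window start (t_hi-1)
            for length in range(min_len, min(W - i0, j0 + 1) + 1):
                if all(paired(i0 + k, j0 - k) for k in range(length)):
                    left_ext = paired(i0 - 1, j0 + 1)
                    right_ext = paired(i0 + length, j0 - length)
                    if not left_ext and not right_ext:
                        p = i0 - W
                        q = p + length - 1
                        t_hi = j0 + 1
                        t_lo = t_hi - length + 1
                        out.add((p, q, t_lo, t_hi))
    return out


def brute_force_tail_candidates(counts, query_seq, core_offset, k_downstream=5,
                                proximity_nt=4):
    """All termini satisfying both identification criteria, by direct check."""
    import re

    m = re.search("GATCACCTCCTT[TA]", query_seq)
    assert m is not None
    mstart, mend = m.span()
    core_end = core_offset + 4
    out = []
    for t in range(len(counts)):
        tail = query_seq[mstart : t + 1]
        in_window = mstart <= t <= mend - 1 + proximity_nt
        has_core = "CCTCC" in tail
        if not (in_window and has_core and counts[t] > 0):
            continue
        ds = sum(counts[t + 1 : t + 1 + k_downstream])
        if counts[t] > ds:
            out.append((t, int(counts[t])))
    return out


def exhaustive_interval(values, mass):
    """Shortest integer interval with >= mass of values; ties -> smaller lo."""
    import math

    need = math.ceil(mass * len(values))
    best = None
    for lo in range(min(values), max(values) + 1):
        for hi in range(lo, max(values) + 1):
            if sum(lo <= v <= hi for v in values) >= need:
                cand = (hi - lo, lo, hi)
                if best is None or cand < best:
                    best = cand
                break  # wider hi only grows the width
    return best[1], best[2]


def exact_rank_sum_pvalue(a, b):
    """Two-sided rank-sum p via U-statistic pair counting over all group
    assignments of the pooled values (independent of rank-based code)."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(group):
        other = [pooled[i] for i in range(len(pooled)) if i not in group]
        mine = [pooled[i] for i in group]
        u = 0.0
        for x in mine:
            for y in other:
                u += (x > y) + 0.5 * (x == y)
        return u

    mu = n1 * (len(pooled) - n1) / 2
    d_obs = abs(u_stat(tuple(range(n1))) - mu)
    total = extreme = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(combo) - mu) >= d_obs - 1e-9:
            extreme += 1
    return extreme / total


def pair_count_tau_b(x, y):
    """Kendall tau-b by O(n^2) pair enumeration with tie corrections."""
    n = len(x)
    C = D = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[j] - x[i])
            dy = np.sign(y[j] - y[i])
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                C += 1
            else:
                D += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (C - D) / denom if denom > 0 else float("nan")


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    """Small three-gene genome written as GenBank and FASTA+GFF3.

    geneA: + strand, geneB: - strand, geneC: + strand pseudo; circular.
    """
    from sdscan.genome_io import Genome, GeneRecord, Replicon
    from sdscan.synthetic import write_genome_genbank, write_genome_fasta_gff

    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    # plant a recognizable context upstream of geneA's start codon (pos 50)
    seq = seq[:37] + "TTAGGAGGTTTTT" + "ATGGCTGCTTAA" + seq[62:]
    genome = Genome()
    genome.replicons["toy"] = Replicon("toy", seq, circular=True)
    genome.genes = [
        GeneRecord("geneA", "toy", "+", 51, 12, False, 50, 62),
        GeneRecord("geneB", "toy", "-", len(seq) - 120 + 1, 12, False, 108, 120),
        GeneRecord("geneC", "toy", "+", 151, 12, True, 150, 162),
    ]
    d = tmp_path_factory.mktemp("toy_genome")
    gb = d / "toy.gbk"
    fa = d / "toy.fa"
    gff = d / "toy.gff"
    write_genome_genbank(genome, str(gb))
    write_genome_fasta_gff(genome, str(fa), str(gff))
    return {"genome": genome, "seq": seq, "gbk": str(gb), "fasta": str(fa), "gff": str(gff)}


@pytest.fixture(scope="session")
def sim_reads_bundle():
    """One simulated 16S read set with a planted terminus."""
    from sdscan.synthetic import make_rdna, simulate_16s_reads

    rdna, terminus = make_rdna(seed=11)
    reads, truth = simulate_16s_reads(rdna, terminus, depth=1000, seed=11)
    return {"rdna": rdna, "terminus": terminus, "reads": reads, "truth": truth}
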