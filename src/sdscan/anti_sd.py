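"""Observed vs expected anti-SD site usage and the site-preference Z-test.

Each SD/anti-SD duplex "uses" the tail sites it pairs.  Summing over all
maximal matches from all non-pseudo genes gives observed per-site counts
O_i.  The null expectation E_i comes from re-scanning composition-preserving
shuffles of the upstream windows (mononucleotide permutation within each
window), rescaled so that sum(E) = n = sum(O).  With p_i = O_i / n and
phat_i = E_i / n, the central-limit Z-score

    Z_i = (p_i - phat_i) / sqrt(phat_i (1 - phat_i) / n)

is tested upper-tailed: a site is a preferred anti-SD site when
Z_i >= z_crit (1.645, i.e. P < 0.05 one-sided).  The preferred anti-SD
motif is the longest contiguous run of significant sites read 5'->3'.

An analytic alternative null treats each window as i.i.d. draws from its
own base composition; it avoids Monte-Carlo noise but ignores the
without-replacement structure of a permutation, so shuffling is the
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._alphabet import encode, to_rna
from .sd_scanner import SDMatch, find_sd_matches, site_coverage_batch


class UndefinedExpectationError(ValueError):
    """No observed usage at all -- O:E statistics are undefined."""


@dataclass
class AntiSDUsage:
    """Per-site usage table for one tail/gene-set combination."""

    tail: str
    O: np.ndarray
    E: np.ndarray
    n: int
    p: np.ndarray
    p_hat: np.ndarray
    z: np.ndarray
    significant: np.ndarray
    testable: np.ndarray
    z_crit: float
    preferred_motif: str

    def to_frame(self) -> pd.DataFrame:
        oe = np.divide(self.O, self.E, out=np.full_like(self.E, np.nan), where=self.E > 0)
        return pd.DataFrame(
            {
                "site": np.arange(1, len(self.tail) + 1),
                "base": list(self.tail),
                "O": self.O,
                "E": self.E,
                "OE_ratio": oe,
                "Z": self.z,
                "significant": self.significant,
            }
        )


def tabulate_observed_usage(matches: list[SDMatch], tail_len: int) -> np.ndarray:
    """O_i: how many matches pair tail site i (every site of every match)."""
    O = np.zeros(tail_len, dtype=np.int64)
    for m in matches:
        O[m.t_lo - 1 : m.t_hi] += 1
    return O


def _shuffle_coverage(
    enc_windows: np.ndarray, tail_enc: np.ndarray, n_shuffles: int,
    rng: np.random.Generator, min_len: int, chunk: int = 200_000,
) -> np.ndarray:
    """Mean per-site coverage (summed over windows) across shuffle replicates."""
    N, W = enc_windows.shape
    L = tail_enc.shape[0]
    total = np.zeros(L, dtype=np.float64)
    rows_per_rep = N
    reps_per_chunk = max(1, chunk // max(rows_per_rep, 1))
    done = 0
    while done < n_shuffles:
        reps = min(reps_per_chunk, n_shuffles - done)
        tiled = np.tile(enc_windows, (reps, 1))
        perm = np.argsort(rng.random(tiled.shape), axis=1)
        shuffled = np.take_along_axis(tiled, perm, axis=1)
        cov = site_coverage_batch(shuffled, tail_enc, min_len=min_len)
        total += cov.sum(axis=0)
        done += reps
    return total / n_shuffles


def estimate_expected_usage(
    windows,
    tail: str,
    n_shuffles: int = 1000,
    seed: int | None = None,
    min_len: int = 4,
    rescale_to: float | None = None,
    rescale: bool = True,
) -> np.ndarray:
    """E_i under per-window mononucleotide shuffling.

    ``windows`` is a list of UpstreamWindow objects or plain sequences.  The
    mean per-site coverage over ``n_shuffles`` replicates is rescaled so
    that sum(E) equals ``rescale_to`` (default: the observed n from the same
    windows), matching phat_i = E_i / n.  Deterministic given ``seed``.
    """
    seqs = [to_rna(getattr(w, "seq", w)) for w in windows]
    if not seqs:
        raise ValueError("no windows supplied")
    tail_enc = encode(to_rna(tail))
    L = tail_enc.shape[0]
    width = max(len(s) for s in seqs)
    if len({len(s) for s in seqs}) != 1:
        # pad shorter (truncated) windows on the 5' side with A -- they are
        # shuffled per-window anyway, and composition is what matters; to
        # keep composition exact we shuffle ragged windows individually.
        raise ValueError("windows must share a length; scan ragged sets separately")
    enc_windows = np.stack([encode(s) for s in seqs])
    if rescale_to is None:
        obs = site_coverage_batch(enc_windows, tail_enc, min_len=min_len).sum(axis=0)
        rescale_to = float(obs.sum())
    if rescale and rescale_to == 0:
        raise UndefinedExpectationError(
            "observed usage is zero for this gene set; O:E is undefined"
        )
    rng = np.random.default_rng(seed)
    mean_cov = _shuffle_coverage(enc_windows, tail_enc, n_shuffles, rng, min_len)
    if not rescale:
        return mean_cov
    s = mean_cov.sum()
    if s == 0:
        raise UndefinedExpectationError(
            "no match possible under any permutation of these windows"
        )
    return mean_cov * (rescale_to / s)


def analytic_expected_usage(
    windows, tail: str, min_len: int = 4, rescale_to: float | None = None
) -> np.ndarray:
    """Composition-based analytic E_i (i.i.d. approximation to shuffling).

    For each window, bases are modelled as i.i.d. draws from the window's
    own composition; along each anti-diagonal the per-cell pairing
    probabilities are independent, so the probability that a cell belongs
    to a maximal run of length >= min_len has a closed form evaluated by
    summing over run intervals.
    """
    seqs = [to_rna(getattr(w, "seq", w)) for w in windows]
    tail_enc = encode(to_rna(tail))
    L = tail_enc.shape[0]
    E = np.zeros(L, dtype=np.float64)
    for s in seqs:
        w_enc = encode(s)
        W = len(w_enc)
        comp = np.bincount(w_enc, minlength=4) / max(W, 1)
        # probability a window base pairs tail base t: freq of complement
        p_pair = comp[3 - tail_enc]  # (L,)
        for c in range(W + L - 1):
            i_lo = max(0, c - L + 1)
            i_hi = min(W - 1, c)
            m = i_hi - i_lo + 1
            if m < min_len:
                continue
            cell_p = np.array([p_pair[c - i] for i in range(i_lo, i_hi + 1)])
            # P(cells a..b all pair, flanks fail); accumulate coverage per cell
            for a in range(m):
                prod = 1.0
                for b in range(a, m):
                    prod *= cell_p[b]
                    if b - a + 1 < min_len:
                        continue
                    pr = prod
                    if a > 0:
                        pr *= 1 - cell_p[a - 1]
                    if b < m - 1:
                        pr *= 1 - cell_p[b + 1]
                    for k in range(a, b + 1):
                        j = c - (i_lo + k)
                        E[j] += pr
    if rescale_to is not None:
        s = E.sum()
        if s == 0:
            raise UndefinedExpectationError("zero analytic expectation")
        E = E * (rescale_to / s)
    return E


def z_test_sites(
    O: np.ndarray,
    E: np.ndarray,
    tail: str,
    z_crit: float = 1.645,
) -> AntiSDUsage:
    """Upper-tailed CLT test of p_i > phat_i at every tail site.

    Sites with E_i = 0 but O_i > 0 are flagged untestable and never enter
    the preferred motif.  Significance is >= z_crit exactly (ties count).
    """
    O = np.asarray(O, dtype=np.float64)
    E = np.asarray(E, dtype=np.float64)
    tail = to_rna(tail)
    n = O.sum()
    if n <= 0:
        raise UndefinedExpectationError("sum(O) must be positive")
    p = O / n
    p_hat = E / n
    testable = E > 0
    z = np.zeros_like(O)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(p_hat * (1 - p_hat) / n)
        z = np.where(testable & (denom > 0), (p - p_hat) / denom, 0.0)
    significant = testable & (z >= z_crit)
    motif = _longest_significant_run(significant, tail)
    return AntiSDUsage(
        tail=tail, O=O, E=E, n=int(round(n)), p=p, p_hat=p_hat, z=z,
        significant=significant, testable=testable, z_crit=z_crit,
        preferred_motif=motif,
    )


def _longest_significant_run(significant: np.ndarray, tail: str) -> str:
    """Longest contiguous run of significant sites; ties -> most 3' run."""
    best = (0, -1)  # (length, start)
    run_start = None
    for i in range(len(significant) + 1):
        on = i < len(significant) and significant[i]
        if on and run_start is None:
            run_start = i
        elif not on and run_start is not None:
            length = i - run_start
            if length >= best[0]:  # >= keeps the most 3' among ties
                best = (length, run_start)
            run_start = None
    if best[0] == 0:
        return ""
    return tail[best[1] : best[1] + best[0]]


def usage_analysis(
    windows,
    tail: str,
    matches: list[SDMatch] | None = None,
    n_shuffles: int = 1000,
    seed: int | None = None,
    min_len: int = 4,
    z_crit: float = 1.645,
) -> AntiSDUsage:
    """Convenience wrapper: tabulate O, estimate E by shuffling, run the test."""
    tail = to_rna(tail)
    if matches is None:
        matches = []
        for w in windows:
            matches.extend(
                find_sd_matches(getattr(w, "seq", w), tail, min_len=min_len,
                                gene_id=getattr(w, "gene_id", ""))
            )
    O = tabulate_observed_usage(matches, len(tail))
    E = estimate_expected_usage(
        windows, tail, n_shuffles=n_shuffles, seed=seed, min_len=min_len,
        rescale_to=float(O.sum()),
    )
    return z_test_sites(O, E, tail, z_crit=z_crit)
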