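"""Expression metrics and group contrasts.

FPKM normalizes a gene's fragment count by transcript length (kb) and
library size (millions of mapped fragments):

    FPKM = count * 1e9 / (gene_len_nt * total_mapped)

Replicate FPKMs are averaged within a BioProject (arithmetic mean), and
translation efficiency is summarized as protein per transcript =
protein abundance / mean FPKM (undefined, and excluded from contrasts,
when the mean FPKM is zero).

Group contrasts between SD-facilitated and SD-independent genes use the
Wilcoxon rank-sum test with midranks, tie-corrected variance and a 0.5
continuity correction (exact enumeration over rank assignments when both
groups are small), and ordinal association uses Kendall's tau-b with
tie adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sd_scanner import SD_FACILITATED, SD_INDEPENDENT


@dataclass
class GeneExpressionRecord:
    gene_id: str
    protein_abundance: float
    protein_unit: str
    fpkm_by_project: dict[str, float]
    protein_per_transcript: dict[str, float | None]
    label: str | None = None


@dataclass
class GroupContrast:
    metric: str
    n_facilitated: int
    n_independent: int
    median_facilitated: float
    median_independent: float
    statistic: float
    p_value: float


def compute_fpkm(count: float, gene_len_nt: int, total_mapped: int) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if gene_len_nt <= 0:
        raise ValueError("gene_len_nt must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count * 1e9 / (gene_len_nt * total_mapped)


def protein_per_transcript(protein: float, mean_fpkm: float) -> float | None:
    """protein abundance / mean FPKM; None (excluded) when mean FPKM is 0."""
    if protein < 0:
        raise ValueError("protein abundance must be non-negative")
    if mean_fpkm > 0:
        return protein / mean_fpkm
    return None  # flagged exclusion, never infinity


def fpkm_table(counts: pd.DataFrame, gene_lengths: dict[str, int]) -> pd.DataFrame:
    """Per-replicate FPKM from a count table.

    ``counts`` columns: gene_id, project, replicate, count.  Library size is
    the within-replicate total count.
    """
    df = counts.copy()
    df["total"] = df.groupby(["project", "replicate"])["count"].transform("sum")
    df["length"] = df["gene_id"].map(gene_lengths)
    df["fpkm"] = df["count"] * 1e9 / (df["length"] * df["total"])
    return df


def mean_fpkm_by_project(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean FPKM across replicates within each project."""
    return (
        fpkm.groupby(["gene_id", "project"])["fpkm"].mean().rename("mean_fpkm").reset_index()
    )


def build_expression_records(
    proteins: pd.DataFrame,
    counts: pd.DataFrame,
    gene_lengths: dict[str, int],
    labels: dict[str, str] | None = None,
) -> list[GeneExpressionRecord]:
    """Join protein abundances with per-project mean FPKM.

    ``proteins`` columns: gene_id, abundance[, unit].
    """
    mean_fpkm = mean_fpkm_by_project(fpkm_table(counts, gene_lengths))
    by_gene: dict[str, dict[str, float]] = {}
    for row in mean_fpkm.itertuples():
        by_gene.setdefault(row.gene_id, {})[row.project] = row.mean_fpkm
    records = []
    unit_col = "unit" in proteins.columns
    for row in proteins.itertuples():
        fbp = by_gene.get(row.gene_id, {})
        records.append(
            GeneExpressionRecord(
                gene_id=row.gene_id,
                protein_abundance=float(row.abundance),
                protein_unit=getattr(row, "unit", "ppm") if unit_col else "ppm",
                fpkm_by_project=fbp,
                protein_per_transcript={
                    proj: protein_per_transcript(float(row.abundance), fpkm)
                    for proj, fpkm in fbp.items()
                },
                label=(labels or {}).get(row.gene_id),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Tests of group differences / association


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by enumerating all group assignments of the
    pooled midranks (valid with ties)."""
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    n1, n = len(a), len(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2
    d_obs = abs(w_obs - mu)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= d_obs - 1e-9:
            extreme += 1
    return w_obs, extreme / total


def wilcoxon_rank_sum(
    a, b, continuity: bool = True, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of ``a``, p).

    ``method='auto'`` enumerates exactly when both groups have <= 10
    observations and otherwise uses the normal approximation with midranks,
    tie-corrected variance and 0.5 continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    ranks = _midranks(np.concatenate([a, b]))
    w = float(ranks[: len(a)].sum())
    if np.unique(np.concatenate([a, b])).size == 1:
        return w, 1.0  # every value identical across both groups
    if method == "exact" or (method == "auto" and len(a) <= 10 and len(b) <= 10):
        return _exact_rank_sum_p(a, b)
    _, p = stats.mannwhitneyu(
        a, b, use_continuity=continuity, alternative="two-sided", method="asymptotic"
    )
    return w, float(p)


def kendall_tau_b(x, y) -> tuple[float, float]:
    """Kendall's tau-b with tie adjustment; returns (tau_b, two-sided p).

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)); NaN when either vector is
    entirely tied (association undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan"), float("nan")
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic), float(res.pvalue)


def contrast_groups(
    records: list[GeneExpressionRecord],
    metric: str,
    project: str | None = None,
    values: dict[str, float] | None = None,
) -> GroupContrast:
    """Wilcoxon contrast of a metric between SD-facilitated and
    SD-independent genes with protein abundance > 0.

    ``metric`` is one of ``protein_abundance``, ``protein_per_transcript``
    (requires ``project``) or an arbitrary name when per-gene ``values``
    are supplied (e.g. MFE).
    """
    groups: dict[str, list[float]] = {SD_FACILITATED: [], SD_INDEPENDENT: []}
    for rec in records:
        if rec.label not in groups or rec.protein_abundance <= 0:
            continue
        if values is not None:
            v = values.get(rec.gene_id)
        elif metric == "protein_abundance":
            v = rec.protein_abundance
        elif metric == "protein_per_transcript":
            if project is None:
                raise ValueError("protein_per_transcript contrast needs a project")
            v = rec.protein_per_transcript.get(project)
        else:
            raise ValueError(f"unknown metric {metric!r} without explicit values")
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        groups[rec.label].append(float(v))
    fac, ind = groups[SD_FACILITATED], groups[SD_INDEPENDENT]
    if not fac or not ind:
        empty = SD_FACILITATED if not fac else SD_INDEPENDENT
        raise ValueError(
            f"no {empty} genes left for metric {metric!r} after the "
            "protein-abundance>0 / defined-value filter"
        )
    w, p = wilcoxon_rank_sum(fac, ind)
    return GroupContrast(
        metric=metric,
        n_facilitated=len(fac),
        n_independent=len(ind),
        median_facilitated=float(np.median(fac)),
        median_independent=float(np.median(ind)),
        statistic=w,
        p_value=p,
    )
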