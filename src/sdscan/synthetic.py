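"""Synthetic datasets with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes:

* ``simulate_16s_reads`` -- reads from a 16S rDNA whose mature 3' terminus
  is planted: a dominant fraction of read 3' ends sit exactly at the
  terminus, a precursor-like fraction decays geometrically downstream, and
  a degradation-like fraction is uniform upstream (the pileup shape the
  tail caller is built for).
* ``simulate_genome`` -- an annotated genome whose genes carry SD motifs
  planted at controlled D_toStart (rejection sampling guarantees the
  planted duplex is each window's unique longest match).
* ``simulate_expression`` -- protein-abundance and read-count tables with
  a multiplicative protein effect for SD-facilitated genes.

One global seed expands into independent per-stage streams via a stable
label-hash splitting rule, so any stage can be regenerated alone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._alphabet import revcomp_dna, to_dna, to_rna
from .genome_io import Genome, GeneRecord, Replicon
from .sd_scanner import find_sd_matches

_BASES = np.array(list("ACGT"))


def stage_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-stage random stream derived from one global seed."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(label.encode())])


@dataclass
class SimTruth:
    seed: int
    planted_terminus: int | None = None
    planted_sd_per_gene: dict[str, tuple[str, int] | None] = field(default_factory=dict)
    planted_effect: float | None = None


# ---------------------------------------------------------------------------
# 16S reads


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def make_rdna(
    length: int = 1500,
    tail_motif: str = "GATCACCTCCTTT",
    terminus: int | None = None,
    gc: float = 0.5,
    seed: int = 0,
) -> tuple[str, int]:
    """A toy 16S rDNA with a single CCTCC core; returns (seq, terminus).

    ``terminus`` is the 0-based position of the mature 3'-terminal base,
    i.e. the last base of ``tail_motif`` (default: 100 nt before the 3'
    end, leaving downstream sequence for precursor reads).
    """
    rng = stage_rng(seed, "rdna")
    if terminus is None:
        terminus = length - 101
    motif = to_dna(tail_motif)
    start = terminus - len(motif) + 1
    if start < 0 or terminus >= length:
        raise ValueError("terminus does not fit in the sequence")
    for _ in range(1000):
        seq = _random_dna(rng, length, gc)
        seq = seq[:start] + motif + seq[start + len(motif):]
        if seq.count("CCTCC") == 1:
            return seq, terminus
    raise RuntimeError("could not build an rDNA with a unique CCTCC core")


@dataclass
class ReadNoise:
    """End-position noise around the planted terminus."""

    signal_frac: float = 0.6
    upstream_uniform_frac: float = 0.3
    downstream_geometric_p: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.signal_frac + self.upstream_uniform_frac <= 1:
            raise ValueError("fractions must sum to <= 1")


def simulate_16s_reads(
    rdna: str,
    terminus: int,
    depth: int = 1000,
    noise: ReadNoise | None = None,
    read_len: int = 50,
    seed: int = 0,
) -> tuple[list[tuple[str, int]], SimTruth]:
    """Reads (aggregated as (sequence, multiplicity)) with a planted 3' end.

    Every read is an exact ``read_len`` substring of ``rdna`` ending at its
    assigned 3' position.  Deterministic given ``seed``.
    """
    noise = noise or ReadNoise()
    if depth <= 0:
        raise ValueError("depth must be positive")
    if terminus < read_len - 1:
        raise ValueError("terminus closer than read_len to the sequence start")
    if terminus >= len(rdna):
        raise ValueError("terminus outside the sequence")
    rng = stage_rng(seed, "reads")
    n_sig = int(round(noise.signal_frac * depth))
    n_up = int(round(noise.upstream_uniform_frac * depth))
    n_down = depth - n_sig - n_up
    ends = [np.full(n_sig, terminus, dtype=np.int64)]
    if n_up:
        ends.append(rng.integers(read_len - 1, terminus, size=n_up))
    if n_down:
        offs = rng.geometric(noise.downstream_geometric_p, size=n_down)
        ends.append(np.minimum(terminus + offs, len(rdna) - 1))
    all_ends = np.concatenate(ends)
    agg: dict[str, int] = {}
    for e in all_ends:
        seq = rdna[e - read_len + 1 : e + 1]
        agg[seq] = agg.get(seq, 0) + 1
    reads = sorted(agg.items())
    return reads, SimTruth(seed=seed, planted_terminus=terminus)


def write_fasta_plus(reads: list[tuple[str, int]], path: str, prefix: str = "read") -> None:
    """Write collapsed reads in FASTA+ convention (``>SeqID_count``)."""
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(reads):
            fh.write(f">{prefix}{i}_{count}\n{seq}\n")


# ---------------------------------------------------------------------------
# Genomes with planted SDs


def _feasible_placements(d: int, length: int, tail_len: int, window_len: int):
    """(p, t_hi) placements of an ``length``-nt duplex with D_toStart == d."""
    out = []
    for t_hi in range(length, tail_len + 1):
        p = -(d - (tail_len - t_hi))
        if -window_len <= p and p + length - 1 <= -1:
            out.append((p, t_hi))
    return out


def _plant_window(
    rng: np.random.Generator,
    tail_rna: str,
    d: int,
    window_len: int,
    gc: float,
    min_len: int = 4,
    max_len: int | None = None,
    retries: int = 500,
) -> tuple[str, str, int]:
    """A window whose unique longest match is a planted duplex at D = d.

    Returns (window_dna, motif_rna, match_len).  Rejection sampling redraws
    the background until the planted match is strictly the longest match
    and reports exactly the planted D_toStart.
    """
    L = len(tail_rna)
    max_len = min(max_len or 8, L)
    lengths = list(range(min_len, max_len + 1))
    rng.shuffle(lengths)
    for length in lengths:
        placements = _feasible_placements(d, length, L, window_len)
        if not placements:
            continue
        p, t_hi = placements[rng.integers(len(placements))]
        t_lo = t_hi - length + 1
        motif_rna = revcomp_dna(to_dna(tail_rna[t_lo - 1 : t_hi]))
        motif_rna = to_rna(motif_rna)  # window-side SD motif, RNA
        i0 = window_len + p  # 0-based index of motif start in window
        for _ in range(retries):
            win = list(_random_dna(rng, window_len, gc))
            win[i0 : i0 + length] = to_dna(motif_rna)
            window = "".join(win)
            matches = find_sd_matches(window, tail_rna, min_len=min_len)
            longest = sorted(matches, key=lambda m: -m.match_len)
            if not longest:
                continue
            top = longest[0]
            unique_top = len(longest) == 1 or longest[1].match_len < top.match_len
            if (
                unique_top
                and top.match_len == length
                and top.p == p
                and top.t_hi == t_hi
                and top.d_to_start == d
            ):
                return window, motif_rna, length
    raise RuntimeError(f"could not plant an SD at D_toStart={d}")


def simulate_genome(
    n_genes: int = 500,
    sd_fraction: float = 0.6,
    d_sampler=None,
    tail: str = "GAUCACCUCCUUU",
    gc: float = 0.5,
    seed: int = 0,
    window_len: int = 30,
    pseudo_fraction: float = 0.0,
    minus_strand_fraction: float = 0.3,
    replicon_id: str = "simchrom",
    circular: bool = True,
) -> tuple[Genome, SimTruth]:
    """An annotated genome whose genes carry SDs at controlled D_toStart.

    ``d_sampler(rng)`` draws one spacing per planted gene (default: uniform
    on the canonical optimal band 11..21).  The truth table records the
    planted (motif, D_toStart) per gene, or None for unplanted genes.
    """
    if not 0 <= sd_fraction <= 1:
        raise ValueError("sd_fraction must be in [0, 1]")
    rng = stage_rng(seed, "genome")
    tail_rna = to_rna(tail)
    if d_sampler is None:
        d_sampler = lambda r: int(r.integers(11, 22))
    truth = SimTruth(seed=seed)
    parts: list[str] = []
    genes: list[GeneRecord] = []
    pos = 0
    for gi in range(n_genes):
        gid = f"sg{gi:04d}"
        planted = rng.random() < sd_fraction
        if planted:
            d = d_sampler(rng)
            window, motif, _ = _plant_window(rng, tail_rna, d, window_len, gc)
            truth.planted_sd_per_gene[gid] = (motif, d)
        else:
            window = _random_dna(rng, window_len, gc)
            truth.planted_sd_per_gene[gid] = None
        n_codons = int(rng.integers(20, 61))
        cds = "ATG" + "".join(
            rng.choice(["GCT", "GAA", "CTG", "AAA", "GGT", "TCC", "CGT", "ACC"])
            for _ in range(n_codons)
        ) + "TAA"
        strand = "-" if rng.random() < minus_strand_fraction else "+"
        is_pseudo = rng.random() < pseudo_fraction
        spacer = _random_dna(rng, 10, gc)
        unit = window + cds
        if strand == "+":
            parts.append(unit)
            s0 = pos + window_len
            e0 = s0 + len(cds)
        else:
            parts.append(revcomp_dna(unit))
            s0 = pos
            e0 = pos + len(cds)
        parts.append(spacer)
        genes.append((gid, strand, s0, e0, len(cds), is_pseudo))
        pos += len(unit) + len(spacer)
    seq = "".join(parts)
    rlen = len(seq)
    genome = Genome()
    genome.replicons[replicon_id] = Replicon(replicon_id, seq, circular)
    for gid, strand, s0, e0, clen, is_pseudo in genes:
        cds_start = s0 + 1 if strand == "+" else rlen - e0 + 1
        genome.genes.append(
            GeneRecord(gid, replicon_id, strand, cds_start, clen, is_pseudo, s0, e0)
        )
    return genome, truth


def write_genome_genbank(genome: Genome, path: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for rid, rep in genome.replicons.items():
        rec = SeqRecord(Seq(rep.seq), id=rid, name=rid[:16], description="synthetic genome")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if rep.circular else "linear"
        for g in genome.genes:
            if g.replicon_id != rid:
                continue
            quals = {"locus_tag": [g.gene_id]}
            if g.is_pseudo:
                quals["pseudo"] = [""]
            rec.features.append(
                SeqFeature(
                    FeatureLocation(g.start0, g.end0, strand=1 if g.strand == "+" else -1),
                    type="CDS",
                    qualifiers=quals,
                )
            )
        records.append(rec)
    SeqIO.write(records, path, "genbank")


def write_genome_fasta_gff(genome: Genome, fasta_path: str, gff_path: str) -> None:
    with open(fasta_path, "w") as fh:
        for rid, rep in genome.replicons.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(rep.seq), 70):
                fh.write(rep.seq[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rid, rep in genome.replicons.items():
            fh.write(f"##sequence-region {rid} 1 {len(rep.seq)}\n")
            circ = "true" if rep.circular else "false"
            fh.write(
                f"{rid}\tsdscan\tregion\t1\t{len(rep.seq)}\t.\t+\t.\t"
                f"ID=region-{rid};Is_circular={circ}\n"
            )
        for g in genome.genes:
            attrs = f"ID=cds-{g.gene_id};locus_tag={g.gene_id}"
            if g.is_pseudo:
                attrs += ";pseudo=true"
            fh.write(
                f"{g.replicon_id}\tsdscan\tCDS\t{g.start0 + 1}\t{g.end0}\t.\t"
                f"{g.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Expression tables


def simulate_expression(
    classes: dict[str, str],
    effect: float = 2.0,
    protein_sigma: float = 1.0,
    count_mean: float = 200.0,
    count_dispersion: float = 0.3,
    n_projects: int = 2,
    n_replicates: int = 3,
    gene_lengths: dict[str, int] | None = None,
    protein_mu: float = np.log(50.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Protein and count tables with a planted class effect on protein.

    Protein abundances are lognormal(mu, sigma), multiplied by ``effect``
    for SD-facilitated genes.  Counts are negative-binomial
    (gamma-Poisson) and independent of the class, so any protein-level
    contrast reflects the planted translational effect.
    """
    from .sd_scanner import SD_FACILITATED

    labels = set(classes.values())
    if len(labels) < 2:
        raise ValueError("both class labels must be present")
    rng = stage_rng(seed, "expression")
    genes = sorted(classes)
    prot = np.exp(rng.normal(protein_mu, protein_sigma, size=len(genes)))
    fac = np.array([classes[g] == SD_FACILITATED for g in genes])
    prot = prot * np.where(fac, effect, 1.0)
    proteins = pd.DataFrame({"gene_id": genes, "abundance": prot, "unit": "ppm"})

    rows = []
    shape = 1.0 / count_dispersion
    for proj in range(n_projects):
        for rep in range(n_replicates):
            lam = rng.gamma(shape, count_mean * count_dispersion, size=len(genes))
            counts = rng.poisson(lam)
            for g, c in zip(genes, counts):
                rows.append((g, f"project{proj + 1}", f"rep{rep + 1}", int(c)))
    counts_df = pd.DataFrame(rows, columns=["gene_id", "project", "replicate", "count"])
    truth = SimTruth(seed=seed, planted_effect=effect)
    return proteins, counts_df, truth
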