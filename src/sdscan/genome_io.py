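"""Annotated-genome I/O and strand-aware upstream window extraction.

Reads GenBank flat files or FASTA + GFF3 pairs, enumerates protein-coding
genes (flagging pseudogenes, which every downstream analysis excludes), and
extracts the upstream window immediately 5' of each annotated start codon on
the coding strand.  Internally all coordinates are 0-based half-open on the
reference strand; reported coordinates follow the 1-based GenBank convention
(for minus-strand genes, on the gene's own strand).

Replicons are treated as circular unless the file says linear (bacterial
chromosomes and plastid genomes are circular molecules); upstream windows
wrap across the origin on circular replicons and are truncated, with a flag,
on linear ones.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

from ._alphabet import revcomp_dna, to_rna


class GenomeFormatError(ValueError):
    """Raised when an input genome file cannot be interpreted."""


class EmptyAnnotationError(GenomeFormatError):
    """Raised when a genome carries no CDS features."""


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene.

    ``cds_start`` is the 1-based position of the first base of the start
    codon *on the gene's own strand* (for minus-strand genes this counts
    from the 3' end of the reference strand).  ``start0``/``end0`` are the
    internal 0-based half-open span on the reference strand.
    """

    gene_id: str
    replicon_id: str
    strand: str  # "+" or "-"
    cds_start: int
    length_nt: int
    is_pseudo: bool
    start0: int
    end0: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.cds_start < 1 or self.length_nt < 3:
            raise ValueError(f"invalid coordinates for gene {self.gene_id}")


@dataclass(frozen=True)
class UpstreamWindow:
    """Bases immediately 5' of a start codon, in RNA alphabet.

    Positions are labelled -L..-1 with -1 abutting the start codon;
    ``seq[-1]`` is position -1.  ``truncated`` flags windows shortened by a
    linear-replicon edge.
    """

    gene_id: str
    seq: str
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Replicon:
    replicon_id: str
    seq: str  # DNA, uppercase
    circular: bool = True


@dataclass
class Genome:
    replicons: dict[str, Replicon] = field(default_factory=dict)
    genes: list[GeneRecord] = field(default_factory=list)

    def coding_genes(self) -> list[GeneRecord]:
        """Non-pseudo protein-coding genes (the analysis gene set)."""
        return [g for g in self.genes if not g.is_pseudo]

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _unique_id(base: str, seen: set[str]) -> str:
    gid = base
    k = 2
    while gid in seen:
        gid = f"{base}_{k}"
        k += 1
    seen.add(gid)
    return gid


def _from_genbank(path: str) -> Genome:
    try:
        records = list(SeqIO.parse(path, "genbank"))
    except Exception as exc:
        raise GenomeFormatError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise GenomeFormatError(f"no records in GenBank file {path}")
    genome = Genome()
    seen: set[str] = set()
    for rec in records:
        topology = rec.annotations.get("topology", "circular")
        genome.replicons[rec.id] = Replicon(rec.id, str(rec.seq).upper(), topology != "linear")
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            base = (quals.get("locus_tag") or quals.get("gene") or quals.get("protein_id") or ["cds"])[0]
            gid = _unique_id(base, seen)
            strand = "-" if feat.location.strand == -1 else "+"
            s0, e0 = int(feat.location.start), int(feat.location.end)
            cds_start = s0 + 1 if strand == "+" else len(rec.seq) - e0 + 1
            genome.genes.append(
                GeneRecord(
                    gene_id=gid,
                    replicon_id=rec.id,
                    strand=strand,
                    cds_start=cds_start,
                    length_nt=len(feat.location),
                    is_pseudo="pseudo" in quals or "pseudogene" in quals,
                    start0=s0,
                    end0=e0,
                )
            )
    if not genome.genes:
        raise EmptyAnnotationError(f"no CDS features in {path}")
    return genome


def _from_fasta_gff(fasta_path: str, gff_path: str) -> Genome:
    try:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
    except Exception as exc:
        raise GenomeFormatError(f"cannot parse FASTA {fasta_path}: {exc}") from exc
    if not seqs:
        raise GenomeFormatError(f"no sequences in {fasta_path}")
    try:
        db = gffutils.create_db(
            gff_path, dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise GenomeFormatError(f"cannot parse GFF3 {gff_path}: {exc}") from exc

    circular: dict[str, bool] = {}
    for region in db.features_of_type("region"):
        flag = (region.attributes.get("Is_circular") or ["true"])[0]
        circular[region.seqid] = flag.lower() == "true"

    genome = Genome()
    for rid, seq in seqs.items():
        genome.replicons[rid] = Replicon(rid, seq, circular.get(rid, True))

    seen: set[str] = set()
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        attrs = feat.attributes
        base = (attrs.get("locus_tag") or attrs.get("ID") or attrs.get("Name") or ["cds"])[0]
        gid = _unique_id(base.removeprefix("cds-"), seen)
        if feat.seqid not in genome.replicons:
            raise GenomeFormatError(f"CDS {gid} on unknown replicon {feat.seqid}")
        strand = "-" if feat.strand == "-" else "+"
        s0, e0 = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
        rlen = len(genome.replicons[feat.seqid].seq)
        cds_start = s0 + 1 if strand == "+" else rlen - e0 + 1
        is_pseudo = "pseudo" in attrs or attrs.get("pseudogene") not in (None, ["false"])
        genome.genes.append(
            GeneRecord(gid, feat.seqid, strand, cds_start, e0 - s0, bool(is_pseudo), s0, e0)
        )
    if not genome.genes:
        raise EmptyAnnotationError(f"no CDS features in {gff_path}")
    return genome


def load_genome(path: str, annotation: str | None = None) -> Genome:
    """Load an annotated genome.

    Parameters
    ----------
    path
        GenBank flat file, or a FASTA file when ``annotation`` is given.
    annotation
        GFF3 file describing CDS features on the FASTA sequences.
    """
    if annotation is not None:
        return _from_fasta_gff(path, annotation)
    ext = os.path.splitext(path)[1].lower()
    if ext in {".gb", ".gbk", ".gbff", ".genbank"}:
        return _from_genbank(path)
    # fall back on sniffing
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("LOCUS"):
        return _from_genbank(path)
    raise GenomeFormatError(
        f"{path}: not a GenBank file; FASTA input requires annotation=<gff3>"
    )


def extract_upstream_window(
    gene: GeneRecord, genome: Genome, window_len: int = 30
) -> UpstreamWindow:
    """Return the ``window_len`` bases immediately 5' of the start codon.

    The window is read on the coding strand and transcribed to RNA.  On
    circular replicons it wraps across the origin; on linear replicons it is
    truncated (flag set, with a warning) when fewer than ``window_len``
    upstream bases exist.
    """
    rep = genome.replicons[gene.replicon_id]
    seq, n = rep.seq, len(rep.seq)
    if gene.strand == "+":
        lo, hi = gene.start0 - window_len, gene.start0
        if lo >= 0:
            window = seq[lo:hi]
            truncated = False
        elif rep.circular:
            window = seq[lo % n:] + seq[:hi]
            truncated = False
        else:
            window = seq[:hi]
            truncated = True
    else:
        lo, hi = gene.end0, gene.end0 + window_len
        if hi <= n:
            window = seq[lo:hi]
            truncated = False
        elif rep.circular:
            window = seq[lo:] + seq[: hi % n]
            truncated = False
        else:
            window = seq[lo:]
            truncated = True
        window = revcomp_dna(window)
    if truncated:
        warnings.warn(
            f"gene {gene.gene_id}: only {len(window)} nt upstream on linear "
            f"replicon {gene.replicon_id}; window truncated",
            stacklevel=2,
        )
    return UpstreamWindow(gene.gene_id, to_rna(window), truncated)


def extract_all_windows(
    genome: Genome, window_len: int = 30, include_pseudo: bool = False
) -> list[UpstreamWindow]:
    genes = genome.genes if include_pseudo else genome.coding_genes()
    return [extract_upstream_window(g, genome, window_len) for g in genes]


def windows_to_tsv(windows: list[UpstreamWindow], genome: Genome, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tstrand\twindow_seq\ttruncated\n")
        for w in windows:
            strand = genome.gene(w.gene_id).strand
            fh.write(f"{w.gene_id}\t{strand}\t{w.seq}\t{int(w.truncated)}\n")


def windows_to_fasta(windows: list[UpstreamWindow], path: str) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.gene_id}\n{w.seq}\n")
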