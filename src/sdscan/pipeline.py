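"""End-to-end orchestration: tail call -> SD scan -> classification ->
anti-SD preference -> expression and structure contrasts.

Per-species defaults for the optimal D_toStart band (the spacing window in
which an SD/anti-SD duplex correctly juxtaposes the start codon with the
ribosomal A site) are bundled in :data:`OPTIMAL_RANGES` and can be
overridden in the run configuration.
"""

from __future__ import annotations

import dataclasses
import json
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import anti_sd, expression, genome_io, sd_scanner, structure_mfe, tail_caller

#: Optimal D_toStart ranges (inclusive) per species label.
OPTIMAL_RANGES: dict[str, tuple[int, int]] = {
    "synechocystis": (11, 21),
    "microcystis": (11, 20),
    "s-ssm6a": (8, 16),
    "s-ssm6b": (10, 21),
    "tobacco-chloroplast": (8, 16),
    "arabidopsis-chloroplast": (10, 21),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    species: str = "synechocystis"
    genome_path: str | None = None
    annotation_path: str | None = None  # GFF3 when genome is FASTA
    reads_path: str | None = None
    rdna_path: str | None = None  # FASTA with the 16S rDNA sequence
    tail: str | None = None  # override: skip tail calling
    proteins_path: str | None = None
    counts_path: str | None = None
    optimal_range: tuple[int, int] | None = None
    window_len: int = 30
    mfe_window_len: int = 40
    min_match: int = 25
    min_identity: float = 0.95
    min_sd_len: int = 4
    core: str = "CCTCC"
    flank: int = 100
    z_crit: float = 1.645
    n_shuffles: int = 1000
    seed: int = 17
    outdir: str | None = None

    def resolved_range(self) -> tuple[int, int]:
        if self.optimal_range is not None:
            return tuple(self.optimal_range)
        try:
            return OPTIMAL_RANGES[self.species]
        except KeyError:
            raise ValueError(
                f"no bundled optimal D_toStart range for species "
                f"{self.species!r}; set optimal_range explicitly"
            ) from None


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("tail-call")
def _tail_stage(config: RunConfig) -> tuple[str, dict]:
    if config.tail:
        return config.tail.upper().replace("T", "U"), {"mode": "override"}
    if not (config.reads_path and config.rdna_path):
        raise ValueError("either a tail override or reads+rdna inputs are required")
    from Bio import SeqIO

    rdna = str(next(SeqIO.parse(config.rdna_path, "fasta")).seq)
    query = tail_caller.build_query(rdna, core=config.core, flank=config.flank)
    pileup = tail_caller.map_read_ends(
        config.reads_path, query, min_match=config.min_match,
        min_identity=config.min_identity,
    )
    call = tail_caller.call_prominent_tail(pileup)
    secondary = tail_caller.detect_secondary_tails(pileup, call)
    return call.tail_seq, {
        "mode": "called",
        "terminus": call.terminus,
        "peak_count": call.peak_count,
        "secondary": [(c.terminus, c.tail_seq, c.peak_count) for c in secondary],
    }


def run_pipeline(config: RunConfig, genome: genome_io.Genome | None = None) -> dict:
    """Execute every configured stage; returns the report bundle.

    When ``outdir`` is set, per-stage TSV/JSON artifacts and a manifest
    sufficient to reproduce the run are written there.
    """
    report: dict = {"config": dataclasses.asdict(config)}

    tail, tail_info = _tail_stage(config)
    report["tail"] = {"sequence": tail, **tail_info}

    if genome is None:
        if not config.genome_path:
            raise PipelineError("load-genome", "no genome supplied")
        try:
            genome = genome_io.load_genome(config.genome_path, config.annotation_path)
        except Exception as exc:
            raise PipelineError("load-genome", str(exc)) from exc

    try:
        genes = genome.coding_genes()
        windows = [
            genome_io.extract_upstream_window(g, genome, config.window_len) for g in genes
        ]
        per_gene = sd_scanner.scan_genes(windows, tail, min_len=config.min_sd_len)
        all_matches = [m for ms in per_gene.values() for m in ms]
        rng_lo, rng_hi = config.resolved_range()
        classes = [
            sd_scanner.classify_gene(gid, ms, (rng_lo, rng_hi))
            for gid, ms in per_gene.items()
        ]
        n_fac = sum(c.label == sd_scanner.SD_FACILITATED for c in classes)
        rep_matches = [c.best_match for c in classes if c.best_match is not None]
        report["sd_scan"] = {
            "tail_len": len(tail),
            "n_genes": len(genes),
            "n_matches": len(all_matches),
            "n_genes_with_sd": sum(bool(ms) for ms in per_gene.values()),
            "n_sd_facilitated": n_fac,
            "n_sd_independent": len(classes) - n_fac,
            "optimal_range": [rng_lo, rng_hi],
            "motif_usage_optimal": sd_scanner.motif_usage(
                rep_matches, (rng_lo, rng_hi)
            ).to_dict(),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("sd-scan", str(exc)) from exc

    try:
        usage = anti_sd.usage_analysis(
            windows, tail, matches=all_matches,
            n_shuffles=config.n_shuffles, seed=config.seed, z_crit=config.z_crit,
        )
        report["anti_sd"] = {
            "n": usage.n,
            "preferred_motif": usage.preferred_motif,
            "table": usage.to_frame().to_dict(orient="list"),
        }
    except anti_sd.UndefinedExpectationError as exc:
        report["anti_sd"] = {"error": str(exc)}
    except Exception as exc:
        raise PipelineError("anti-sd", str(exc)) from exc

    label_by_gene = {c.gene_id: c.label for c in classes}

    records = None
    if config.proteins_path and config.counts_path:
        try:
            proteins = pd.read_csv(config.proteins_path, sep="\t")
            counts = pd.read_csv(config.counts_path, sep="\t")
            gene_lengths = {g.gene_id: g.length_nt for g in genes}
            records = expression.build_expression_records(
                proteins, counts, gene_lengths, labels=label_by_gene
            )
            contrast = expression.contrast_groups(records, "protein_abundance")
            report["expression"] = {"protein_abundance": dataclasses.asdict(contrast)}
            for proj in sorted(counts["project"].unique()):
                c = expression.contrast_groups(
                    records, "protein_per_transcript", project=proj
                )
                report["expression"][f"protein_per_transcript[{proj}]"] = dataclasses.asdict(c)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("expression", str(exc)) from exc

    try:
        mfe_records = structure_mfe.mfe_table(genome, config.mfe_window_len)
        mfe_values = {r.gene_id: r.mfe_kcal_mol for r in mfe_records}
        report["mfe"] = {
            "n": len(mfe_records),
            "median": float(np.median(list(mfe_values.values()))),
            "engine": f"{structure_mfe.ENGINE} {structure_mfe.ENGINE_VERSION}",
        }
        if records is not None:
            c = expression.contrast_groups(records, "mfe", values=mfe_values)
            report["mfe"]["contrast"] = dataclasses.asdict(c)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("mfe", str(exc)) from exc

    if config.outdir:
        _write_outputs(config, report, windows, genome, all_matches, classes, mfe_records)
    return report


def _write_outputs(config, report, windows, genome, matches, classes, mfe_records):
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)
    genome_io.windows_to_tsv(windows, genome, out("windows.tsv"))
    sd_scanner.matches_to_tsv(matches, out("sd_matches.tsv"))
    sd_scanner.classes_to_tsv(classes, out("gene_classes.tsv"))
    structure_mfe.mfe_to_tsv(mfe_records, out("mfe.tsv"))
    with open(out("report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    manifest = {
        "sdscan_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "folding_engine": f"{structure_mfe.ENGINE} {structure_mfe.ENGINE_VERSION}",
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
    }
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
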