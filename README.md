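# sdscan

Tools for analysing Shine–Dalgarno (SD) sequence usage in bacteria,
bacteriophages and plastids — built for the questions raised by
Cyanobacteria and chloroplasts, where the importance of SD-facilitated
translation initiation has long been debated.

## The problem

In bacteria the SD sequence in the 5′ UTR base-pairs with the anti-SD
sequence — the single-stranded 3′ tail of the mature 16S rRNA — to position
the start codon at the ribosome. Answering whether a genome actually *uses*
this mechanism requires three ingredients that this package provides:

1. **The true anti-SD tail.** Automated 16S rRNA annotations frequently
   mis-place the mature 3′ terminus. `sdscan.tail_caller` re-derives it from
   RNA-Seq: reads are mapped (ungapped, ≥ 25 matched columns) onto a 205-nt
   query built around the conserved CCTCC core, read 3′ ends are piled up
   per site, and the terminus is called where (i) the implied tail contains
   CCUCC and sits within/near the conserved 5′-GAUCACCUCCUU(U|A)-3′ motif and
   (ii) its peak count exceeds the combined counts of the next ≥ 5
   downstream sites. Secondary termini (3′-end heterogeneity) are reported.

2. **Where SDs sit.** `sdscan.sd_scanner` enumerates every maximal
   antiparallel Watson–Crick duplex (≥ 4 nt) between each gene's 30-nt
   upstream window and the tail, and scores its position with the spacing
   statistic

   *D*<sub>toStart</sub> = |p| + (L − t<sub>hi</sub>),

   the number of mRNA nucleotides from the projected position of the tail's
   3′-terminal base to the base immediately upstream of the start codon
   (window position p pairs tail position t<sub>hi</sub>; L = tail length).
   Genes with a duplex inside the species' optimal *D*<sub>toStart</sub>
   band (e.g. 11–21 nt) are **SD-facilitated**, the rest **SD-independent**.

3. **Which tail sites are preferred.** `sdscan.anti_sd` tabulates observed
   per-site pairing counts *O*<sub>i</sub> against a shuffle-based null
   expectation *E*<sub>i</sub> (per-window mononucleotide permutation,
   rescaled so ΣE = n = ΣO) and applies the upper-tailed CLT test
   *Z*<sub>i</sub> = (p<sub>i</sub> − p̂<sub>i</sub>) /
   √(p̂<sub>i</sub>(1 − p̂<sub>i</sub>)/n), significant at
   *Z*<sub>i</sub> ≥ 1.645.

Downstream, `sdscan.expression` contrasts protein abundance, FPKM-based
protein-per-transcript and 5′-UTR folding stability between the two gene
classes (Wilcoxon rank-sum with continuity correction; Kendall τ<sub>b</sub>
for motif-usage association), and `sdscan.structure_mfe` folds the 40-nt
initiation region (simplified Turner nearest-neighbor model, no lonely
pairs). `sdscan.synthetic` generates genomes, read sets and expression
tables with planted ground truth so every stage is testable offline.

## Worked example

Simulate a dataset and run the pipeline end to end:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

prints (seed 1):

```
[tail-call] called tail GAUCACCUCCUUU (peak 600, downstream sum 98)
[sd-scan] 374 maximal duplexes in 300 genes; 211 SD-facilitated (181 planted)
[anti-sd] n = 1886; preferred motif: U
[expression] protein abundance: n = 211/89, medians 105.4/44.4, p = 2.79e-09
[expression] protein per transcript (project1): p = 1.20e-07
[mfe] 300 windows folded; median -3.11 kcal/mol; class contrast p = 2.65e-01
```

Reading this: the caller recovered the planted mature tail exactly (its
peak of 600 read ends dwarfs the 98 downstream counts); 211 of 300 genes
carry a duplex at optimal spacing (181 were planted, the rest arise by
chance in random windows, as in real genomes); the planted 2× protein
effect on SD-facilitated genes is detected at p ≈ 10⁻⁹ while the MFE
contrast is null — as it should be, since this simulation plants no
structure difference.

The same stages are available as a CLI (`sdscan tail-call`, `sdscan
sd-scan`, `sdscan anti-sd`, `sdscan mfe`, `sdscan run --config run.yaml`,
`sdscan simulate ...`) and as plain library calls; see `docs/methods.md`
for the model details and parameter defaults.

## What `scripts/acceptance.py` does

It re-runs the whole analysis from scratch on self-generated data: calls
the 16S tail from simulated reads, scans and classifies a simulated
genome, runs the anti-SD site-preference test, and computes the
expression and structure contrasts, writing its JSON result to `--out`.
All randomness derives from `--seed`. The statistical acceptance
properties (terminus recovery rate, scanner-oracle equivalence, planted
*D*<sub>toStart</sub> recovery, Z-test calibration, rank-statistic
oracles, contrast power) live in `tests/test_acceptance.py`.
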