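# Methods

This note documents the models, conventions and numerical choices behind
`sdscan`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what a passing test does and does not establish.

## 1. Mature 16S 3′-tail calling (`tail_caller`)

**Model.** The mature 16S rRNA 3′ terminus is identified from the pileup
of RNA-Seq read 3′ ends along a query built as the CCTCC anti-SD core plus
100 nt of flanking rDNA on each side (205 nt total; truncated and flagged
when the core sits near a sequence end). Two criteria define a valid
terminus: the implied tail (from the conserved-motif start to the
terminus) must contain CCUCC and end within the conserved genomic motif
5′-GAUCACCUCCUU(U|A)-3′ or at most `proximity_nt` (default 4) nt
downstream of it; and its count must exceed the summed counts of the next
`k_downstream` (default 5) sites, reflecting rapid RNase turnover of
precursor intermediates. Among qualifying termini the highest peak wins;
count ties break toward the most upstream position (the conservative
call — precursor signal accumulates downstream). "Close to" the conserved
motif is not quantified in the literature; 4 nt spans the observed
heterogeneity (e.g. termini extending …CUUUU).

**Mapping contract.** Reads map by ungapped local alignment, either
orientation, best hit only: ≥ `min_match` (25) aligned columns at
≥ `min_identity` (0.95) identity. This replaces a BLAST E-value cutoff —
E-values are database-size dependent; the essential constraint is the
25-column ungapped match. Identical reads are collapsed first, and FASTA
headers in `SeqID_count` form carry multiplicities; SAM/BAM input is
accepted so any external aligner can be substituted (the ungapped check is
re-applied from the CIGAR). The recorded 3′-end is the **rightmost aligned
query coordinate** for both orientations: a reverse-orientation read is
the antisense copy of a sense fragment, whose 3′ end is its rightmost
reference position. This convention makes the pileup invariant under
reverse-complementing the read set, which is a tested property.

**Secondary termini.** Heterogeneous 3′ ends are reported as secondary
calls: non-primary termini meeting both criteria at ≥ 25% of the primary
peak. One deliberate refinement: the primary terminus is excluded from a
secondary candidate's downstream sum. Without this, a secondary end lying
1–5 nt upstream of the primary could never qualify, because the mature
peak itself — which is product, not precursor — would veto it; observed
secondary tails sit exactly in that geometry.

**Trimming** is out of scope; a minimal convenience trimmer (drop reads
with mean Phred < 20, clip configured adapters, keep ≥ 25 nt) mirrors the
thresholds the pipeline assumes for its inputs.

## 2. SD/anti-SD scanning and D_toStart (`sd_scanner`)

A match is a **maximal** contiguous antiparallel Watson–Crick duplex of
length ≥ 4 between the 30-nt upstream window (positions −30…−1, −1
abutting the start codon) and the tail; all window × tail offsets are
examined, and maximality means no single-base extension is possible on
either side. Pairing is strict A:U / G:C; G:U wobble is a switch, off by
default, because the canonical SD examples are Watson–Crick. Since window
position p pairs tail position t_hi and extension moves (p+1, t_hi−1),
matches live on anti-diagonals of the complementarity matrix, which gives
the O(W·L) enumeration and the identity D_toStart = W + L − 1 − c for a
diagonal c — every cell of one diagonal shares one spacing, which is the
point of the statistic: different motifs pairing different tail segments
at the same D_toStart place the ribosome identically.

Classification: a gene is SD-facilitated iff some match has D_toStart
inside the configured optimal band (bundled per-species defaults:
Synechocystis 11–21, Microcystis 11–20, cyanophage S-SSM6a 8–16, S-SSM6b
10–21, tobacco chloroplast 8–16, Arabidopsis chloroplast 10–21). The
per-gene representative match is the longest in-range match, ties to the
smallest D_toStart. All maximal matches (not just representatives) feed
the O:E tabulation and D_toStart histograms. `propose_optimal_range` — the
shortest integer interval holding ≥ 60% of the D values — is a helper for
eyeballing where the peak sits; classification always uses an explicit
band, because published bands were chosen by inspection of the full
distribution, not by an automatic rule.

Degenerate inputs: windows shorter than 4 nt yield no matches and hence
SD-independent genes; truncated windows on linear replicons are flagged,
never padded.

## 3. Anti-SD site preference (`anti_sd`)

Observed usage O_i counts, per tail site, every maximal match that pairs
it. The null expectation E_i is a Monte-Carlo average: each window's bases
are permuted uniformly (composition preserved — composition is the main
confounder), the scan re-runs, and mean per-site counts are rescaled so
ΣE = n = ΣO. With p_i = O_i/n, p̂_i = E_i/n, the site test is upper-tailed,
Z_i = (p_i − p̂_i)/√(p̂_i(1−p̂_i)/n), significant at Z_i ≥ 1.645 (inclusive;
one-sided 5%), no multiple-testing correction — matching the published
construction exactly. The preferred anti-SD motif is the longest
contiguous run of significant sites (ties to the most 3′ run, since
preference concentrates at the 3′ terminus). Sites with E_i = 0 but
O_i > 0 are flagged untestable rather than divided by zero. An analytic
alternative expectation (i.i.d. draws from each window's composition,
with closed-form run-membership probabilities along each diagonal) avoids
Monte-Carlo noise; it ignores the without-replacement structure of a true
permutation, so shuffling stays the default.

**Known calibration property.** Under a null where windows are i.i.d.
from their own composition, the empirical per-site type-I rate at
Z ≥ 1.645 measures ≈ 0.029–0.031, not 0.05: each duplex contributes a
contiguous run of ≥ 4 sites, so O_i and n are strongly positively
correlated and the binomial variance p̂(1−p̂)/n overstates the variance of
p_i − p̂_i. The statistic itself is nominal (measured 0.052) when counts
are drawn multinomially from the expected proportions. The conservative
behaviour is therefore a property of the published test construction,
which this package reproduces rather than corrects.

## 4. Expression metrics (`expression`)

FPKM = count·10⁹/(length·total), averaged arithmetically across
replicates within a BioProject; projects are analysed separately, so each
gene carries one protein-per-transcript value (protein abundance / mean
FPKM) per project, undefined when the mean FPKM is zero (the gene is then
excluded from contrasts, never infinite). Contrasts include only
non-pseudo genes with protein abundance > 0.

The Wilcoxon rank-sum test uses midranks, tie-corrected variance and a
0.5 continuity correction (verified to reproduce R's `wilcox.test`); when
both groups have ≤ 10 observations the p-value comes from exhaustive
enumeration over rank assignments, which, unlike the usual exact
algorithms, remains valid under ties. Kendall's τ_b uses the standard tie
adjustment, τ_b = (C−D)/√((n₀−n₁)(n₀−n₂)), and is reported as undefined
when either vector is entirely tied. Two-sided p-values throughout. The
normal approximation agrees with exact enumeration to < 0.02 for n ≥ 8 in
the informative regime; near p ≈ 1 the two-sided continuity correction
saturates and the difference can reach ≈ 0.023.

## 5. Initiation-region folding (`structure_mfe`)

The 40 nt immediately 5′ of the start codon are folded at 37 °C with a
self-contained Zuker-style dynamic program (no external folding engine is
available in the supported environment). The energy model: Watson–Crick
nearest-neighbor stack energies from the standard Turner nearest-neighbor set; a flat
−0.8 kcal/mol for wobble-containing stacks; size-based hairpin/bulge/
internal-loop initiation with 1.75·RT·ln(n/n₀) extrapolation and a capped
asymmetry term; affine multiloops (3.4 close + 0.4/branch); 0.5 kcal/mol
terminal A:U/G:U penalty; no tetraloop bonuses, terminal mismatches,
dangles or coaxial stacking. The default no-lonely-pairs constraint is
enforced exactly by splitting the paired state into "helix continues
inward" and "innermost pair of its helix" matrices, so every helix
carries ≥ 2 pairs. MFE is min(0, best), hence never positive.

Consequences of the simplifications: absolute MFEs differ from a full
Turner implementation by roughly 0.5–2 kcal/mol on 40-mers (no dangles
also means unpairable flanking bases are exactly neutral, which is
regression-tested). The analysis consumes rank order and group contrasts,
which are robust to these offsets; published absolute MFE values are
therefore not asserted anywhere, and the fixed-hairpin regression constant
(−7.54 kcal/mol) is pinned to this engine at version 1.0.

## 6. Synthetic data (`synthetic`)

The generators state the world the tests live in:

* **Reads**: 60% of read 3′ ends sit exactly at the planted terminus, 30%
  uniformly upstream (degradation/internal fragments), 10% downstream with
  geometric(0.5) decay (precursor intermediates) — the canonical pileup
  shape with a dominant mature peak. Reads are exact 50-nt substrings; no
  sequencing-error model, so caller recovery tests establish peak logic,
  not robustness to base errors.
* **Genomes**: per-gene 30-nt windows from an i.i.d. composition model
  (configurable GC), with probability `sd_fraction` (0.6) carrying a
  planted reverse-complement of a random 4–8-nt tail substring placed so
  its D_toStart equals a draw from the spacing sampler (default uniform
  11–21). Rejection sampling guarantees the planted duplex is the unique
  longest match in its window, so scanner recovery is exact by
  construction — chance background matches still occur and are wanted, as
  in real genomes. No operon structure or codon realism.
* **Expression**: lognormal protein abundances (σ = 1, median 50 ppm)
  multiplied by the planted effect (default 2×) for SD-facilitated genes;
  negative-binomial counts (mean 200, dispersion 0.3) independent of
  class, so protein-level contrasts isolate the translational effect.

One global seed expands to per-stage streams via a CRC-based label split,
so every stage is independently reproducible; all generated datasets
round-trip through their on-disk formats (FASTA+, GenBank, FASTA+GFF3,
TSV).

## 7. Coordinates and conventions

Internal coordinates are 0-based half-open on the reference strand;
reported coordinates are 1-based inclusive, on the gene's own strand for
minus-strand genes. Pseudogenes are parsed, flagged and excluded from all
analyses. Replicons are circular unless the file says linear; upstream
windows wrap across the origin on circular replicons and truncate (with a
warning flag) on linear ones. Start codons are taken from the annotation
as-is (not restricted to AUG); upstream windows come from genomic
sequence regardless of transcript boundaries. Multi-exon plastid CDS use
the annotated feature span's start.

## 8. Known limitations

* The folding engine is a deliberate simplification (see §5); use it for
  contrasts, not for publishing absolute ΔG values.
* The per-site CLT preference test is mildly conservative under a
  faithful null (see §3).
* Multi-mapping reads count once, at their best hit; rRNA operon copies
  must be disambiguated by the user's choice of query sequence.
* FPKM fragment assignment is CDS-based and single-best-hit; isoforms,
  TPM and batch effects are out of scope.
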