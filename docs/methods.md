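# Methods

## Scope and model

`cirloop` implements the two computational analyses that link a failure of
circRNA nuclear export (loss of the exportin XPO4) to genome instability:

1. **R-loop decomposition.** DRIP-seq with the S9.6 antibody recovers the DNA
   strand of R-loops. Predigesting the sample with RNase R — a 3'→5'
   exonuclease that degrades linear RNA but spares covalently closed circles —
   leaves only R-loops whose RNA moiety is a circRNA. Operationally:
   peaks from the RNase-R-treated library are **ciR-loops**; the **liR-loop**
   profile is the total R-loop profile minus the ciR-loops. ciR-loops are
   **cis** when they overlap a genomic region that produces a circRNA and
   **trans** otherwise; liR-loops are **WAT**/**WOT** according to overlap with
   an annotated transcript. Because the assay sequences DNA, a ciR-loop at a
   circRNA-producing locus is always counted cis even if the hybridizing
   circle came from elsewhere: cis and WAT are overestimates, trans and WOT
   underestimates, and reports carry this caveat.

2. **CircRNA nucleocytoplasmic enrichment.** CircRNAs are quantified by reads
   crossing their back-splice junction (BSJ), the non-colinear donor–acceptor
   joint absent from linear transcripts. Junction counts are TPM-normalized
   (count / library size × 10⁶), replicate detections intersected, and
   per-circRNA nuclear vs cytoplasmic enrichment tested. A circRNA is
   **cytoplasmic** when log2(Nuc/Cyto) < −0.3 with p < 0.05 and **nuclear**
   when log2(Nuc/Cyto) > 0.3 with p < 0.05; all inequalities strict, all else
   unclassified. Cytoplasmic circRNAs in WT are the export-receptor-sensitive
   cohort; cytoplasmic circRNAs in KO are the insensitive cohort; a circRNA
   cytoplasmic in both belongs to both condition-wise sets.

## Statistical choices

- **Nuc/Cyto test.** Welch's unpaired two-sided t on log2(TPM + pseudocount)
  replicate values, pseudocount 0.5. This deliberately replaces a
  negative-binomial GLM framework (DESeq2-style) with the explicit t-test the
  rest of the study uses; the substitution is simple, transparent, and exactly
  reproducible. With both groups at zero variance, p = 1 when the means agree
  and 0 otherwise. No multiple-testing correction is applied to the
  classification (the thresholds are raw p < 0.05); a Benjamini–Hochberg
  column is emitted for users who want it.
- **Export-dependent set.** Beyond the condition-wise sets, the analysis
  reports an `export_dependent` set by a half-recovery rule: cytoplasmic in
  WT *and* log2(Nuc/Cyto)_KO > log2(Nuc/Cyto)_WT / 2, i.e. the KO point
  estimate has given back at least half of the WT cytoplasmic enrichment.
  The rule deliberately does not gate on the KO p-value: with 4 replicates
  and overdispersed counts, single t-test failures are common, and requiring
  a localization-class flip converts those p-value accidents into both false
  positives and false negatives. A point-estimate rule is insensitive to
  them while leaving genuinely unshifted circRNAs (KO ratio ≈ WT ratio)
  excluded.
- **Intensity correlation.** ciR/liR intensity pairs are formed for every
  overlapping ciR-loop/liR-loop interval pair and correlated with Pearson's r
  on log10(intensity + 1). The log transform stabilizes the heavy-tailed
  intensity scale; +1 keeps zero-score peaks finite. Fewer than 3 pairs or a
  zero-variance vector raises an error rather than returning NaN. Because
  base-level subtraction leaves liR fragments abutting (not overlapping)
  their ciR peak, the batch report pairs with a 1 bp tolerance
  (``max_gap=1``); the operation's default remains strict overlap.
- **Feature comparisons** (length, expression, GC, structure proxy) use the
  two-sample Kolmogorov–Smirnov test (asymptotic p) plus Welch's t, with
  cumulative-fraction curve coordinates emitted for plotting.
- **Folding proxy.** RNA structural stability is summarized by the maximum
  number of nested Watson–Crick/GU base pairs (Nussinov recursion, hairpin
  loops ≥ 3 nt). More attainable pairs ≈ more stable structure ≈ lower ΔG,
  so the proxy's sign convention is inverted relative to a free energy; a
  hook accepts externally computed ΔG values via the feature table when a
  thermodynamic folder is available.

## Interval algebra

Coordinates are 0-based half-open everywhere; BED I/O involves no shifting;
strand is ignored (S9.6 DRIP is not strand-resolved). `merge` unions
same-chromosome intervals separated by ≤ gap bases (book-ended intervals
join at gap 0, as bedtools does); `intersect` and `subtract` are base-level;
`common_peaks` keeps peaks overlapping (≥1 bp) at least one peak of the
other replicate and union-merges them — replicate-specific peaks drop. The
overlap predicate defaults to ≥1 bp with a configurable minimum-overlap
fraction. All four operations are exact: the test suite checks them
base-for-base against a per-base boolean-mask brute force on random
instances. Decomposition defaults: base-level subtraction (the liR profile
is a profile, not a peak list) with a 50 bp residual filter against spurious
slivers; `whole_peak` mode is available for peak-count semantics. Fold
changes default to peak counts, with covered-bases and summed-intensity
modes selectable. Spike-in scaling multiplies per-peak coverage sums by
(reference spike-in reads / sample spike-in reads), reference = first
sample.

## The simulator

The generator emulates the statistical structure the analyses assume, at
desk scale, with full ground truth; it is first-class tested code, and every
stream (annotation, genome, loops, counts, reads, qPCR, intensity pairs)
draws from its own child of the master seed so adding one stream never
perturbs another. Identical parameters + seed give byte-identical bundles.

**Annotation/genome.** 4 chromosomes × 3 Mb; 400 non-overlapping genes of 3
exons (exon ~400 bp, intron ~800 bp); 300 circRNA-producing loci sampled
from exons; gene FPKM log-normal (median 5, σ_log 1). The genome sequence is
uniform random A/C/G/T — no composition or repeat structure.

**Loops.** Default per-condition counts (WT: 25 cis / 10 trans / 120 WAT /
35 WOT; KO: 160 / 290 / 835 / 525; 2000 loops total) fix the planted
condition structure: KO/WT total ratio 9.53, a ~29× trans-ciR increase and a
15× WOT increase — the class structure of the genome-wide experiment at
roughly 1/10 scale. Loop lengths are log-normal (median 400 bp, σ_log 0.4,
floor 150 bp). cis/WAT loops are anchored to overlap their target locus or
transcript by ≥150 bp; trans/WOT placement keeps a 60 bp margin from every
forbidden annotation; all loops of one condition are mutually separated by
≥150 bp. These margins make the decomposition exactly invertible at zero
jitter and keep label flips rare at 20 bp boundary jitter. WAT genes are
drawn with probability ∝ FPKM, so liR-loops track transcription as expected
physiologically. Intensities are log-normal on the log10 scale (μ 2.5, σ
0.5).

**Replicates.** Each replicate jitters both peak ends independently by
N(0, σ) rounded to integers and truncated at chromosome bounds. Dropout is
applied per peak per replicate, and the event is shared between the treated
and untreated libraries of that replicate — both libraries derive from the
same culture, so a peak absent from a replicate is absent from both of its
libraries. This also means the recovery analyses compare against the
truth's *detectable* peaks (present in both replicates), which the truth
object records per peak; reproducibility filtering necessarily loses peaks
missing from a replicate, and that loss is a property of the common-peak
rule, not of the decomposition.

**Overlapping intensity pairs.** Base-level subtraction makes recovered ciR
and liR loops disjoint by construction, so overlapping pairs cannot arise
from a decomposed bundle; a dedicated stream emits overlapping ciR/liR call
pairs whose log10 intensities are bivariate normal with configurable
correlation (default 0.8) for testing the correlation estimator.

**Junction counts.** 1000 circRNAs; abundance log-normal (median 150 TPM,
σ_log 0.8); per-sample library size 2×10⁶ reads with 10% log-normal jitter;
replicate counts negative-binomial parameterized by mean μ and dispersion α
with variance μ + αμ² (α = 0.1; the α→0 limit is Poisson). Every circRNA's
true log2(Nuc/Cyto) is normal with mean −1.6 and sd 0.1 — circRNAs are
predominantly cytoplasmic at baseline — and the planted export-dependent 30%
is shifted nucleus-ward by +1.5 log2 units in KO only. The planted subset
also carries the covariate links seen in real data: 1.25× longer, +0.5 log2
more abundant, GC 5 points lower. The nuclear molecule fraction is
2^r/(1+2^r); nuclear/cytoplasmic TPMs are 2·A·share and 2·A·(1−share) so
the compartment average matches the total abundance A. The tight
between-circRNA spread (sd 0.1) represents a cohort sharing one export
equilibrium; real data are more heterogeneous, so passing recovery tests
bound estimator behavior under the planted structure, not under arbitrary
mixtures.

**Reads.** Junction-library entries carry `junction_flank` (40 nt) of
sequence either side of the back-splice point; emitted junction reads have
random overhangs within [max(min_overhang, L−flank), min(L−min_overhang,
flank)] so every read is recoverable by junction-window matching; colinear
decoy reads come from the sequence interior and never cross the junction.
Mates of BSJ reads are placed in an exon or an intron of a two-exon host
model according to a truth flag (EIciRNA fraction 0.3). No sequencing-error
model is simulated.

## What the tests show — and what they do not

The simulator reproduces the *statistical* structure of the experiments
(replicate peak sets with class-specific placement, NB counts with
compartment/condition effects), not their biology: no chromatin context, no
GC/repeat-driven peak artifacts, no mapping bias, no circRNA discovery step
(the junction library is known a priori), and dropout/jitter are the only
replicate disagreement mechanisms. Recovery results therefore validate the
pipeline's correctness and its estimators' consistency under the assumed
model; they do not certify performance on real DRIP-seq or fractionation
RNA-seq data.

## Numerical conventions and degenerate inputs

- Half-open interval abutment is not overlap; classification at an exactly
  shared boundary base follows from this (a loop starting where a locus ends
  is trans).
- Zero-denominator fold changes raise a dedicated error advising a
  pseudocount; they are reported as NaN in batch reports.
- Correlation with <3 pairs or zero variance raises; the report stores null.
- Empty circRNA-locus or transcript sets classify everything trans / WOT
  with a warning.
- Welch test with both groups degenerate: p = 1 if means equal, else 0.
- The Nussinov table is O(n³) time, O(n²) memory; adequate for circRNA-scale
  sequences (≤ a few kb).

## Problem sizes

Default analysis/simulation sizes (2000 loops on a 12 Mb genome, 1000
circRNAs × 2 conditions × 3 compartments × 4 replicates) run end-to-end in
a few seconds on one CPU; the bundled verification script and test suite use
these sizes and complete in well under a minute. They are the package's
chosen desk-scale study conditions, small enough to iterate on and large
enough for the recovery bands quoted above.
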