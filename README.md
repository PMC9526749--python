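# cirloop

Analysis of what happens when exonic circular RNAs (ecircRNAs) fail to leave
the nucleus. When the export receptor XPO4 is lost, ecircRNAs accumulate in
the nucleus and hybridize with genomic DNA, forming circRNA:DNA R-loops
(**ciR-loops**) alongside the ordinary linear-RNA R-loops (**liR-loops**).
`cirloop` implements the two computational pipelines of that analysis, for
genomicists working with DRIP-seq and nucleocytoplasmic fractionation
RNA-seq:

1. **R-loop decomposition** — DRIP-seq peaks from an RNase-R-predigested
   sample (linear RNA destroyed, circles spared) are the ciR-loops; the
   liR-loop profile is the total R-loop profile minus the ciR-loops.
   ciR-loops are *cis* if they overlap a circRNA-producing locus, else
   *trans*; liR-loops are *WAT*/*WOT* by overlap with annotated transcripts.
   The pipeline reports class counts, KO/WT fold changes, ciR/liR intensity
   correlation at shared regions, and expression association.

2. **circRNA nucleocytoplasmic enrichment** — circRNAs are counted from
   reads crossing their back-splice junction, TPM-normalized, and tested per
   circRNA with Welch's t on log2(TPM+0.5). Localization calls use
   log2(Nuc/Cyto) < −0.3 (cytoplasmic) or > 0.3 (nuclear), both at p < 0.05
   with strict inequalities. The condition-wise cytoplasmic sets define the
   XPO4-sensitive (WT) and XPO4-insensitive (KO) cohorts, and a
   half-recovery rule extracts the export-dependent set. Feature comparisons
   (length, expression, GC, base-pairing proxy) use the Kolmogorov–Smirnov
   test with cumulative-fraction curves; qPCR ΔCt fold changes
   (2^(Ct_ref − Ct_target)) are supported.

A fully ground-truthed simulator generates genomes, annotations, replicate
peak sets, coverage, negative-binomial junction counts, junction-spanning
reads and Ct tables, so every stage is verifiable without any sequencing
download. See `docs/methods.md` for the model, parameter and design details.

## Worked example

Simulate a default bundle (2 conditions × 2 replicates, 2000 planted loops,
1000 circRNAs), decompose it, run the enrichment analysis, and combine:

```sh
cat > sim.yaml <<'YAML'
simulate:
  seed: 1
YAML
cirloop simulate  --config sim.yaml --outdir sim
cirloop decompose --config dec.yaml --outdir dec    # paths to the sim/ BEDs
cirloop circdist  --counts sim/counts.tsv --library-sizes sim/library_sizes.tsv \
                  --circ-meta sim/circ_meta.tsv --outdir cd
cirloop report    --decomp dec --circ cd --outdir rep
cat rep/combined_report.txt
```

prints

```
cirloop combined report
=======================

[R-loop decomposition]
  KO: R_loop=1810, WAT=835, WOT=525, ciR_loop=450, cis=160, liR_loop=1360, trans=290
  WT: R_loop=190, WAT=120, WOT=35, ciR_loop=35, cis=25, liR_loop=155, trans=10
  fold R_loop_KO_vs_WT: 9.53
  fold WOT_KO_vs_WT: 15
  fold trans_KO_vs_WT: 29
  ...

[circRNA localization]
  n_tested: 1000
  n_sensitive: 956
  n_insensitive: 672
  n_sensitive_only: 312
```

Reading this: the KO cell carries 9.53× more R-loop peaks than WT, and the
increase is dominated by *trans* ciR-loops (29×) — circles hybridizing away
from their locus of origin — and by liR-loops outside annotated transcripts
(15×), the class structure expected when nuclear circRNA pileup drives
R-loop formation and downstream DNA damage. On the circRNA side, 956 of
1000 circRNAs are cytoplasmically enriched in WT but only 672 remain so in
KO; the 312 that lost cytoplasmic enrichment upon KO are the
export-dependent candidates. The feature table (`cd/features.tsv`) shows
they are longer (mean 712 vs 598 nt, KS p = 9e-4), more abundant (258 vs
208 TPM, KS p = 1e-3) and lower-GC (0.41 vs 0.45, KS p < 1e-4) than the
rest — the covariates the simulator plants and the analysis recovers.

Every command is a thin shell over the library; the same run in Python:

```python
from cirloop import SimulationParams, gen_annotation, gen_loops, decompose_conditions

params = SimulationParams(seed=1)
ann = gen_annotation(params)
bundle = gen_loops(params, ann)
reps = {}
for (cond, treat, rep), ps in bundle.peaksets.items():
    reps.setdefault((cond, treat), []).append(ps)
report, loops = decompose_conditions(reps, ann, coverages=bundle.coverages)
print(report.counts["KO"])        # {'R_loop': 1810, 'ciR_loop': 450, ... 'trans': 290, ...}
```

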