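# isoformgrid

Integrative analysis of transcription-factor **isoform-specific chromatin
binding** and **knockdown transcriptome response**, built around the
C/EBPα p42/p30 system in acute myeloid leukaemia models.

The biological question: the *CEBPA* gene produces a full-length (p42) and
an N-terminally truncated (p30) isoform, and AML-associated mutations skew
the balance between them. Where do the two isoforms bind differently, and
how does that binding pattern relate to which genes respond when a
cooperating factor (Myb) is knocked down? `isoformgrid` implements the
complete desk-side analysis for that design:

1. **Peak classification.** Summits of the p42 and p30 ChIP-seq peak sets
   are merged (single-linkage, ≤ 200 bp), tags of every factor are counted
   in ±200 bp windows and normalised to tags per 10⁷, and each merged
   summit is scored

   r = log2((n_p30 + c) / (n_p42 + c)),  c = 1

   with classes *p42-specific* (r ≤ −1), *shared* (|r| < 1), *p30-specific*
   (r ≥ 1). Peaks are ranked by r; that ranking orders every downstream
   heat-map. A FRiP (fraction of reads in peaks) statistic flags
   non-specific datasets such as the DNA-binding-dead K313KK mutant.
2. **Differential expression.** siMyb vs siNEG per cell line:
   median-of-ratios size factors, per-gene negative-binomial dispersion by
   method of moments moderated toward the across-gene median, Wald test on
   the log2 fold change, Benjamini–Hochberg adjustment. Plus FPKM,
   Spearman sample clustering, fold-change clustering and Venn overlaps.
3. **Integration.** Each peak is linked to the gene with the nearest TSS;
   knockdown fold changes are laid out along the p30/p42 ranking and
   summarised per class (Mann–Whitney between classes).
4. **Enrichment.** Gene-set mean fold change with a permutation null;
   hypergeometric over-representation; GSEA (weighted Kolmogorov–Smirnov
   enrichment score, gene-label permutation null, NES, BH q-values) of
   top-peak nearest-gene sets against fold-change-ranked lists.
5. **Motifs.** Log-odds PWM scanning of summit windows on both strands
   (threshold = 0.8 × max attainable score), one-sided Fisher enrichment
   between peak classes, and binary match matrices along the ranking.
6. **Simulator.** A ground-truth-bearing generator that emulates the whole
   study — three peak classes with distinct p42:p30 tag rates, co-localised
   Myb/p300 signal, a background-dominated K313KK analogue, NB counts for
   three cell lines × {siNEG, siMyb} with class-linked response directions,
   and planted motif occurrences — so every stage is testable against
   known truth.

## Worked example

```python
import pandas as pd
from isoformgrid import synthetic_data as sd, diffexpr as de, \
    peak_classify as pc, integration as integ

cfg = sd.SimulationConfig(seed=1)
genome, models, truth = sd.simulate_genome(cfg)
tracks, calls = sd.simulate_chip_tags(cfg, truth)
counts = sd.simulate_rnaseq_counts(cfg, truth)

summits = pc.merge_summits(calls["p42"], calls["p30"])
peaks = pc.classify(summits, tracks["p30"], tracks["p42"])
print(pd.Series([p.peak_class for p in peaks]).value_counts().to_string())

print(f"K313KK FRiP: {pc.frip(tracks['k313kk'], calls['k313kk']):.3f}")

fcm = pd.DataFrame({
    line: de.nb_test_all(counts, line).set_index("gene_id")["log2fc"]
    for line in sd.CELL_LINES
})
links = integ.nearest_gene(peaks, models)
summary, tests = integ.group_fold_change(links, peaks, fcm)
print(summary.pivot(index="class", columns="cell_line",
                    values="mean_log2fc").round(2).to_string())
```

Output:

```
shared          400
p42_specific    150
p30_specific    150
K313KK FRiP: 0.099
cell_line     FMH9    KL    LL
class
p30_specific -0.92 -1.01 -0.04
p42_specific  1.17  1.00  0.01
shared       -0.03  0.02 -0.01
```

Reading it: all 700 planted binding sites are recovered in their true
classes; the K313KK track's FRiP of 0.099 sits an order of magnitude below
the specific tracks (~0.66 for p42) and is flagged non-specific at any QC
floor above it (e.g. `frip_floor: 0.15`); and genes near p42-specific sites are de-repressed (~+1 log2) upon
Myb knockdown in the two responsive cell lines while genes near
p30-specific sites go down, with the third (non-responsive) line flat —
the binding-class/response-direction coupling the analysis is designed to
expose.

The same pipeline runs end-to-end from the command line:

```bash
isoformgrid run --out myrun --seed 1          # simulate + all stages
isoformgrid simulate --out fixture --seed 1   # just the synthetic data
isoformgrid de --counts fixture/counts.tsv --samples fixture/samples.tsv \
    --cellline FMH9 --out de_FMH9.tsv
```

Every stage writes plain TSV tables plus a run manifest with per-file
checksums; re-running with an unchanged configuration skips completed
stages.

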