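# cateno-iso

Analysis toolkit for **p120 catenin (CTNND1) isoform biology in breast
cancer**: quantify alternative exon usage from exon-level RNA-seq counts,
profile p120 isoform immunofluorescence as a function of distance from the
invasive front of a migrating cell sheet, and run the cohort and image
statistics that tie isoform ratios to tumor grade, size, survival and
histological subregion. Every input can be generated synthetically with
known ground truth, so the full pipeline is testable end to end.

It is written for cancer cell biologists and bioinformaticians who have
exon count tables (e.g. from TCGA SpliceSeq-style pipelines), multichannel
TIFF images of gap-closure assays, or cohort/score tables, and want the
analyses as reproducible, scriptable Python instead of a one-off
ImageJ/spreadsheet workflow.

## What it computes

**Relative exon usage.** For exon *e* with length *L_e* (kb) in sample *s*
with *N_s* million mapped reads,

    RPKM[e,s] = counts[e,s] / (L_e · N_s)
    u[e,s]    = RPKM[e,s] / mean_e' RPKM[e',s]

The gene-level reference cancels overall expression differences, so group
means of *u* compare exon inclusion, and the tumor/normal fold
`mean_tumor(u_e) / mean_normal(u_e)` reports differential exon usage (e.g.
cassette exon B, entry exons 4.1/4.3 of CTNND1).

**Invasive-front profiling.** The F-actin channel is thresholded with the
Kittler–Illingworth minimum-error criterion (exhaustive minimization of the
two-Gaussian classification-error functional), intra-sheet holes are closed
by *n* erosions + *n* dilations of the background phase, the mask outline
minus image-border pixels gives the front line, and an exact Euclidean
distance transform assigns every cell pixel to 0.2 µm distance bins out to
180 µm. Marker means per bin give the isoform profiles; 30 µm coarse bins
of `mean(p120-3)/mean(p120-1)` are compared against confluent control
images with Kruskal–Wallis + Dunn.

**Cohort statistics.** Band-densitometry isoform ratios; Spearman rank
correlation of ratio vs ordinal grade; tie-corrected Kruskal–Wallis with
Dunn's post hoc (z on pooled mid-ranks, Bonferroni/Holm/Šidák adjustment)
across size categories or tumor subregions; Mantel–Cox log-rank test for
median-split survival; pooled-variance Student t-test guarded by an F-test.
Each rank test and the log-rank test offer `exact=True` (exhaustive label
permutation) for small samples.

## Worked example

`examples/` contains one short script per capability. For instance:

```sh
$ python examples/exon_usage_demo.py
exon   tumor/normal fold   generator expectation
 4.1               0.899                   0.946
 4.3               0.952                   0.946
   A               0.950                   0.946
   B               3.030                   3.039
   C               0.964                   0.946
   D               0.956                   0.946
```

Exon B was simulated with 90 % inclusion in tumor versus 28 % in normal
tissue; the chain recovers the expected ≈3-fold enrichment while unchanged
exons stay near 1. And the front profile:

```sh
$ python examples/front_profile_demo.py
confluent reference ratio:  0.417

30-um bin   mean p120-3/p120-1 ratio   Dunn p (vs confluent)
    0-30um                      1.382   0.0001
   30-60um                      0.599   0.0049
   60-90um                      0.462   0.1059
```

The p120-3/p120-1 ratio is several-fold elevated at the leading edge and
decays toward the confluent value within ~90 µm — the signature of local
p120-3 enrichment at the invasive front.

A thin CLI mirrors the library for shell pipelines:

```sh
cateno-iso simulate front --seed 7 --out sim/
cateno-iso front-profile --image sim/image.tif --out prof/
cateno-iso exon-usage --counts counts.tsv --samples samples.tsv --out ratios.tsv
cateno-iso cohort-stats --records cohort.csv --analysis survival --out surv.tsv
```

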