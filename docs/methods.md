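# Methods

## Relative exon usage

Exon-level counts for one gene are normalized in two steps. Per-exon RPKM,
`counts / (length_kb × million mapped reads)`, removes length and depth
effects; dividing by a per-sample gene-level reference then removes overall
gene-expression differences so that group comparisons reflect exon
*inclusion*. The reference is the mean exon RPKM of the gene in that sample
(default) or the sum (`mode="sum"`); the mean is the default because a
uniformly expressed gene then sits at relative usage 1.0 everywhere, which
makes the invariants (scale invariance, all-ones null) exact.

Normalization order is a genuine design choice: normalizing each sample
before averaging groups is the only order that cancels per-sample
expression differences, so it is the default; `literal_order=True` averages
the group RPKM profiles first and then gene-normalizes each group profile,
for comparison. The two agree closely on well-behaved cohorts and exactly
in the noise-free limit.

Degenerate cases are flagged, never silently fixed: non-positive lengths
or depths are validation errors naming the exon/sample; samples whose gene
reference is zero are excluded from group means with a warning; exons with
a zero normal-group mean get NaN ratios and are listed in `undefined`.

The estimator of the tumor/normal fold is a ratio of group means of
per-sample ratios, so it carries a small Jensen-type bias of order the
squared coefficient of variation of the gene reference divided by the
group size; at 200 samples per group this is well under the ±10% envelope
the recovery tests use.

## Invasive-front profiling

The segmentation follows the classic wound-healing quantification recipe.

*Thresholding.* The minimum-error (Kittler–Illingworth) criterion models
the 256-bin histogram as two Gaussians split at level *t* and minimizes
`J(t) = 1 + 2[P1 ln σ1 + P2 ln σ2] − 2[P1 ln P1 + P2 ln P2]`. The
criterion is minimized exhaustively over all admissible splits rather than
by the fixed-point iteration some tools use: exhaustive search is
deterministic and cannot fail to converge. Ties break to the lowest level.
Class variances are floored at 1/12 level² — the variance of a uniform
spread within one bin — so single-spike classes (e.g. noise-free synthetic
images) remain admissible. Near-flat criterion valleys can make two split
points tie to machine precision; any minimizer is then acceptable.

*Cleanup.* Holes inside the sheet ("small areas within the cell layer not
thresholded") are removed by n erosions then n dilations of the background
phase, which is exactly a binary closing of the cell phase with a 3×3
(8-connected) structuring element. The image border is padded by edge
replication during the closing so sheets touching the frame are not eroded
at the frame. Default n = 5, removing holes up to ~10 px across; the
original tool left this "predefined" count unspecified, so it is a
parameter.

*Front line.* The outline is the set of mask pixels 8-adjacent to
background; pixels on the first/last row or column are removed so only the
free edge remains. A mask that fills the image, or whose outline lies
entirely on the border, raises "no free edge found".

*Distance profile.* The original macro marched the front line inward in
0.2 µm steps; here every cell pixel gets its exact Euclidean distance
(center-to-center, µm) to the nearest front pixel via a distance
transform — the continuous limit of the marching construction — and is
assigned to left-closed bins [k·0.2, (k+1)·0.2) µm out to 180 µm (900
bins). This is verified exactly against a brute-force all-pairs search on
small images. Bins with no pixels are reported as missing (NaN mean, zero
count), never as zero intensity. Pixels are assumed isotropic; anisotropic
resolution tags are rejected. Each bin also records its mean pixel
distance, which profile fits use instead of the nominal bin center to
avoid discretization bias.

*Binned ratios.* 30 µm coarse bins aggregate fine bins by pixel-weighted
means (equal to direct per-pixel means over the annulus) and form
`mean(marker3)/mean(marker1)` per image. The confluent reference is the
same ratio over whole control images taken far from any edge. Bins whose
marker1 mean is zero are flagged undefined. Per-image intensities are not
normalized before the ratio — the ratio itself cancels shared scaling.
The bin-vs-confluent comparison pools per-image bin ratios and control
ratios into one Kruskal–Wallis + Dunn family.

## Cohort statistics

Kruskal–Wallis uses the standard tie correction; an all-identical pooled
sample is reported as H = 0, p = 1 by convention. Dunn's z compares mean
pooled mid-ranks with the tie-corrected variance term and two-sided normal
p-values; the adjustment default is Bonferroni (Holm and Šidák available)
since the original analyses state only "Dunn's correction". Spearman and
the log-rank test are delegated to scipy and lifelines respectively; the
Mantel–Cox statistic is additionally implemented in-package from the
hypergeometric risk-table identity to support exhaustive permutation
p-values (`exact=True`), which all rank tests offer for small samples —
the asymptotic p cannot match an enumeration at n ≤ 8, the exact variant
does.

Survival dichotomization by isoform ratio defaults to a median split
within the analyzed stratum (e.g. T1 tumors only), with an explicit
threshold option, because the original cut-off is not recoverable. The
t-test is the pooled-variance form, preceded by a variance-ratio F-test;
if the F-test rejects at 0.05 the t-test is still reported but flagged.

Ordinal fluorescence scores are coded absent/intermediate/high → 0/1/2;
any monotone coding gives identical rank tests. Two-rater tables are
resolved by averaging and rounding half up (default) or by strict
consensus that drops discordant cells with a warning.

## Synthetic data

The generators encode the study conditions and return machine-readable
ground truth.

*Exon counts.* `counts ~ NegBin(mean = length_kb × depth × expression ×
inclusion, dispersion)` via a Gamma–Poisson mixture; depth and expression
are log-normal across samples (50 M reads, dispersion 10, typical
bulk-RNA-seq values). The default gene has 8 constitutive exons, entry
exons 4.1/4.3 at inclusion 0.8 and cassette exons A–D near 0.3, with exon
B at 0.28 in normal vs 0.90 in tumor. The returned ground truth is the
expected *relative-usage* ratio `(incl_t/mean incl_t)/(incl_n/mean
incl_n)`, which differs from the raw inclusion fold (3.21 for exon B)
because the gene mean shifts with inclusion (3.04 for the single-effect
default; ≈3.27 when the entry exons are simultaneously halved).

*Front images.* The sheet occupies the frame up to a straight or
sinusoidal free edge. At true distance d µm from the edge, marker3 =
p₃ + A·exp(−d/λ) with λ = 20 µm (≈95 % decayed by 60 µm) and marker1 =
p₁·(1 − B·exp(−d/λ₂)) with λ₂ = 30 µm (≈96 % of plateau by 100 µm) —
the qualitative gradient shapes reported for migrating sheets. Noise is
Poisson shot noise plus additive Gaussian read noise (sd 5), giving an
amplitude-to-noise ratio near 10 at the front; pixel 0.5 µm, frame
400×400 px (200×200 µm, so the profile reaches ~150 µm of sheet depth and
the farthest coarse bin is reported missing). `confluent=True` renders the
far-field plateau everywhere — the control condition. The simulator
returns the true mask, true front line and exact distance field for oracle
tests.

*Cohort.* Ratios are log-normal per grade/size stratum (modest positive
shifts of 0.15 log units per step); survival is exponential (Weibull
optional) with hazard 0.02/month and a 2.5× hazard in the high-ratio arm;
censoring is independent exponential with its rate matched to the target
censored fraction. *Scores* are per-subregion multinomials, either uniform
(null) or the "invasion shift" preset (p120-1 lost in stromal invasion and
lymph nodes, high intravascular, p120-3 retained).

What the generators do **not** emulate: real cell texture, uneven
illumination, segmentation-confounding debris, batch effects, isoform
cross-bleed, or correlated censoring. Passing tests therefore demonstrate
correctness of the computational chain under the stated statistical
structure, not robustness to every imaging or cohort artifact.

## Problem sizes and numerical choices

Tests and the acceptance script use 200 samples/group exon cohorts, 10–20
images of 400×400 px, 2000-replicate null calibrations and 200-replicate
power runs — sizes at which Monte-Carlo error is comfortably inside the
asserted tolerances. The acceptance script averages the exon folds over 5
replicate cohorts to report the estimator's central value. All floats are
written with a pinned `%.10g` format and all randomness flows through
seeded `numpy` generators, making every output reproducible byte for byte.

## Known limitations

- The exon chain starts from a count table; it does not estimate PSI from
  junction reads or align anything.
- The front profiler handles a single free edge per image; images with
  multiple disjoint sheets will profile distance to the union of their
  edges.
- The erosion/dilation step count and the ratio dichotomization threshold
  are parameters the original study left unstated; defaults are documented
  choices, not recovered values.
- Dunn p-values use the normal approximation unless `exact=True`, which is
  exponential in sample size and intended for n ≲ 10.
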