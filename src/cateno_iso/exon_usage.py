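"""Relative exon usage and tumor/normal exon-expression ratios.

Quantifies alternative exon usage of a single gene (here: *CTNND1*, encoding
p120 catenin) from an exon-level read-count matrix.  The chain is

1. per-exon RPKM: counts / (exon length in kb x million mapped reads),
2. relative usage: exon RPKM divided by a per-sample gene-level reference
   (mean exon RPKM by default), which cancels overall gene-expression
   differences between samples,
3. group means and tumor/normal fold ratios per exon.

Relative usage is exactly invariant to rescaling all counts and the depth of
a sample by a common factor, and to multiplying every exon of a sample by a
constant — the property that makes exon ratios comparable across cohorts
with different gene expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExonCountTable",
    "ExonUsageTable",
    "ExonRatioResult",
    "rpkm_normalize",
    "relative_usage",
    "group_ratio",
    "exon_usage_pipeline",
]

GROUPS = ("tumor", "normal")


class ValidationError(ValueError):
    """Raised when an input table violates its schema invariants."""


@dataclass
class ExonCountTable:
    """Exon x sample integer read counts for one gene.

    Parameters
    ----------
    exon_ids : ordered exon identifiers, e.g. ``["4.1", "4.3", "A", "B"]``.
    gene_id : gene identifier the exons belong to.
    lengths_kb : exon lengths in kilobases (positive).
    counts : ``(n_exons, n_samples)`` non-negative integer matrix.
    sample_ids : sample identifiers, one per column.
    totals_million : per-sample total mapped reads in millions (positive).
    group_labels : per-sample label, each in ``{"tumor", "normal"}``.
    """

    exon_ids: list[str]
    gene_id: str
    lengths_kb: np.ndarray
    counts: np.ndarray
    sample_ids: list[str]
    totals_million: np.ndarray
    group_labels: np.ndarray

    def __post_init__(self) -> None:
        self.exon_ids = [str(e) for e in self.exon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.lengths_kb = np.asarray(self.lengths_kb, dtype=float)
        self.counts = np.asarray(self.counts)
        self.totals_million = np.asarray(self.totals_million, dtype=float)
        self.group_labels = np.asarray(self.group_labels, dtype=object)
        ne, ns = len(self.exon_ids), len(self.sample_ids)
        if self.counts.shape != (ne, ns):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{ne} exons x {ns} samples"
            )
        if len(set(self.sample_ids)) != ns:
            raise ValidationError("duplicated sample ids")
        if np.any(self.counts < 0):
            e, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count for exon {self.exon_ids[e]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        bad = np.flatnonzero(~(self.lengths_kb > 0))
        if bad.size:
            raise ValidationError(
                f"exon {self.exon_ids[bad[0]]!r} has non-positive length"
            )
        bad = np.flatnonzero(~(self.totals_million > 0))
        if bad.size:
            raise ValidationError(
                f"sample {self.sample_ids[bad[0]]!r} has non-positive "
                "total mapped reads"
            )
        unknown = set(self.group_labels) - set(GROUPS)
        if unknown:
            raise ValidationError(f"unknown group labels: {sorted(unknown)}")

    @property
    def n_exons(self) -> int:
        return len(self.exon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class ExonUsageTable:
    """Normalized exon expression: RPKM and gene-referenced relative usage."""

    exon_ids: list[str]
    sample_ids: list[str]
    group_labels: np.ndarray
    rpkm: pd.DataFrame
    relative_usage: pd.DataFrame | None = None
    mode: str | None = None
    #: samples whose gene-level reference was zero (excluded downstream)
    excluded_samples: list[str] = field(default_factory=list)


@dataclass
class ExonRatioResult:
    """Per-exon group means and tumor/normal fold ratios.

    ``ratios`` holds NaN for exons whose normal-group mean is zero; those
    exons are listed in ``undefined`` rather than dropped.
    """

    group_means: pd.DataFrame  # exon x group
    ratios: pd.Series  # exon -> tumor/normal fold
    undefined: list[str] = field(default_factory=list)


def rpkm_normalize(table: ExonCountTable) -> ExonUsageTable:
    """Reads per kilobase of exon per million mapped reads.

    ``rpkm[e, s] = counts[e, s] / (lengths_kb[e] * totals_million[s])``.
    """
    rpkm = table.counts / (
        table.lengths_kb[:, None] * table.totals_million[None, :]
    )
    return ExonUsageTable(
        exon_ids=table.exon_ids,
        sample_ids=table.sample_ids,
        group_labels=table.group_labels,
        rpkm=pd.DataFrame(rpkm, index=table.exon_ids, columns=table.sample_ids),
    )


def relative_usage(usage: ExonUsageTable, mode: str = "mean") -> ExonUsageTable:
    """Divide each sample's exon RPKMs by a gene-level reference.

    Parameters
    ----------
    mode : ``"mean"`` (default) uses the mean exon RPKM of the gene in the
        sample as reference, so a uniformly expressed gene sits at relative
        usage 1.0 everywhere; ``"sum"`` uses the summed exon RPKM.

    Samples whose reference is zero (gene not expressed) are flagged in
    ``excluded_samples`` with a warning and excluded from group means.
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"mode must be 'mean' or 'sum', got {mode!r}")
    ref = usage.rpkm.mean(axis=0) if mode == "mean" else usage.rpkm.sum(axis=0)
    excluded = list(ref.index[ref == 0])
    if excluded:
        warnings.warn(
            f"samples with zero gene-level reference excluded: {excluded}",
            UserWarning,
            stacklevel=2,
        )
    safe_ref = ref.replace(0, np.nan)
    rel = usage.rpkm / safe_ref
    return ExonUsageTable(
        exon_ids=usage.exon_ids,
        sample_ids=usage.sample_ids,
        group_labels=usage.group_labels,
        rpkm=usage.rpkm,
        relative_usage=rel,
        mode=mode,
        excluded_samples=excluded,
    )


def group_ratio(usage: ExonUsageTable) -> ExonRatioResult:
    """Average relative usage within tumor and normal groups and form
    per-exon tumor/normal fold ratios.

    Exons with a zero normal-group mean get a NaN ratio and are reported in
    ``undefined``; they are never silently dropped.
    """
    if usage.relative_usage is None:
        raise ValueError("relative_usage not computed; call relative_usage() first")
    keep = ~np.isin(usage.sample_ids, usage.excluded_samples)
    labels = usage.group_labels[keep]
    rel = usage.relative_usage.loc[:, keep]
    means = {}
    for g in GROUPS:
        cols = rel.loc[:, labels == g]
        if cols.shape[1] == 0:
            raise ValidationError(f"no valid samples in group {g!r}")
        means[g] = cols.mean(axis=1)
    group_means = pd.DataFrame(means)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = group_means["tumor"] / group_means["normal"]
    undefined = list(ratios.index[group_means["normal"] == 0])
    ratios[group_means["normal"] == 0] = np.nan
    return ExonRatioResult(
        group_means=group_means, ratios=ratios, undefined=undefined
    )


def exon_usage_pipeline(
    table: ExonCountTable, mode: str = "mean", literal_order: bool = False
) -> ExonRatioResult:
    """Full chain: RPKM -> relative usage -> group ratios.

    ``literal_order=True`` averages RPKM per group *before* the gene-level
    normalization (average first, then divide the group-mean exon profile by
    its gene reference).  The default order (per-sample normalization first)
    is the one that actually cancels per-sample gene-expression differences;
    the literal order is kept for comparison.
    """
    usage = rpkm_normalize(table)
    if not literal_order:
        usage = relative_usage(usage, mode=mode)
        return group_ratio(usage)
    means = {}
    for g in GROUPS:
        cols = usage.rpkm.loc[:, usage.group_labels == g]
        if cols.shape[1] == 0:
            raise ValidationError(f"no valid samples in group {g!r}")
        m = cols.mean(axis=1)
        ref = m.mean() if mode == "mean" else m.sum()
        if ref == 0:
            raise ValidationError(f"group {g!r} has zero gene-level signal")
        means[g] = m / ref
    group_means = pd.DataFrame(means)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = group_means["tumor"] / group_means["normal"]
    undefined = list(ratios.index[group_means["normal"] == 0])
    ratios[group_means["normal"] == 0] = np.nan
    return ExonRatioResult(
        group_means=group_means, ratios=ratios, undefined=undefined
    )
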