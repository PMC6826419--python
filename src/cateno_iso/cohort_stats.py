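"""Cohort and image statistics for isoform-ratio analyses.

Covers the statistical layer of the study design: gel-densitometry isoform
ratios, their association with ordinal tumor grade (Spearman) and size
category (Kruskal–Wallis + Dunn), survival comparison by ratio (Mantel–Cox
log-rank), the pooled-variance t-test with an F-test variance check, the
binned front-profile ratio test, and ordinal subregion-score comparisons.

All rank-based tests are tie-corrected.  For tiny samples every test offers
``exact=True``, which replaces the asymptotic p-value by exhaustive
permutation of group labels — the reference behaviour the asymptotics
approximate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lifelines.statistics import logrank_test as _lifelines_logrank

__all__ = [
    "KruskalDunnResult",
    "band_ratio",
    "kruskal_dunn",
    "spearman_assoc",
    "logrank",
    "ratio_vs_size",
    "survival_by_ratio",
    "ttest_with_f",
    "subregion_compare",
    "consensus_scores",
    "front_bins_vs_control",
    "SIZE_CATEGORIES",
    "SUBREGIONS",
    "SCORE_LEVELS",
]

SIZE_CATEGORIES = ("T1", "T2", "T3")
SUBREGIONS = (
    "normal gland",
    "in situ",
    "fibrous invasion",
    "adipose invasion",
    "intravascular",
    "lymph node",
)
SCORE_LEVELS = {"absent": 0, "intermediate": 1, "high": 2}


# --------------------------------------------------------------------------
# band densitometry

def band_ratio(bands: pd.DataFrame) -> pd.Series:
    """Per-sample p120-3/p120-1 band-intensity ratio.

    ``bands`` needs columns ``p120_1`` and ``p120_3`` (integrated densities,
    arbitrary units).  Samples with zero p120-1 intensity get NaN and a
    warning; they must be excluded downstream rather than treated as zero.
    """
    for col in ("p120_1", "p120_3"):
        if col not in bands.columns:
            raise ValueError(f"missing column {col!r}")
        if (bands[col] < 0).any():
            raise ValueError(f"negative intensity in {col!r}")
    denom = bands["p120_1"].astype(float)
    undefined = denom == 0
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} sample(s) with zero p120-1 intensity "
            "flagged undefined",
            UserWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = bands["p120_3"].astype(float) / denom
    ratio[undefined] = np.nan
    ratio.name = "ratio"
    return ratio


# --------------------------------------------------------------------------
# Kruskal–Wallis + Dunn

@dataclass
class KruskalDunnResult:
    H: float
    p: float
    dunn: pd.DataFrame  # columns: group_i, group_j, z, p_unadj, p_adj
    group_names: list[str] = field(default_factory=list)


def _tie_correction_sum(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def _kw_statistic(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal–Wallis H (0 by convention when every pooled
    value is identical)."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    tie = 1.0 - _tie_correction_sum(pooled) / (n**3 - n)
    if tie == 0.0:
        return 0.0
    return h / tie


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = len(p)
    if method == "none" or m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "sidak":
        return 1.0 - (1.0 - p) ** m
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def _label_permutations(sizes: list[int]):
    """Yield index tuples partitioning range(N) into groups of the given
    sizes (each distinct assignment once)."""
    n = sum(sizes)
    idx = list(range(n))

    def rec(remaining, sizes_left):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = [i for i in remaining if i not in combo]
            for tail in rec(rest, sizes_left[1:]):
                yield [list(combo)] + tail

    yield from rec(idx, sizes)


def kruskal_dunn(
    groups: list,
    adjust: str = "bonferroni",
    exact: bool = False,
    group_names: list[str] | None = None,
) -> KruskalDunnResult:
    """Tie-corrected Kruskal–Wallis test with Dunn's pairwise post hoc.

    Dunn's z for groups i, j compares mean pooled ranks,

        z = (Ri - Rj) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/ni + 1/nj)]

    with T = sum(t^3 - t) over tie groups; two-sided normal p-values are
    multiplicity-adjusted (Bonferroni default; holm/sidak/none available).

    ``exact=True`` replaces both the omnibus p and the unadjusted pairwise
    p-values by exhaustive label permutation (feasible for small samples).
    When all pooled values are identical, H = 0 and p = 1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if len(pooled) < 3:
        raise ValueError("need total n >= 3")
    names = group_names or [f"group{i + 1}" for i in range(len(groups))]

    all_identical = np.all(pooled == pooled[0])
    if all_identical:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
        h = float(h)

    # Dunn pairwise z on pooled mid-ranks
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    tie_sum = _tie_correction_sum(pooled)
    var_term = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p_u = 1.0 if se == 0 else 2.0 * stats.norm.sf(abs(z))
        rows.append((names[i], names[j], z, min(p_u, 1.0)))
    dunn = pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p_unadj"])

    if exact and not all_identical:
        h_obs = _kw_statistic(groups)
        z_obs = np.abs(dunn["z"].to_numpy())
        count_h = 0
        count_z = np.zeros(len(z_obs))
        total = 0
        pairs = list(itertools.combinations(range(len(groups)), 2))
        for part in _label_permutations(sizes):
            perm_groups = [pooled[ix] for ix in part]
            if _kw_statistic(perm_groups) >= h_obs - 1e-12:
                count_h += 1
            perm_ranks = stats.rankdata(pooled)  # ranks fixed; means vary
            pm = [perm_ranks[ix].mean() for ix in part]
            for k, (i, j) in enumerate(pairs):
                se = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
                zp = 0.0 if se == 0 else (pm[i] - pm[j]) / se
                if abs(zp) >= z_obs[k] - 1e-12:
                    count_z[k] += 1
            total += 1
        p = count_h / total
        dunn["p_unadj"] = count_z / total
        h = h_obs

    dunn["p_adj"] = _adjust(dunn["p_unadj"].to_numpy(), adjust)
    return KruskalDunnResult(H=float(h), p=float(p), dunn=dunn, group_names=names)


# --------------------------------------------------------------------------
# Spearman

@dataclass
class SpearmanResult:
    rho: float
    p: float
    undefined: bool = False


def spearman_assoc(x, y) -> SpearmanResult:
    """Tie-corrected Spearman rank correlation with two-sided p.

    Grade is ordinal, hence the rank correlation.  Constant input on either
    side leaves rho undefined (flagged, NaN)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman rho undefined", UserWarning,
                      stacklevel=2)
        return SpearmanResult(rho=np.nan, p=np.nan, undefined=True)
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p=float(p))


# --------------------------------------------------------------------------
# Mantel–Cox log-rank

@dataclass
class LogrankResult:
    chi2: float
    p: float
    undefined: bool = False


def _mantel_cox_chi2(times: np.ndarray, events: np.ndarray,
                     in_a: np.ndarray) -> float:
    """Mantel–Cox chi-square from the risk table at each distinct event
    time (hypergeometric expected events and variance)."""
    event_times = np.unique(times[events.astype(bool)])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = ((times == t) & events.astype(bool)).sum()
        d_a = ((times == t) & events.astype(bool) & in_a).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


def logrank(
    times_a, events_a, times_b, events_b, exact: bool = False
) -> LogrankResult:
    """Two-group Mantel–Cox (log-rank) test, chi-square with 1 df.

    With no events in either group the statistic is undefined (flagged).
    ``exact=True`` computes the p-value by exhaustive permutation of group
    membership (all subject-to-arm assignments of the observed sizes).
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("each group needs at least one subject")
    if not (ea.any() or eb.any()):
        warnings.warn("no events: log-rank statistic undefined", UserWarning,
                      stacklevel=2)
        return LogrankResult(chi2=np.nan, p=np.nan, undefined=True)
    if exact:
        times = np.concatenate([ta, tb])
        events = np.concatenate([ea, eb])
        in_a = np.zeros(len(times), dtype=bool)
        in_a[: len(ta)] = True
        chi2_obs = _mantel_cox_chi2(times, events, in_a)
        count = 0
        total = 0
        for combo in itertools.combinations(range(len(times)), len(ta)):
            perm = np.zeros(len(times), dtype=bool)
            perm[list(combo)] = True
            if _mantel_cox_chi2(times, events, perm) >= chi2_obs - 1e-12:
                count += 1
            total += 1
        return LogrankResult(chi2=float(chi2_obs), p=count / total)
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(chi2=float(res.test_statistic), p=float(res.p_value))


# --------------------------------------------------------------------------
# patient-record analyses

def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([vars(r) if not isinstance(r, dict) else r
                         for r in records])


def ratio_vs_size(records, adjust: str = "bonferroni") -> KruskalDunnResult:
    """Kruskal–Wallis (+ Dunn) of the isoform ratio across tumor size
    categories T1/T2/T3."""
    df = _records_frame(records).dropna(subset=["ratio"])
    groups, names = [], []
    for cat in SIZE_CATEGORIES:
        vals = df.loc[df["size_category"] == cat, "ratio"].to_numpy(float)
        if len(vals):
            groups.append(vals)
            names.append(cat)
    if len(groups) < 2:
        raise ValueError("need ratios in at least two size categories")
    return kruskal_dunn(groups, adjust=adjust, group_names=names)


def survival_by_ratio(
    records,
    split_rule: str = "median",
    threshold: float | None = None,
    size_category: str | None = None,
) -> LogrankResult:
    """Dichotomize patients by isoform ratio and compare survival curves.

    ``split_rule='median'`` cuts at the median ratio of the analyzed stratum
    (optionally restricted to one size category first, e.g. T1);
    ``split_rule='threshold'`` uses an explicit cut.  High-ratio arm =
    ratio > cut.
    """
    df = _records_frame(records).dropna(subset=["ratio"])
    if size_category is not None:
        df = df[df["size_category"] == size_category]
    if split_rule == "median":
        cut = float(df["ratio"].median())
    elif split_rule == "threshold":
        if threshold is None:
            raise ValueError("threshold split requires an explicit threshold")
        cut = float(threshold)
    else:
        raise ValueError(f"unknown split rule {split_rule!r}")
    high = df["ratio"] > cut
    if high.all() or (~high).all():
        raise ValueError("ratio split left one arm empty")
    a, b = df[high], df[~high]
    return logrank(
        a["survival_time"], a["event"], b["survival_time"], b["event"]
    )


# --------------------------------------------------------------------------
# t-test with F-test variance check

@dataclass
class TTestFResult:
    f: float
    f_p: float
    t: float
    p: float
    unequal_variance_warning: bool = False
    undefined: bool = False


def ttest_with_f(a, b, alpha: float = 0.05) -> TTestFResult:
    """Two-tailed pooled-variance Student t-test preceded by a variance-ratio
    F-test.  If the F-test rejects equal variances at ``alpha`` the t-test is
    still reported but carries a warning flag."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance and equal means: t undefined",
                          UserWarning, stacklevel=2)
            return TTestFResult(f=np.nan, f_p=np.nan, t=np.nan, p=np.nan,
                                undefined=True)
        f, f_p = np.nan, np.nan
    elif vb == 0 or va == 0:
        f, f_p = np.inf, 0.0
    else:
        f = va / vb
        dist = stats.f(len(a) - 1, len(b) - 1)
        f_p = 2.0 * min(dist.cdf(f), dist.sf(f))
        f_p = min(f_p, 1.0)
    flag = bool(np.isfinite(f_p) and f_p < alpha) or f_p == 0.0
    if flag:
        warnings.warn(
            "F-test rejects equal variances; pooled t-test may be invalid",
            UserWarning, stacklevel=2,
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestFResult(f=float(f), f_p=float(f_p), t=float(t), p=float(p),
                        unequal_variance_warning=flag)


# --------------------------------------------------------------------------
# ordinal subregion scores

def _coded(scores: pd.Series) -> pd.Series:
    if scores.dtype == object:
        return scores.map(SCORE_LEVELS).astype(float)
    return scores.astype(float)


def consensus_scores(
    table: pd.DataFrame, rule: str = "average"
) -> pd.DataFrame:
    """Resolve two-rater ordinal scores into one ``score`` column.

    ``rule='average'`` averages the coded scores and rounds half up;
    ``rule='strict'`` keeps only concordant cells, flagging the rest as NaN
    with a warning.  Tables already carrying a ``score`` column pass through.
    """
    df = table.copy()
    if "score" in df.columns:
        df["score"] = _coded(df["score"])
        return df
    r1, r2 = _coded(df["rater1"]), _coded(df["rater2"])
    if rule == "average":
        df["score"] = np.floor((r1 + r2) / 2.0 + 0.5)
    elif rule == "strict":
        agree = r1 == r2
        if not agree.all():
            warnings.warn(
                f"{int((~agree).sum())} discordant score(s) dropped under "
                "strict consensus", UserWarning, stacklevel=2,
            )
        df["score"] = np.where(agree, r1, np.nan)
    else:
        raise ValueError(f"unknown consensus rule {rule!r}")
    return df


def subregion_compare(
    table: pd.DataFrame,
    marker: str,
    adjust: str = "bonferroni",
    consensus: str = "average",
    exact: bool = False,
) -> KruskalDunnResult:
    """Kruskal–Wallis (+ Dunn) of ordinal fluorescence scores across tumor
    subregions for one marker.

    Scores are coded absent/intermediate/high -> 0/1/2 (any monotone coding
    gives identical rank tests).  Subregions without specimens are excluded
    with a warning.
    """
    df = consensus_scores(table, rule=consensus)
    df = df[df["marker"] == marker].dropna(subset=["score"])
    groups, names = [], []
    for sub in SUBREGIONS:
        vals = df.loc[df["subregion"] == sub, "score"].to_numpy(float)
        if len(vals):
            groups.append(vals)
            names.append(sub)
        elif sub in set(table.get("subregion", [])):
            warnings.warn(f"subregion {sub!r} has no usable specimens",
                          UserWarning, stacklevel=2)
    if len(groups) < 2:
        raise ValueError("need scores in at least two subregions")
    return kruskal_dunn(groups, adjust=adjust, exact=exact, group_names=names)


# --------------------------------------------------------------------------
# binned front-profile ratio test

def front_bins_vs_control(binned, adjust: str = "bonferroni") -> dict:
    """Compare per-image coarse-bin isoform ratios against the confluent
    reference (Kruskal–Wallis + Dunn across bins and control images).

    Returns the omnibus result plus the Dunn rows for each bin-vs-confluent
    comparison, keyed by bin label.
    """
    ratios = binned.ratios
    control = np.asarray(binned.control_ratios, dtype=float)
    if control.size == 0:
        raise ValueError("no control images: confluent reference missing")
    groups, names = [], []
    for col in ratios.columns:
        vals = ratios[col].dropna().to_numpy(float)
        if len(vals):
            groups.append(vals)
            names.append(str(col))
    groups.append(control)
    names.append("confluent")
    res = kruskal_dunn(groups, adjust=adjust, group_names=names)
    vs_control = {}
    for _, row in res.dunn.iterrows():
        pair = {row["group_i"], row["group_j"]}
        if "confluent" in pair:
            (bin_name,) = pair - {"confluent"}
            vs_control[bin_name] = row
    return {"omnibus": res, "vs_control": vs_control}
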