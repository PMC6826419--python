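"""Synthetic-data generators for every analysis stage.

The generators produce inputs with the statistical structure the analyses
assume — a multi-exon gene with alternative entry-point and cassette exons
whose inclusion differs between tumor and normal tissue, a noisy fluorescence
image of a migrating cell sheet with distance-dependent marker gradients, a
patient cohort with ratio-dependent survival, and ordinal subregion score
tables — together with their machine-readable ground truth, so recovery can
be tested without any external download.

All randomness flows through ``numpy.random.default_rng(seed)``; the same
seed reproduces every output bit for bit.

Default parameter choices mirror the study conditions: exon B inclusion
0.28 (normal) vs 0.90 (tumor) and entry exons at 0.8, marker3 decaying from
the front with length scale 20 µm (≈95 % decayed by 60 µm) and marker1
rising to its plateau with length scale 30 µm (≈96 % of plateau by 100 µm).
Image noise is Poisson shot noise on the signal plus additive Gaussian read
noise, the standard fluorescence camera model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .exon_usage import ExonCountTable
from .front_profile import FrontImage, FrontLine
from .cohort_stats import SIZE_CATEGORIES, SUBREGIONS

__all__ = [
    "ExonSimConfig",
    "FrontSimConfig",
    "CohortSimConfig",
    "simulate_exon_counts",
    "simulate_front_image",
    "simulate_cohort",
    "simulate_scores",
    "FrontSimResult",
]


# --------------------------------------------------------------------------
# exon counts

@dataclass
class ExonSimConfig:
    """Negative-binomial exon-count simulator for one gene.

    ``counts[e, s] ~ NB(mean = length_kb[e] * depth[s] * expr[s] *
    inclusion[group(s), e], dispersion)``; sequencing depth (million reads)
    and gene expression are log-normal across samples.
    """

    exon_ids: tuple = (
        "3", "4.1", "4.3", "5", "6", "7", "A", "B", "C", "D",
        "15", "16", "17", "18",
    )
    lengths_kb: tuple = (
        0.20, 0.12, 0.09, 0.25, 0.18, 0.22, 0.10, 0.13, 0.08, 0.11,
        0.24, 0.19, 0.21, 0.30,
    )
    #: per-exon inclusion probability in normal tissue
    inclusion_normal: tuple = (
        1.0, 0.8, 0.8, 1.0, 1.0, 1.0, 0.30, 0.28, 0.30, 0.30,
        1.0, 1.0, 1.0, 1.0,
    )
    #: per-exon inclusion probability in tumor tissue
    inclusion_tumor: tuple = (
        1.0, 0.8, 0.8, 1.0, 1.0, 1.0, 0.30, 0.90, 0.30, 0.30,
        1.0, 1.0, 1.0, 1.0,
    )
    gene_id: str = "CTNND1"
    n_per_group: int = 200
    #: log-normal gene expression across samples (log-scale mean and sd)
    expr_log_mean: float = np.log(40.0)
    expr_log_sd: float = 0.5
    #: log-normal sequencing depth in million mapped reads
    depth_log_mean: float = np.log(50.0)
    depth_log_sd: float = 0.3
    nb_dispersion: float = 10.0

    def validate(self) -> None:
        n = len(self.exon_ids)
        if not (len(self.lengths_kb) == len(self.inclusion_normal)
                == len(self.inclusion_tumor) == n):
            raise ValueError("per-exon fields must have equal length")
        for incl in (self.inclusion_normal, self.inclusion_tumor):
            if not all(0.0 <= x <= 1.0 for x in incl):
                raise ValueError("inclusions must lie in [0, 1]")
        if not all(l > 0 for l in self.lengths_kb):
            raise ValueError("exon lengths must be positive")
        if not self.nb_dispersion > 0:
            raise ValueError("dispersion must be positive")
        if self.n_per_group < 1:
            raise ValueError("need at least one sample per group")

    def with_fold_change(self, exon: str, fold: float) -> "ExonSimConfig":
        """Copy of the config with one exon's tumor inclusion set to
        ``fold`` times its normal inclusion (clipped to 1)."""
        idx = list(self.exon_ids).index(exon)
        tumor = list(self.inclusion_normal)
        tumor[idx] = min(tumor[idx] * fold, 1.0)
        return ExonSimConfig(
            exon_ids=self.exon_ids, lengths_kb=self.lengths_kb,
            inclusion_normal=self.inclusion_normal,
            inclusion_tumor=tuple(tumor), gene_id=self.gene_id,
            n_per_group=self.n_per_group,
            expr_log_mean=self.expr_log_mean, expr_log_sd=self.expr_log_sd,
            depth_log_mean=self.depth_log_mean, depth_log_sd=self.depth_log_sd,
            nb_dispersion=self.nb_dispersion,
        )


def _neg_bin(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Gamma–Poisson mixture: var = mean + mean^2 / dispersion."""
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 1e-12) / dispersion)
    return rng.poisson(lam)


def simulate_exon_counts(
    cfg: ExonSimConfig, seed: int = 0
) -> tuple[ExonCountTable, dict]:
    """Draw an exon-count table and return it with its ground truth.

    The ground truth carries the exact expected tumor/normal relative-usage
    ratio per exon: ``(incl_t/mean(incl_t)) / (incl_n/mean(incl_n))`` — the
    quantity the analysis chain estimates (it differs from the raw inclusion
    fold change by the shift in the gene-level mean).
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    incl = {
        "tumor": np.asarray(cfg.inclusion_tumor, dtype=float),
        "normal": np.asarray(cfg.inclusion_normal, dtype=float),
    }
    lengths = np.asarray(cfg.lengths_kb, dtype=float)
    n = cfg.n_per_group
    labels = np.array(["tumor"] * n + ["normal"] * n, dtype=object)
    depth = rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd, size=2 * n)
    expr = rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sd, size=2 * n)
    mean = (
        lengths[:, None]
        * depth[None, :]
        * expr[None, :]
        * np.stack([incl[g] for g in labels], axis=1)
    )
    counts = _neg_bin(rng, mean, cfg.nb_dispersion)
    table = ExonCountTable(
        exon_ids=list(cfg.exon_ids),
        gene_id=cfg.gene_id,
        lengths_kb=lengths,
        counts=counts,
        sample_ids=[f"{g[0].upper()}{i:03d}" for i, g in enumerate(labels)],
        totals_million=depth,
        group_labels=labels,
    )
    rel = {g: incl[g] / incl[g].mean() for g in ("tumor", "normal")}
    truth = {
        "expected_ratio": dict(
            zip(cfg.exon_ids, (rel["tumor"] / rel["normal"]).tolist())
        ),
        "inclusion_fold": dict(
            zip(cfg.exon_ids, (incl["tumor"] / incl["normal"]).tolist())
        ),
    }
    return table, truth


# --------------------------------------------------------------------------
# front images

@dataclass
class FrontSimConfig:
    """Migrating-sheet image simulator.

    The sheet occupies the left part of the frame up to a straight or
    sinusoidal free edge.  Inside the sheet, at true distance ``d`` (µm)
    from the edge,

        marker3(d) = p3 + A * exp(-d / lambda_um)
        marker1(d) = p1 * (1 - B * exp(-d / lambda2_um))

    ``confluent=True`` fills the whole frame with sheet at its far-field
    (plateau) intensities — the control condition imaged >= 1 mm from any
    edge.
    """

    shape: tuple = (400, 400)
    pixel_size_um: float = 0.5
    front: str = "straight"  # or "sinusoidal"
    front_frac: float = 0.75  # edge position as fraction of image width
    amplitude_um: float = 8.0
    period_um: float = 60.0
    # marker gradients
    p3: float = 50.0
    amp3: float = 100.0
    lambda_um: float = 20.0
    p1: float = 120.0
    deficit1: float = 0.6
    lambda2_um: float = 30.0
    # structural channel
    fg_mean: float = 200.0
    bg_mean: float = 20.0
    # noise
    gaussian_sd: float = 5.0
    poisson: bool = True
    confluent: bool = False

    def validate(self) -> None:
        if not (self.lambda_um > 0 and self.lambda2_um > 0):
            raise ValueError("decay lengths must be positive")
        if not self.fg_mean > self.bg_mean:
            raise ValueError("foreground mean must exceed background mean")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel size must be positive")
        if self.front not in ("straight", "sinusoidal"):
            raise ValueError(f"unknown front geometry {self.front!r}")
        if not self.confluent and not 0.0 < self.front_frac < 1.0:
            raise ValueError("front must leave background in the frame")


@dataclass
class FrontSimResult:
    image: FrontImage
    true_mask: np.ndarray
    true_front: FrontLine | None
    true_distance_um: np.ndarray | None
    clean_channels: dict[str, np.ndarray]
    config: FrontSimConfig = field(repr=False, default=None)


def _true_front_line(mask: np.ndarray) -> FrontLine:
    s8 = np.ones((3, 3), dtype=bool)
    outline = mask & ndimage.binary_dilation(~mask, structure=s8, border_value=0)
    outline[0, :] = outline[-1, :] = False
    outline[:, 0] = outline[:, -1] = False
    return FrontLine(coords=np.argwhere(outline))


def simulate_front_image(cfg: FrontSimConfig, seed: int = 0) -> FrontSimResult:
    """Render a sheet image with its true mask, front line and distance
    field (exact Euclidean distance to the true front, in µm)."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    h, w = cfg.shape
    yy, xx = np.mgrid[0:h, 0:w]
    if cfg.confluent:
        mask = np.ones((h, w), dtype=bool)
        front = None
        dist = None
        d_for_markers = np.full((h, w), np.inf)
    else:
        x_edge = cfg.front_frac * (w - 1)
        if cfg.front == "sinusoidal":
            amp_px = cfg.amplitude_um / cfg.pixel_size_um
            per_px = cfg.period_um / cfg.pixel_size_um
            x_edge = x_edge + amp_px * np.sin(2 * np.pi * yy[:, 0] / per_px)
            mask = xx <= x_edge[:, None]
        else:
            mask = xx <= x_edge
        if mask.all() or not mask.any():
            raise ValueError("front geometry leaves no background")
        front = _true_front_line(mask)
        seedmap = np.ones((h, w), dtype=bool)
        seedmap[front.coords[:, 0], front.coords[:, 1]] = False
        dist = ndimage.distance_transform_edt(seedmap) * cfg.pixel_size_um
        d_for_markers = dist

    with np.errstate(over="ignore"):
        m3 = cfg.p3 + cfg.amp3 * np.exp(-d_for_markers / cfg.lambda_um)
        m1 = cfg.p1 * (1.0 - cfg.deficit1 * np.exp(-d_for_markers / cfg.lambda2_um))
    bg3 = 0.1 * cfg.p3
    bg1 = 0.1 * cfg.p1
    clean = {
        "structural": np.where(mask, cfg.fg_mean, cfg.bg_mean).astype(float),
        "marker3": np.where(mask, m3, bg3),
        "marker1": np.where(mask, m1, bg1),
    }
    channels = {}
    for role, img in clean.items():
        noisy = img
        if cfg.poisson:
            noisy = rng.poisson(np.maximum(img, 0.0)).astype(float)
        if cfg.gaussian_sd > 0:
            noisy = noisy + rng.normal(0.0, cfg.gaussian_sd, size=img.shape)
        channels[role] = noisy
    image = FrontImage(channels=channels, pixel_size_um=cfg.pixel_size_um)
    return FrontSimResult(
        image=image, true_mask=mask, true_front=front,
        true_distance_um=dist, clean_channels=clean, config=cfg,
    )


# --------------------------------------------------------------------------
# patient cohort

@dataclass
class CohortSimConfig:
    """Patient-cohort simulator with ratio-dependent exponential survival.

    Isoform ratios are log-normal per grade/size stratum; patients in the
    high-ratio arm (above the cohort median) carry hazard
    ``baseline_hazard * hazard_ratio``.  Censoring is independent
    exponential with rate tuned so the expected censored fraction under the
    baseline hazard equals ``censoring_rate``.
    """

    n_patients: int = 200
    grade_probs: tuple = (0.30, 0.45, 0.25)
    size_probs: tuple = (0.40, 0.40, 0.20)
    ratio_log_mu: float = 0.0
    ratio_log_sd: float = 0.5
    #: additive log-ratio shift per grade step above 2 and size step above T2
    grade_effect: float = 0.15
    size_effect: float = 0.15
    baseline_hazard: float = 0.02  # events per month
    hazard_ratio: float = 2.5
    censoring_rate: float = 0.2
    survival_model: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.5

    def validate(self) -> None:
        if not self.baseline_hazard > 0:
            raise ValueError("hazard must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring rate must lie in [0, 1)")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.survival_model not in ("exponential", "weibull"):
            raise ValueError(f"unknown survival model {self.survival_model!r}")


def simulate_cohort(cfg: CohortSimConfig, seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Draw patient records (ratio, grade, size, survival) plus ground truth
    (true hazard ratio and arm assignment)."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = cfg.n_patients
    grade = rng.choice([1, 2, 3], size=n, p=np.asarray(cfg.grade_probs) /
                       np.sum(cfg.grade_probs))
    size_idx = rng.choice([0, 1, 2], size=n, p=np.asarray(cfg.size_probs) /
                          np.sum(cfg.size_probs))
    mu = (cfg.ratio_log_mu + cfg.grade_effect * (grade - 2)
          + cfg.size_effect * (size_idx - 1))
    ratio = rng.lognormal(mu, cfg.ratio_log_sd)
    high = ratio > np.median(ratio)
    hazard = cfg.baseline_hazard * np.where(high, cfg.hazard_ratio, 1.0)
    if cfg.survival_model == "exponential":
        t_event = rng.exponential(1.0 / hazard)
    else:
        # Weibull with proportional hazards: S(t) = exp(-(h t)^k)
        t_event = rng.weibull(cfg.weibull_shape) / hazard
    if cfg.censoring_rate > 0:
        mu_c = cfg.baseline_hazard * cfg.censoring_rate / (1 - cfg.censoring_rate)
        t_cens = rng.exponential(1.0 / mu_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    records = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "ratio": ratio,
        "grade": grade,
        "size_category": [SIZE_CATEGORIES[i] for i in size_idx],
        "survival_time": time,
        "event": event,
    })
    truth = {
        "hazard_ratio": cfg.hazard_ratio,
        "baseline_hazard": cfg.baseline_hazard,
        "high_arm": high.tolist(),
        "grade_effect": cfg.grade_effect,
        "size_effect": cfg.size_effect,
    }
    return records, truth


# --------------------------------------------------------------------------
# ordinal scores

#: per-subregion multinomial over (absent, intermediate, high) mirroring the
#: observed pattern: p120-1 lost in stromal invasion and lymph-node
#: metastases but high in intravascular cells; p120-3 retained throughout.
_INVASION_SHIFT = {
    "p120_1": {
        "normal gland": (0.05, 0.25, 0.70),
        "in situ": (0.10, 0.30, 0.60),
        "fibrous invasion": (0.60, 0.30, 0.10),
        "adipose invasion": (0.60, 0.30, 0.10),
        "intravascular": (0.05, 0.15, 0.80),
        "lymph node": (0.60, 0.30, 0.10),
    },
    "p120_3": {sub: (0.10, 0.30, 0.60) for sub in SUBREGIONS},
    "E-cadherin": {
        "normal gland": (0.05, 0.25, 0.70),
        "in situ": (0.10, 0.30, 0.60),
        "fibrous invasion": (0.40, 0.40, 0.20),
        "adipose invasion": (0.40, 0.40, 0.20),
        "intravascular": (0.10, 0.30, 0.60),
        "lymph node": (0.40, 0.40, 0.20),
    },
}


def simulate_scores(
    n_per_subregion: int = 10,
    pattern: str = "null",
    seed: int = 0,
    markers: tuple = ("p120_1", "p120_3", "E-cadherin"),
) -> tuple[pd.DataFrame, dict]:
    """Draw ordinal fluorescence scores per specimen x subregion x marker.

    ``pattern='null'`` uses a uniform multinomial everywhere;
    ``pattern='invasion_shift'`` uses the preset in which p120-1 is reduced
    in invasive subregions and lymph nodes but high intravascularly.
    """
    rng = np.random.default_rng(seed)
    if pattern == "null":
        probs = {m: {sub: (1 / 3, 1 / 3, 1 / 3) for sub in SUBREGIONS}
                 for m in markers}
    elif pattern == "invasion_shift":
        probs = {m: _INVASION_SHIFT[m] for m in markers}
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    rows = []
    for marker in markers:
        for sub in SUBREGIONS:
            p = np.asarray(probs[marker][sub], dtype=float)
            if p.min() < 0 or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"invalid multinomial for {marker}/{sub}")
            draws = rng.choice([0, 1, 2], size=n_per_subregion, p=p)
            for i, s in enumerate(draws):
                rows.append((f"S{i:03d}", sub, marker, int(s)))
    table = pd.DataFrame(rows, columns=["specimen", "subregion", "marker",
                                        "score"])
    return table, {"pattern": pattern, "probs": {
        m: {s: list(v) for s, v in d.items()} for m, d in probs.items()}}
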