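"""Readers/writers for TIFF images and TSV/CSV tables, plus pipeline config.

Conventions: 0-based pixel indices in row-major (y, x) order; TSV for exon
and profile tables, CSV for cohort and score tables; all floats written with
a pinned ``%.10g`` format so reruns with the same seed/config are
byte-identical.  Writers prepend a comment header with the tool version and
a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .exon_usage import ExonCountTable, ExonRatioResult, ValidationError
from .front_profile import (
    CHANNEL_ROLES,
    BinnedRatioProfile,
    DistanceProfile,
    FrontImage,
)

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_image",
    "write_image",
    "read_exon_table",
    "write_exon_table",
    "write_ratio_result",
    "read_cohort",
    "write_cohort",
    "read_scores",
    "write_scores",
    "write_profile",
    "write_binned_ratios",
    "config_hash",
]

log = logging.getLogger("cateno_iso")

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Stage parameters shared across the pipeline; unknown keys rejected."""

    n_steps: int = 5
    step_um: float = 0.2
    max_um: float = 180.0
    coarse_bin_um: float = 30.0
    gene_reference_mode: str = "mean"
    split_rule: str = "median"
    dunn_adjust: str = "bonferroni"
    seed: int = 0
    pixel_size_um: float | None = None
    channel_roles: dict | None = None

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if not (self.step_um > 0 and self.max_um >= self.step_um):
            raise ValueError("invalid distance binning")
        if self.gene_reference_mode not in ("mean", "sum"):
            raise ValueError("gene_reference_mode must be mean or sum")
        if self.split_rule not in ("median", "threshold"):
            raise ValueError("split_rule must be median or threshold")
        if self.dunn_adjust not in ("bonferroni", "holm", "sidak", "none"):
            raise ValueError("unknown dunn_adjust")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config, rejecting unknown keys by name."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def config_hash(cfg) -> str:
    payload = json.dumps(asdict(cfg) if not isinstance(cfg, dict) else cfg,
                         sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(cfg_digest: str | None = None) -> str:
    h = f"# cateno-iso {__version__}"
    if cfg_digest:
        h += f" config_hash={cfg_digest}"
    return h + "\n"


# --------------------------------------------------------------------------
# images

_CM_PER_UM = 1e-4


def write_image(path: str | Path, image: FrontImage,
                channel_order: list[str] | None = None) -> list[str]:
    """Write channels as a (C, Y, X) TIFF stack with a centimeter-based
    resolution tag encoding the pixel size; returns the channel order."""
    order = channel_order or [r for r in CHANNEL_ROLES if r in image.channels]
    stack = np.stack([image.channels[r] for r in order]).astype(np.float32)
    ppcm = 1.0 / (image.pixel_size_um * _CM_PER_UM)
    tifffile.imwrite(path, stack, resolution=(ppcm, ppcm),
                     resolutionunit="CENTIMETER",
                     photometric="minisblack", planarconfig="separate")
    return order


def read_image(
    path: str | Path,
    channel_map: dict[str, int],
    pixel_size_um: float | None = None,
) -> FrontImage:
    """Read a multichannel TIFF and map channel indices to roles.

    Pixel size comes from ``pixel_size_um`` (config) or, failing that, from
    the TIFF resolution tags; when both exist and disagree the config value
    wins and a warning is logged.
    """
    if "structural" not in channel_map:
        raise ValueError("channel_map must assign a 'structural' channel")
    unknown = set(channel_map) - set(CHANNEL_ROLES)
    if unknown:
        raise ValueError(f"unknown channel roles: {sorted(unknown)}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        page = tif.pages[0]
        tag_px = None
        res = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is not None and unit is not None:
            num, den = res.value
            if num > 0:
                per_unit = num / den
                unit_val = getattr(unit.value, "value", unit.value)
                if unit_val == 3:  # centimeter
                    tag_px = 1.0 / (per_unit * _CM_PER_UM)
                elif unit_val == 2:  # inch
                    tag_px = 25400.0 / per_unit
                if tag_px is not None and yres is not None:
                    ynum, yden = yres.value
                    if ynum > 0 and not np.isclose(ynum / yden, per_unit,
                                                   rtol=1e-6):
                        raise ValueError("anisotropic pixels are not supported")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected 2-D channels, got array of ndim {arr.ndim}")
    px = pixel_size_um
    if px is None:
        px = tag_px
    elif tag_px is not None and not np.isclose(px, tag_px, rtol=1e-3):
        log.warning(
            "pixel size: config %.6g um overrides TIFF tag %.6g um", px, tag_px
        )
    if px is None:
        raise ValueError("pixel size missing: give pixel_size_um or a "
                         "resolution-tagged TIFF")
    channels = {}
    for role, idx in channel_map.items():
        if not 0 <= idx < arr.shape[0]:
            raise ValueError(f"channel index {idx} for role {role!r} out of "
                             f"range (stack has {arr.shape[0]})")
        channels[role] = arr[idx].astype(float)
    return FrontImage(channels=channels, pixel_size_um=float(px))


# --------------------------------------------------------------------------
# exon tables

def write_exon_table(counts_path: str | Path, samples_path: str | Path,
                     table: ExonCountTable, cfg_digest: str | None = None) -> None:
    cdf = pd.DataFrame(table.counts, columns=table.sample_ids)
    cdf.insert(0, "exon_id", table.exon_ids)
    cdf.insert(1, "gene_id", table.gene_id)
    cdf.insert(2, "length_kb", table.lengths_kb)
    with open(counts_path, "w") as fh:
        fh.write(_header(cfg_digest))
        cdf.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)
    sdf = pd.DataFrame({
        "sample": table.sample_ids,
        "group": table.group_labels,
        "total_million": table.totals_million,
    })
    with open(samples_path, "w") as fh:
        fh.write(_header(cfg_digest))
        sdf.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_exon_table(counts_path: str | Path,
                    samples_path: str | Path) -> ExonCountTable:
    cdf = pd.read_csv(counts_path, sep="\t", comment="#")
    sdf = pd.read_csv(samples_path, sep="\t", comment="#")
    for col in ("exon_id", "gene_id", "length_kb"):
        if col not in cdf.columns:
            raise ValidationError(f"counts table missing column {col!r}")
    for col in ("sample", "group", "total_million"):
        if col not in sdf.columns:
            raise ValidationError(f"samples table missing column {col!r}")
    sample_ids = [c for c in cdf.columns
                  if c not in ("exon_id", "gene_id", "length_kb")]
    if sdf["sample"].duplicated().any():
        dup = sdf.loc[sdf["sample"].duplicated(), "sample"].iloc[0]
        raise ValidationError(f"duplicated sample id {dup!r}")
    sdf = sdf.set_index("sample")
    missing = [s for s in sample_ids if s not in sdf.index]
    if missing:
        raise ValidationError(f"samples absent from samples table: {missing}")
    counts = cdf[sample_ids].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValidationError("non-numeric counts")
    neg = np.argwhere(counts < 0)
    if len(neg):
        raise ValidationError(
            f"negative count at row {int(neg[0][0])}, "
            f"sample {sample_ids[int(neg[0][1])]!r}"
        )
    genes = cdf["gene_id"].unique()
    if len(genes) != 1:
        raise ValidationError(f"expected a single gene, got {list(genes)}")
    return ExonCountTable(
        exon_ids=list(cdf["exon_id"].astype(str)),
        gene_id=str(genes[0]),
        lengths_kb=cdf["length_kb"].to_numpy(float),
        counts=counts,
        sample_ids=sample_ids,
        totals_million=sdf.loc[sample_ids, "total_million"].to_numpy(float),
        group_labels=sdf.loc[sample_ids, "group"].to_numpy(object),
    )


def write_ratio_result(path: str | Path, result: ExonRatioResult,
                       cfg_digest: str | None = None) -> None:
    df = result.group_means.copy()
    df["ratio"] = result.ratios
    df["undefined"] = [e in result.undefined for e in df.index]
    df.index.name = "exon_id"
    with open(path, "w") as fh:
        fh.write(_header(cfg_digest))
        df.to_csv(fh, sep="\t", float_format=FLOAT_FMT)


# --------------------------------------------------------------------------
# cohort / score tables

_COHORT_COLS = ["patient_id", "ratio", "grade", "size_category",
                "survival_time", "event"]


def write_cohort(path: str | Path, records: pd.DataFrame,
                 cfg_digest: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg_digest))
        records[_COHORT_COLS].to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _COHORT_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns {missing}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"duplicated patient id {dup!r}")
    bad = df.index[~df["grade"].isin([1, 2, 3])]
    if len(bad):
        raise ValidationError(f"invalid grade at row {int(bad[0])}")
    bad = df.index[~df["size_category"].isin(["T1", "T2", "T3"])]
    if len(bad):
        raise ValidationError(f"invalid size category at row {int(bad[0])}")
    bad = df.index[df["survival_time"] < 0]
    if len(bad):
        raise ValidationError(f"negative survival time at row {int(bad[0])}")
    df["event"] = df["event"].astype(bool)
    return df


def write_scores(path: str | Path, table: pd.DataFrame,
                 cfg_digest: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg_digest))
        table.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in ("specimen", "subregion", "marker"):
        if col not in df.columns:
            raise ValidationError(f"score table missing column {col!r}")
    if "score" not in df.columns and not {"rater1", "rater2"} <= set(df.columns):
        raise ValidationError("score table needs 'score' or 'rater1'+'rater2'")
    for col in ("score", "rater1", "rater2"):
        if col in df.columns and df[col].dtype != object:
            bad = df.index[~df[col].isin([0, 1, 2])]
            if len(bad):
                raise ValidationError(
                    f"score outside {{0,1,2}} at row {int(bad[0])}"
                )
    return df


# --------------------------------------------------------------------------
# profiles

def write_profile(path: str | Path, profile: DistanceProfile,
                  cfg_digest: str | None = None) -> None:
    df = pd.DataFrame({
        "bin_center_um": profile.bin_centers_um,
        "mean_distance_um": profile.mean_distance_um,
    })
    for role in profile.mean_intensity.columns:
        df[f"mean_{role}"] = profile.mean_intensity[role].to_numpy()
    df["n_pixels"] = profile.pixel_count
    with open(path, "w") as fh:
        fh.write(_header(cfg_digest))
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def write_binned_ratios(path: str | Path, binned: BinnedRatioProfile,
                        cfg_digest: str | None = None) -> None:
    df = binned.ratios.copy()
    df.index.name = "image"
    with open(path, "w") as fh:
        fh.write(_header(cfg_digest))
        fh.write(f"# confluent_reference={binned.confluent_reference:.10g}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FMT)
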