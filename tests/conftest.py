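import numpy as np
import pytest

from cateno_iso import (
    ExonCountTable,
    FrontImage,
    FrontSimConfig,
    simulate_front_image,
)


@pytest.fixture
def two_exon_table() -> ExonCountTable:
    """Two exons, two samples, depths chosen for round RPKM numbers."""
    return ExonCountTable(
        exon_ids=["A", "B"],
        gene_id="G",
        lengths_kb=[0.5, 1.0],
        counts=[[100, 200], [100, 100]],
        sample_ids=["s1", "s2"],
        totals_million=[10.0, 10.0],
        group_labels=["tumor", "normal"],
    )


@pytest.fixture
def half_plane_image() -> FrontImage:
    """100x100 image, cells fill the left half (columns 0..49), 1 um/px."""
    actin = np.full((100, 100), 10.0)
    actin[:, 50:] = 200.0  # background bright? no: cells bright
    actin = np.where(actin == 10.0, 200.0, 20.0)
    return FrontImage(channels={"structural": actin}, pixel_size_um=1.0)


@pytest.fixture
def noise_free_front():
    cfg = FrontSimConfig(gaussian_sd=0.0, poisson=False)
    return simulate_front_image(cfg, seed=0)
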