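import numpy as np
import pytest
import scipy.sparse as sp

from spatgonad import (
    SpatialSample,
    default_blueprint,
    normalize,
    qc_filter,
    simulate_section,
)


def make_sample(coords, counts, gene_ids=None, sample_id="toy", stage="E30"):
    """Small dense-counts helper for hand-constructed sections."""
    coords = np.asarray(coords, dtype=int)
    counts = np.asarray(counts)
    if gene_ids is None:
        gene_ids = [f"G{i}" for i in range(counts.shape[0])]
    pixel_ids = [f"{x}x{y}" for x, y in coords]
    return SpatialSample(
        pixel_ids=pixel_ids,
        coords=coords,
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        sample_id=sample_id,
        stage=stage,
    )


@pytest.fixture(scope="session")
def small_blueprint():
    """Desk-scale blueprint for generator unit tests: 64x64 circular
    section (~3.2k tissue pixels), 60 germ pixels per stage."""
    return default_blueprint(
        seed=11,
        grid_width=64,
        grid_height=64,
        germ_counts={
            "E24": {"Mitotic_PGC": 60},
            "E27": {"Mitotic_PGC": 50, "RA_Oogonia": 10},
            "E30": {"Mitotic_PGC": 25, "RA_Oogonia": 35},
            "E35": {"Mitotic_PGC": 10, "RA_Oogonia": 40, "Meiotic_Oogonia": 10},
            "E50": {"RA_Oogonia": 30, "Meiotic_Oogonia": 30},
        },
        n_background_genes=80,
    )


@pytest.fixture(scope="session")
def small_section(small_blueprint):
    return simulate_section(small_blueprint, "E30", seed=5)


@pytest.fixture(scope="session")
def small_norm(small_section):
    sample, _truth = small_section
    return normalize(qc_filter(sample, 100))


@pytest.fixture(scope="session")
def null_blueprint():
    """All folds at 1: no marker enrichment, no module activity."""
    return default_blueprint(
        seed=21,
        grid_width=64,
        grid_height=64,
        marker_fold=1.0,
        module_spec={
            "BMP": (["BMP2", "BMP4", "ID1", "ID2", "ID3", "SMAD6"],
                    ("outer_cortex", "inner_cortex"), 1.0),
            "RA": (["ALDH1A1", "RDH10", "CRABP1", "CRABP2", "CYP26B1"],
                   ("inner_cortex",), 1.0),
        },
        germ_counts={s: {} for s in ("E24", "E27", "E30", "E35", "E50")},
        migration_enabled=False,
        n_background_genes=80,
    )


@pytest.fixture(scope="session")
def null_section(null_blueprint):
    return simulate_section(null_blueprint, "E30", seed=7)
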