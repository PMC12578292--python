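import numpy as np
import pandas as pd
import pytest

from isoscan import matrix, simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(
        seed=7,
        n_genes=20,
        n_cells_per_group={"normal": 60, "cancer": 60},
        planted_apa=[simulate.PlantedAPA("G0001", -50.0, "cancer")],
        planted_das=[simulate.PlantedDAS("G0002", "SE", 0.3, "cancer")],
        planted_dtu=[
            simulate.PlantedDTU(
                "G0003", {"normal": (0.8, 0.2), "cancer": (0.2, 0.8)}
            )
        ],
        n_mutation_sites=4,
        error_rate=0.02,
        coverage_mean=12.0,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate.simulate_bundle(small_config)


@pytest.fixture(scope="session")
def small_nm(small_bundle):
    _, em, _, _ = small_bundle
    return matrix.normalize_expression(em, level="isoform")


def toy_matrix(counts, feature_ids, cell_ids, genes=None, meta=None):
    """Construct an ExpressionMatrix with minimal metadata."""
    from isoscan.models import ExpressionMatrix

    counts = np.asarray(counts)
    if genes is None:
        genes = feature_ids
    if meta is None:
        meta = pd.DataFrame(
            {
                "patient": ["P1"] * len(cell_ids),
                "batch": ["b1"] * len(cell_ids),
                "tissue": ["t"] * len(cell_ids),
                "group": ["g"] * len(cell_ids),
                "cell_type": ["ct"] * len(cell_ids),
            },
            index=cell_ids,
        )
    return ExpressionMatrix(
        counts, feature_ids, cell_ids, pd.Series(genes, index=feature_ids), meta
    )
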