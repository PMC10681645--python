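import numpy as np
import pandas as pd
import pytest

from morphoconn.synthetic_cohort import (AtlasGeometry, CohortSpec,
                                         generate_atlas, generate_cohort)


@pytest.fixture(scope="session")
def small_atlas() -> AtlasGeometry:
    return generate_atlas(20, seed=1)


@pytest.fixture(scope="session")
def planted_cohort():
    """A 25/group cohort on 40 regions with 6 planted effect regions (d=1).

    Session-scoped: several statistical tests reuse it read-only.
    Returns (atlas, feature tables, covariates, planted region ids).
    """
    atlas = generate_atlas(40, seed=11)
    planted = frozenset(range(1, 7))
    spec = CohortSpec(n_per_group=(25, 25, 25), n_regions=40, n_features=47,
                      effect_regions=planted, effect_size=1.0, seed=12)
    tables, covariates = generate_cohort(atlas, spec)
    return atlas, tables, covariates, planted


@pytest.fixture(scope="session")
def planted_rmcs(planted_cohort):
    """RMCS table + covariates for the planted cohort."""
    from morphoconn.r2sn import cohort_rmcs

    _, tables, covariates, planted = planted_cohort
    rmcs, mask = cohort_rmcs(tables)
    return rmcs, covariates, planted


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def grf_map(coords: np.ndarray, length: float, seed: int,
            kernel: str = "gaussian") -> np.ndarray:
    """Helper: one Gaussian-random-field map over the given centroids."""
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(coords))
    K = (np.exp(-0.5 * (D / length) ** 2) if kernel == "gaussian"
         else np.exp(-D / length))
    L = np.linalg.cholesky(K + 1e-8 * np.eye(len(coords)))
    return L @ np.random.default_rng(seed).standard_normal(len(coords))
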