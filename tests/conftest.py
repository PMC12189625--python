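import numpy as np
import pytest

from nichecast import GridSpec
from nichecast import maxent_core as mx
from nichecast import synthetic_data as synth

#: Candidate set used by the recovery tests: the two true drivers plus four
#: partly correlated nuisance variables.
RECOVERY_CANDIDATES = [
    "temperature_ltmin",
    "velocity_mean",
    "salinity_mean",
    "productivity_mean",
    "nitrate_mean",
    "salinity_ltmin",
]


@pytest.fixture(scope="session")
def grid():
    """Small 0.05-degree grid that tiles exactly into 0.2-degree blocks."""
    return GridSpec(
        origin_lon=124.025, origin_lat=32.025, cell_size=0.05, n_rows=40, n_cols=24
    )


@pytest.fixture(scope="session")
def study_grid():
    """Larger domain used by the recovery/selection tests."""
    return GridSpec(
        origin_lon=124.025, origin_lat=32.025, cell_size=0.05, n_rows=120, n_cols=80
    )


@pytest.fixture(scope="session")
def stack(grid):
    return synth.generate_env_stack(grid, seed=1)


@pytest.fixture(scope="session")
def masked_stack(grid):
    st = synth.generate_env_stack(grid, seed=1)
    _, mask = synth.generate_bathymetry_and_mask(
        grid, seed=8, turbid_region=(124.0, 33.4, 132.0, 34.0)
    )
    return synth.apply_mask(st, mask)


def build_study_system(study_grid, seed, n=300, candidates=RECOVERY_CANDIDATES):
    """One seeded synthetic study: masked stack, truth surface, deduplicated
    occurrences, presence design and a 5000-cell background design."""
    from nichecast import data_io

    st = synth.generate_env_stack(study_grid, seed=seed)
    _, mask = synth.generate_bathymetry_and_mask(
        study_grid, seed=seed + 7, turbid_region=(124.0, 40.4, 132.0, 44.0)
    )
    st = synth.apply_mask(st, mask)
    surf = synth.default_surface()
    occ = data_io.dedup_to_grid(
        synth.sample_occurrences(surf, st, n=n, seed=seed + 100), study_grid
    )
    pres, _ = data_io.extract_at_points(st, occ, candidates)
    bg = mx.sample_background(st, seed=seed, max_cells=5000, variables=candidates)
    return st, surf, occ, pres, bg


@pytest.fixture(scope="session")
def study_system(study_grid):
    return build_study_system(study_grid, seed=1)


@pytest.fixture(scope="session")
def binary_feature_toy():
    """Single binary feature: background half ones, presence mean 0.75.

    Closed-form optimum at beta=0: lambda = ln 3.
    """
    defs = [mx.FeatureDef("linear", "x", 0.0, 1.0)]
    F_b = np.r_[np.ones(25), np.zeros(25)].reshape(-1, 1)
    F_p = np.r_[np.ones(6), np.zeros(2)].reshape(-1, 1)
    return F_p, F_b, defs


@pytest.fixture(scope="session")
def fitted_toy_model(study_system):
    st, surf, occ, pres, bg = study_system
    vars2 = ["temperature_ltmin", "velocity_mean"]
    idx = [RECOVERY_CANDIDATES.index(v) for v in vars2]
    return (
        mx.fit_maxent_on_design(
            pres[:, idx], bg[:, idx], vars2, beta_multiplier=1.0, tol=1e-5
        ),
        pres[:, idx],
        bg[:, idx],
        vars2,
    )
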