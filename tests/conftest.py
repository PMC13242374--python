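"""Shared fixtures: a small synthetic market and analysis bundle.

The small market keeps unit tests fast; the default market (the package's
reference study conditions) is exercised in the acceptance tests.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hospchoice import SyntheticConfig, analyze_market, generate_market

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


SMALL = dict(n_zips=30, n_hospitals=8, n_patients=3000)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=7, **SMALL)


@pytest.fixture(scope="session")
def small_market(small_config):
    return generate_market(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_market):
    return analyze_market(small_market)


@pytest.fixture(scope="session")
def small_tables(small_market):
    """(patients, hospitals indexed by id with volume, centroids, distances)."""
    from hospchoice import build_distance_matrix, compute_hospital_volume

    patients = small_market.patients
    volumes = compute_hospital_volume(patients)
    hosp = small_market.hospitals.set_index("hospital_id").copy()
    hosp["volume"] = volumes.reindex(hosp.index).fillna(0).astype(int)
    hosp = hosp.loc[hosp["volume"] > 0]
    centroids = small_market.centroids
    distances = build_distance_matrix(centroids, patients["home_zip"].unique(), hosp["zip"])
    return patients, hosp, centroids, distances


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


def random_panel(rng, n_origins=20, n_dests=10, fill=0.6):
    """Unbalanced origin x destination panel with random y and x."""
    cells = [
        (f"Z{i}", f"H{j}")
        for i in range(n_origins)
        for j in range(n_dests)
        if rng.random() < fill
    ]
    # ensure every origin/destination appears at least once
    for i in range(n_origins):
        cells.append((f"Z{i}", f"H{rng.integers(n_dests)}"))
    for j in range(n_dests):
        cells.append((f"Z{rng.integers(n_origins)}", f"H{j}"))
    cells = sorted(set(cells))
    df = pd.DataFrame(cells, columns=["origin", "dest"])
    df["x"] = rng.normal(size=len(df))
    df["y"] = rng.normal(size=len(df))
    return df


def dummy_ols_slope(df, weights=None):
    """Independent oracle: slope of y on x with explicit two-way indicator
    variables, via numpy least squares."""
    O = pd.get_dummies(df["origin"]).to_numpy(dtype=float)
    D = pd.get_dummies(df["dest"]).to_numpy(dtype=float)[:, 1:]
    X = np.column_stack([df["x"].to_numpy(), O, D])
    y = df["y"].to_numpy(dtype=float)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        X = X * w[:, None]
        y = y * w
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[0])
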