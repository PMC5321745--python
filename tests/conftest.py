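"""Shared fixtures: tiny hand-checkable landscapes and a mid-sized
synthetic study reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from metacap.landscape import Landscape, quality_index
from metacap.synthetic_data import SynthConfig, generate_study


def make_landscape(xs, ys=None, areas=None, **quality):
    """Landscape from coordinate lists with constant default quality."""
    n = len(xs)
    cols = {
        "id": [f"p{i}" for i in range(n)],
        "x_km": xs,
        "y_km": ys if ys is not None else [0.0] * n,
        "area_ha": areas if areas is not None else [1.0] * n,
        "host_plantago": [1] * n,
        "host_veronica": [1] * n,
        "pct_dry": [0.5] * n,
        "pct_low": [0.5] * n,
        "pct_grazed": [0.5] * n,
    }
    cols.update(quality)
    return Landscape.from_patches(pd.DataFrame(cols))


def ring_landscape(n=60, radius=1.5, areas=None):
    """Vertex-transitive ring: every patch equivalent, so the mean-field
    equilibrium identity holds exactly."""
    th = 2 * np.pi * np.arange(n) / n
    return make_landscape(list(radius * np.cos(th)), list(radius * np.sin(th)),
                          areas=areas)


@pytest.fixture(scope="session")
def two_patch():
    return make_landscape([0.0, 3.0], [0.0, 4.0])  # 3-4-5: distance 5 km


@pytest.fixture(scope="session")
def ring60():
    land = ring_landscape()
    return land, quality_index(land)


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared by the integration-style tests."""
    return generate_study(SynthConfig(), seed=20260924)


@pytest.fixture(scope="session")
def small_study():
    cfg = SynthConfig(n_patches=200, n_clusters=4, cluster_spread_km=0.6,
                      domain_km=(12.0, 12.0), years=15, partial_years=3)
    return cfg, generate_study(cfg, seed=7)
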