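import numpy as np
import pandas as pd
import pytest

from avitrend.design import ModelDesign
from avitrend.synthetic import RegionSpec, generate_sites


@pytest.fixture(scope="session")
def small_region():
    return RegionSpec(extent=(0, 0, 25_000.0, 25_000.0),
                      survey_years=list(range(2000, 2008)))


@pytest.fixture(scope="session")
def small_sites(small_region):
    sites, landscape = generate_sites(small_region, n_per_year=60, seed=42)
    return sites, landscape


@pytest.fixture(scope="session")
def year_only_design():
    """Intercept + year-factor design on a minimal covariate table."""
    rng = np.random.default_rng(0)
    n, n_years = 400, 5
    sites = pd.DataFrame({
        "site_id": [f"S{i}" for i in range(n)],
        "year": np.repeat(np.arange(2000, 2000 + n_years), n // n_years),
        "elevation": rng.uniform(100, 900, n),
        "urban_2500": rng.uniform(0, 1, n),
        "forest_2500": rng.uniform(0, 1, n),
    })
    design = ModelDesign.build(sites, smooth_cols=[], linear_cols=[],
                               zero_cols=[], include_spatial=False)
    return sites, design
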