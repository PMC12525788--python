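import numpy as np
import pytest

from nirseed.io import SpectraSet
from nirseed.synthetic import SyntheticConfig, YearParams, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return np.arange(1100.0, 2500.0, 2.0)  # 700 points


@pytest.fixture
def tiny_set(small_grid, rng):
    n = 8
    return SpectraSet(
        wavelengths=small_grid,
        absorbance=rng.normal(0.5, 0.1, size=(n, small_grid.size)),
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        years=np.full(n, 2021),
        reference=rng.uniform(1.0, 15.0, size=n),
    )


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down three-year study for fast pipeline tests."""
    cfg = SyntheticConfig(
        years={
            2021: YearParams(n=60, mean=7.75, min=0.68, max=14.46),
            2022: YearParams(n=60, mean=12.0, min=1.74, max=17.30,
                             offset_scale=0.003),
            2023: YearParams(n=48, mean=8.75, min=1.08, max=13.49,
                             offset_scale=0.02),
        },
        seed=7,
    )
    return generate_study(cfg)
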