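import numpy as np
import pytest

from ibmd import RatingsTable, load_gymnasts, load_maternal_hr


@pytest.fixture(scope="session")
def gymnast_groups() -> dict[str, RatingsTable]:
    return load_gymnasts().split_groups()


@pytest.fixture(scope="session")
def maternal_groups() -> dict[str, RatingsTable]:
    return load_maternal_hr().split_groups()


@pytest.fixture()
def random_rows():
    """Factory for ragged positive-valued per-case rows."""

    def make(n_cases, seed, max_obs=5, allow_zero=False):
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(n_cases):
            m = int(rng.integers(2, max_obs + 1))
            vals = rng.uniform(0.0 if allow_zero else 0.5, 100.0, size=m)
            rows.append(vals.tolist())
        return rows

    return make
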