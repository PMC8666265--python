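import numpy as np
import pandas as pd
import pytest

from didsim import (
    BaselineConfig,
    ExposureSeries,
    Panel,
    generate_baseline,
)


@pytest.fixture(scope="session")
def default_baseline() -> Panel:
    """The package's default synthetic panel: 50 states x 18 years, seed 1."""
    return generate_baseline(BaselineConfig())


@pytest.fixture(scope="session")
def small_baseline() -> Panel:
    """A small, fast panel for estimator plumbing tests."""
    return generate_baseline(BaselineConfig(n_states=8, n_years=10, seed=4))


@pytest.fixture()
def toy_2x2():
    """Two states, two years, treated state exposed in the second year.

    The linear two-way fixed-effects estimate on this panel is the arithmetic
    double difference (15 - 10) - (9 - 8) = 4.
    """
    df = pd.DataFrame(
        {
            "state": ["T", "T", "C", "C"],
            "year": [2000, 2001, 2000, 2001],
            "population": [100_000] * 4,
            "crude_rate": [10.0, 15.0, 8.0, 9.0],
        }
    )
    panel = Panel.from_dataframe(df)
    A = pd.DataFrame(
        [[0.0, 0.0], [0.0, 1.0]],
        index=pd.Index(["C", "T"], name="state"),
        columns=pd.Index([2000, 2001], name="year"),
    )
    exposure = ExposureSeries(A=A, A_change=A.diff(axis=1))
    return panel, exposure


def make_panel(rates: np.ndarray, populations: np.ndarray, first_year: int = 2000,
               covariates: dict | None = None) -> Panel:
    """Panel from a states x years rate matrix and per-state populations."""
    n, T = rates.shape
    df = pd.DataFrame(
        {
            "state": np.repeat([f"S{i:02d}" for i in range(n)], T),
            "year": np.tile(np.arange(first_year, first_year + T), n),
            "population": np.repeat(populations, T),
            "crude_rate": rates.ravel(),
        }
    )
    for name, vals in (covariates or {}).items():
        df[name] = np.asarray(vals).ravel()
    return Panel.from_dataframe(df, validate=False)
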