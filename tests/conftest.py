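import numpy as np
import pytest
from hypothesis import settings

import surfopt as so

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_dataset() -> so.FactorialDataset:
    return so.load_fixture()


@pytest.fixture(scope="session")
def fixture_quadratic(fixture_dataset) -> so.PolynomialModel:
    return so.fit_ols(fixture_dataset, "quadratic")


def make_model(beta, family="quadratic", factors=so.DEFAULT_FACTORS) -> so.PolynomialModel:
    """A PolynomialModel with prescribed coefficients (no fitting)."""
    from surfopt.rsm import PolynomialModel, term_names

    terms = term_names(family)
    assert len(beta) == len(terms)
    return PolynomialModel(
        family=family,
        terms=terms,
        beta=np.asarray(beta, dtype=float),
        sse=0.0,
        sst=1.0,
        r2=1.0,
        adj_r2=1.0,
        df_resid=0,
        factors=tuple(factors),
    )
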