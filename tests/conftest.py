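import pandas as pd
import pytest

import gtrel


@pytest.fixture
def toy_df() -> pd.DataFrame:
    """Printed 3-persons x 2-trials table with scores 1..6."""
    return pd.DataFrame({
        "person": ["A", "A", "B", "B", "C", "C"],
        "trial": [1, 2, 1, 2, 1, 2],
        "score": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
    })


@pytest.fixture
def toy_table(toy_df) -> gtrel.ObservationTable:
    return gtrel.ObservationTable(toy_df)


@pytest.fixture
def one_facet_design() -> gtrel.DesignSpec:
    return gtrel.DesignSpec(facets=[gtrel.Facet("trial", "random")])


@pytest.fixture
def two_facet_design() -> gtrel.DesignSpec:
    return gtrel.DesignSpec(
        facets=[gtrel.Facet("trial", "random"),
                gtrel.Facet("occasion", "random")]
    )


@pytest.fixture
def splits_design() -> gtrel.DesignSpec:
    return gtrel.DesignSpec(
        facets=[gtrel.Facet("split", "random"),
                gtrel.Facet("trial", "random", nested_in="split")]
    )


def make_vcs(components, grand_mean=0.0, layout="one_facet", **kw):
    return gtrel.VarianceComponentSet(
        components=components, grand_mean=grand_mean, estimator="ems",
        layout=layout, **kw,
    )


@pytest.fixture
def two_facet_vcs() -> gtrel.VarianceComponentSet:
    """Hand-specified two-facet component set used in formula fixtures."""
    return make_vcs(
        {"p": 2.0, "po": 0.5, "pi": 1.0, "pio,e": 2.0,
         "o": 0.3, "i": 0.4, "oi": 0.1},
        layout="two_facet",
    )


@pytest.fixture
def splits_vcs() -> gtrel.VarianceComponentSet:
    return make_vcs(
        {"p": 1.0, "ps": 0.2, "p(i:s),e": 1.0, "s": 0.1, "i:s": 0.3},
        layout="splits",
    )
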