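import numpy as np
import pandas as pd
import pytest

from lakeews import standardise as st
from lakeews import synthetic_lakes as sl


@pytest.fixture(scope="session")
def fold_lake():
    """One fold-bifurcation lake (collapse + driver relaxation)."""
    return sl.make_lake("fold_demo", sl.MechanismSpec("fold_bifurcation", seed=3))


@pytest.fixture(scope="session")
def stationary_lake():
    return sl.make_lake("flat_demo", sl.MechanismSpec("stationary", seed=3))


@pytest.fixture
def toy_records():
    """Small raw long-format record set with a missing observation and an
    unidentified taxon."""
    return pd.DataFrame(
        {
            "lake": ["L1"] * 7,
            "date": pd.to_datetime(
                [
                    "2000-01-05",
                    "2000-01-12",
                    "2000-02-03",
                    "2000-03-01",
                    "2000-01-05",
                    "2000-02-03",
                    "2000-03-01",
                ]
            ),
            "taxon": ["Daphnia pulex"] * 4
            + ["unidentified flagellate", "Asterionella formosa", "Asterionella formosa"],
            "trophic_level": ["zooplankton"] * 4 + ["phytoplankton"] * 3,
            "density": [2.0, 4.0, 3.0, 5.0, 9.0, 1.0, 2.0],
            "genus": ["Daphnia"] * 4 + ["?", "Asterionella", "Asterionella"],
        }
    )


def yearly_dataset(lake, level="phytoplankton"):
    """Helper: assemble the yearly community × driver dataset for one level."""
    return st.assemble_lake_dataset(
        lake.yearly[level], lake.drivers_yearly, lake.name, level, "yearly"
    )
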