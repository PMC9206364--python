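import numpy as np
import pandas as pd
import pytest

from cardiomr.io import AssociationTable


def make_table(rows, trait="trait", unit=""):
    """Build an AssociationTable from a list of dicts with defaults."""
    defaults = {
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.25,
        "se": 0.01,
        "pvalue": 1e-9,
        "n": 100_000,
    }
    df = pd.DataFrame([{**defaults, **row} for row in rows])
    return AssociationTable(df, trait=trait, unit=unit)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def simple_pair():
    """Three-SNP exposure/outcome tables already on the same effect allele."""
    exposure = make_table(
        [
            {"rsid": "rs1", "beta": 0.10, "se": 0.005},
            {"rsid": "rs2", "beta": 0.20, "se": 0.005},
            {"rsid": "rs3", "beta": 0.15, "se": 0.005},
        ],
        trait="exposure",
    )
    outcome = make_table(
        [
            {"rsid": "rs1", "beta": 0.05, "se": 0.01},
            {"rsid": "rs2", "beta": 0.10, "se": 0.01},
            {"rsid": "rs3", "beta": 0.075, "se": 0.01},
        ],
        trait="outcome",
    )
    return exposure, outcome
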