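import numpy as np
import pandas as pd
import pytest


def make_samples(rows):
    """Build a canonical sample table from (dataset, station, date, taxon,
    stage, abundance, ind_mass, biomass) tuples; None = missing."""
    df = pd.DataFrame(
        rows,
        columns=[
            "dataset",
            "station",
            "date",
            "taxon",
            "stage",
            "abundance",
            "ind_mass",
            "biomass",
        ],
    )
    df["date"] = pd.to_datetime(df["date"])
    for col in ("abundance", "ind_mass", "biomass"):
        df[col] = pd.to_numeric(df[col])
    return df


@pytest.fixture
def traits_df():
    """Small registry covering every functional class the indicators use."""
    rows = [
        ("Acartia spp.", "copepod", True, False, False),
        ("Cyclopoida", "copepod", False, False, False),
        ("Bosmina maritima", "cladoceran", False, False, True),
        ("Cercopagis pengoi", "cladoceran", False, True, False),
        ("Synchaeta spp.", "rotifer", False, False, True),
        ("Fritillaria borealis", "appendicularian", False, False, True),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "taxon",
            "major_group",
            "is_calanoid",
            "is_predatory_cladoceran",
            "is_microphagous",
        ],
    ).set_index("taxon")


@pytest.fixture
def samples_builder():
    return make_samples
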