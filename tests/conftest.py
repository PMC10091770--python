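from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from palaeodiv.occurrences import S1_COLUMNS, OccurrenceTable
from palaeodiv.synthetic import SyntheticConfig
from palaeodiv.timescale import (CompositeInterval, load_default_scheme,
                                 load_default_timescale)

_DEFAULTS = {
    "occurrence_id": "", "genus": "Genus", "species": "species",
    "qualifier": "none", "locality_name": "Locality", "latitude": 10.0,
    "longitude": 20.0, "country": "United Kingdom", "region": "UK & Ireland",
    "geological_unit": "Some Fm", "stage": "Serpukhovian", "substage": "",
    "max_ma": np.nan, "min_ma": np.nan, "environment": "marine",
    "material": "body", "authority": "Smith", "year_described": 1900,
}


def make_table(rows: list[dict]) -> OccurrenceTable:
    """Build an OccurrenceTable from partial row dicts with sane defaults."""
    full = []
    for i, row in enumerate(rows):
        r = dict(_DEFAULTS)
        r["occurrence_id"] = f"o{i + 1}"
        r.update(row)
        full.append(r)
    df = pd.DataFrame(full, columns=S1_COLUMNS)
    df["year_described"] = pd.array(df["year_described"], dtype="Int64")
    return OccurrenceTable(df)


@pytest.fixture(scope="session")
def ts():
    return load_default_timescale()


@pytest.fixture(scope="session")
def equal_length(ts):
    return load_default_scheme(ts)


@pytest.fixture()
def toy_intervals():
    """Three contiguous 10-Myr bins, 330-300 Ma."""
    return [
        CompositeInterval("I1", "I1", (("stage", "A"),), 330.0, 320.0),
        CompositeInterval("I2", "I2", (("stage", "B"),), 320.0, 310.0),
        CompositeInterval("I3", "I3", (("stage", "C"),), 310.0, 300.0),
    ]


def small_synthetic_config(rng: np.random.Generator,
                           intervals, seed: int) -> SyntheticConfig:
    """A small randomised generator configuration for oracle checks."""
    regions = {
        "UK & Ireland": (50.0, 59.0, -10.0, 1.0),
        "North America": (28.0, 60.0, -120.0, -70.0),
    }
    richness = {iv.id: int(rng.integers(3, 25)) for iv in intervals}
    rate = {(iv.id, r): float(rng.uniform(0.5, 6.0))
            for iv in intervals for r in regions}
    return SyntheticConfig(
        intervals=list(intervals), regions=regions,
        true_genus_richness=richness, locality_rate=rate,
        p_indeterminate=float(rng.uniform(0, 0.2)),
        p_scales_only=float(rng.uniform(0, 0.15)),
        seed=seed)
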