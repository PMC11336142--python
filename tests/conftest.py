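import numpy as np
import pandas as pd
import pytest

from npbclock.datamodel import CohortPanel, TraitSpec


def make_panel(rows, registry, extra_cols=()):
    """Build a CohortPanel from (id, year, age, days, {trait: value}) tuples."""
    records = []
    for ind, year, age, days, traits in rows:
        rec = {
            "individual_id": ind,
            "year_index": year,
            "age_start": age,
            "observation_days": days,
        }
        rec.update(traits)
        records.append(rec)
    df = pd.DataFrame(records)
    for t in registry:
        if t.name not in df.columns:
            df[t.name] = np.nan
    return CohortPanel(df, registry)


@pytest.fixture
def simple_registry():
    return (
        TraitSpec("trait_c00", "continuous"),
        TraitSpec("trait_b00", "binary"),
        TraitSpec("trait_m00", "categorical3"),
    )


@pytest.fixture
def simple_panel(simple_registry):
    rows = [
        ("F001", 0, 4.0, 120, {"trait_c00": 1.0, "trait_b00": 0.0, "trait_m00": 2.0}),
        ("F001", 1, 5.0, 200, {"trait_c00": 2.0, "trait_b00": 1.0, "trait_m00": 1.0}),
        ("F002", 0, 6.0, 90, {"trait_c00": 3.0, "trait_b00": 1.0, "trait_m00": 0.0}),
    ]
    return make_panel(rows, simple_registry)
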