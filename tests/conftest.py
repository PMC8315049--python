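import numpy as np
import pandas as pd
import pytest

import cartisec as cs
from cartisec.preprocess import (
    filter_all_replicates,
    filter_min_fraction,
    impute_half_min,
    log2_transform,
    presence_mask,
    sum_over_timepoints,
)

pytest_plugins = ()


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic dataset (456 proteins, planted groups)."""
    return cs.simulate_dataset(cs.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def processed(default_sim):
    """The preprocessing chain applied to the default dataset."""
    table, truth, annotation = default_sim
    filtered = filter_min_fraction(filter_all_replicates(table))
    mask = presence_mask(filtered)
    imputed = impute_half_min(filtered)
    return {
        "filtered": filtered,
        "mask": mask,
        "imputed": imputed,
        "summed": sum_over_timepoints(imputed),
        "log2": log2_transform(imputed),
        "truth": truth,
        "annotation": annotation,
    }


@pytest.fixture(scope="session")
def contrast_records(processed):
    return cs.run_contrasts(processed["summed"], list(cs.CANONICAL_CONTRASTS))


@pytest.fixture(scope="session")
def roster():
    return cs.load_table1_roster()


@pytest.fixture
def tiny_table():
    """A small handmade long table: 2 proteins, 3 animals, 1 treatment."""
    rows = []
    for protein, base in [("ALPHA", 8.0), ("BETA", 100.0)]:
        for animal in ("A1", "A2", "A3"):
            for day in cs.DAYS:
                rows.append((protein, animal, "N", day, base + day))
    df = pd.DataFrame(
        rows, columns=["protein", "animal", "treatment", "day", "abundance"]
    )
    return cs.AbundanceTable(df)


def make_table(records):
    """Build an AbundanceTable from (protein, animal, treatment, day, value)."""
    df = pd.DataFrame(
        records, columns=["protein", "animal", "treatment", "day", "abundance"]
    )
    return cs.AbundanceTable(df)
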