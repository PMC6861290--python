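import numpy as np
import pandas as pd
import pytest

from rhizonet import (
    CountTable,
    SampleMetadata,
    SVAttributes,
    SyntheticScenario,
    TaxonomyTable,
    simulate_experiment,
)
from rhizonet.containers import RANKS


@pytest.fixture(scope="session")
def small_scenario():
    return SyntheticScenario(n_genera={"bacteria": 30, "fungi": 10}, seed=42)


@pytest.fixture(scope="session")
def small_experiment(small_scenario):
    return simulate_experiment(small_scenario)


@pytest.fixture
def toy_table():
    """3 features x 3 samples with hand-checkable totals."""
    df = pd.DataFrame(
        [[1, 2, 2], [3, 4, 0], [1, 2, 3]],
        index=["f1", "f2", "f3"],
        columns=["s1", "s2", "s3"],
    )
    return CountTable(df)


def make_taxonomy(rows: dict) -> TaxonomyTable:
    """rows: feature -> partial rank dict; unlisted ranks are missing."""
    data = {fid: {r: partial.get(r, np.nan) for r in RANKS} for fid, partial in rows.items()}
    return TaxonomyTable(pd.DataFrame.from_dict(data, orient="index", columns=list(RANKS)))


def make_metadata(groups: dict) -> SampleMetadata:
    """groups: sample -> treatment group like 'mono_A' (or 'soil')."""
    rows = {}
    for sid, group in groups.items():
        if group == "soil":
            rows[sid] = {"variety": "-", "cropping": "-", "group": "soil", "sample_type": "soil"}
        else:
            cropping, variety = group.split("_")
            rows[sid] = {
                "variety": variety,
                "cropping": cropping,
                "group": group,
                "sample_type": "root",
            }
    return SampleMetadata(pd.DataFrame.from_dict(rows, orient="index"))


def make_attrs(lengths: dict, controls: set = frozenset()) -> SVAttributes:
    return SVAttributes(
        pd.DataFrame(
            {
                "length": pd.Series(lengths),
                "is_control": pd.Series({f: f in controls for f in lengths}),
            }
        )
    )
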