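import numpy as np
import pandas as pd
import pytest

from spiralpref import geometry
from spiralpref.features import feature_table


@pytest.fixture(scope="session")
def catalog():
    return geometry.catalog()


@pytest.fixture(scope="session")
def catalog_map(catalog):
    return {s.stimulus_id: s for s in catalog}


@pytest.fixture(scope="session")
def features_tbl(catalog):
    return feature_table(catalog)


@pytest.fixture(scope="session")
def printed_pair_counts():
    """Published pairwise win counts of the three four-turn stimuli (n=79)."""
    w = pd.DataFrame(0, index=["AR", "L1", "GO"], columns=["AR", "L1", "GO"])
    w.loc["L1", "AR"], w.loc["AR", "L1"] = 51, 28
    w.loc["L1", "GO"], w.loc["GO", "L1"] = 47, 32
    w.loc["GO", "AR"], w.loc["AR", "GO"] = 50, 29
    return w


def make_choices(rankings):
    """Choice table for participants with given rankings (or 'cycle')."""
    pairs = [("AR", "L1"), ("L1", "GO"), ("AR", "GO")]
    rows = []
    for i, ranking in enumerate(rankings):
        pid = f"p{i:03d}"
        for left, right in pairs:
            if ranking == "cycle":
                cyc = {("AR", "L1"): "AR", ("L1", "GO"): "L1", ("AR", "GO"): "GO"}
                chosen = cyc[(left, right)]
            else:
                chosen = left if ranking.index(left) < ranking.index(right) else right
            rows.append((pid, left, right, chosen))
    return pd.DataFrame(rows, columns=["participant_id", "left", "right", "chosen"])
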