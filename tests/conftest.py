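import numpy as np
import pandas as pd
import pytest

from aquassembly.io import AbundanceTable, GenePresenceMatrix


@pytest.fixture
def toy_table():
    """Four samples, three taxa, rows summing to one."""
    ab = np.array(
        [
            [0.6, 0.4, 0.0],
            [0.2, 0.4, 0.4],
            [0.5, 0.5, 0.0],
            [0.1, 0.2, 0.7],
        ]
    )
    return AbundanceTable(["s1", "s2", "s3", "s4"], ["a", "b", "c"], ab)


@pytest.fixture
def toy_metadata():
    return pd.DataFrame(
        {
            "region": ["Tibet", "Tibet", "Qilian", "Qilian"],
            "ecosystem": ["river", "river", "river", "wetland"],
            "latitude": [31.0, 32.0, 37.0, 38.0],
            "longitude": [88.0, 89.0, 99.0, 100.0],
            "altitude_m": [4500.0, 4400.0, 3200.0, 3100.0],
            "temperature": [4.0, 5.0, 10.0, np.nan],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )


@pytest.fixture
def toy_genes():
    presence = np.array(
        [
            [1, 1, 1, 0],
            [0, 1, 1, 1],
            [1, 0, 0, 0],
            [0, 0, 0, 0],
        ],
        dtype=bool,
    )
    return GenePresenceMatrix(
        ["s1", "s2", "s3", "s4"], ["g1", "g2", "g3", "g4"], presence
    )
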