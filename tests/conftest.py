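import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from sagmag.io_model import RankedTaxonomy


def make_genomes(rows) -> pd.DataFrame:
    """Build a validated genomes frame from compact row dicts."""
    defaults = {
        "collection": "SAG",
        "taxonomy": RankedTaxonomy(domain="Bacteria").to_string(),
        "completeness": 80.0,
        "contamination": 1.0,
        "sample_id": "s0",
        "depth_m": 10.0,
        "latitude_deg": 0.0,
        "region_flag": "open_ocean",
    }
    out = []
    for i, row in enumerate(rows):
        record = {"genome_id": f"G{i:03d}", **defaults, **row}
        out.append(record)
    return pd.DataFrame(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def genomes_small():
    return make_genomes([
        {"collection": "SAG", "completeness": 92.0},
        {"collection": "SAG", "completeness": 61.0},
        {"collection": "MAG", "completeness": 75.0},
        {"collection": "MAG", "completeness": 55.0},
        {"collection": "ISOLATE", "completeness": 99.0},
    ])
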