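import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from inventario.occurrence import RECORD_COLUMNS

_DEFAULTS = {
    "taxon_raw": "Aus primus",
    "year": 1960.0,
    "month": 7.0,
    "day": 16.0,
    "lat": np.nan,
    "lon": np.nan,
    "state": "Estado",
    "municipality": "",
    "locality": "La Loma",
    "source": "portal_a",
}


def make_records(rows):
    """Canonical record frame from partial row dicts (missing fields defaulted)."""
    filled = []
    for row in rows:
        merged = {**_DEFAULTS, **row}
        merged.setdefault("taxon", merged["taxon_raw"])
        filled.append(merged)
    frame = pd.DataFrame(filled, columns=RECORD_COLUMNS)
    frame["taxon_resolved"] = True
    return frame


@pytest.fixture
def records_factory():
    return make_records


@pytest.fixture
def square_boundary():
    """A 1-degree square boundary polygon."""
    return box(-100.0, 19.0, -99.0, 20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
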