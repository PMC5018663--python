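"""Published reference catalogs of well-inventoried Mexican bird sites.

Three small tables ship with the package, transcribed from the published
national-scale catalog of sites whose pre-1980 avifaunal inventories are
demonstrably complete (C >= 0.8):

- 95 well-inventoried 0.05-degree grid cells,
- 5 rescued non-georeferenced localities,
- 20 sampling hotspots.

Each row carries the incidence summary (N, S_obs, a, b) alongside the
printed S_exp and C, so the tables double as an external cross-check of the
Chao2 implementation: recomputing the estimates from the printed
frequencies must reproduce the printed values at their reporting precision.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_cells", "load_rescued_localities", "load_hotspots"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("inventario.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_cells() -> pd.DataFrame:
    """The 95 well-inventoried grid cells (state, name, center, N, S_obs, a, b, S_exp, C)."""
    return _load("well_inventoried_cells.csv")


def load_rescued_localities() -> pd.DataFrame:
    """The 5 well-inventoried non-georeferenced localities."""
    return _load("rescued_localities.csv")


def load_hotspots() -> pd.DataFrame:
    """The 20 well-inventoried sampling hotspots."""
    return _load("hotspot_summaries.csv")
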