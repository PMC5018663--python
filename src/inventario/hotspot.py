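"""Detection of sampling hotspots with the Getis-Ord Gi* statistic.

Gi* asks, for each grid cell, whether the cell and its neighborhood hold an
unusually large share of the global total.  With binary spatial weights
w_ij (1 for neighbors within the distance band, including the cell itself)
the standard score for cell i over values x_1..x_n is

    z_i = (sum_j w_ij x_j - xbar * W_i)
          / (S * sqrt((n * W_i - W_i^2) / (n - 1)))

where W_i = sum_j w_ij, xbar and S are the global mean and (population)
standard deviation.  Under spatial randomness z_i is approximately standard
normal.  Only positive z (concentrations of sampling, not gaps) can be
significant here; cells passing the significance screen are merged into
hotspots as connected components under queen (8-neighbor) contiguity.

The defaults — fixed distance band of 1.5 grid steps (the queen
neighborhood), self included, Benjamini-Hochberg FDR control at
alpha = 1 - confidence — are declared, reproducible stand-ins for the
undocumented band-selection heuristics of GUI hot-spot tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grid import CellId, GridSpec, cell_area_km2
from .richness import IncidenceSummary, summarize_incidence

__all__ = [
    "WeightsScheme",
    "Hotspot",
    "gi_star",
    "significant_cells",
    "merge_contiguous",
    "hotspot_completeness",
]


@dataclass(frozen=True)
class WeightsScheme:
    """Binary spatial weights for Gi*.

    ``band`` is measured in grid steps (multiples of the resolution) between
    cell centers; 1.5 captures exactly the queen neighborhood.  ``kind``
    "contiguity" is shorthand for a queen band.  Gi* (as opposed to Gi)
    includes the focal cell, so ``include_self`` defaults to True.
    """

    kind: str = "fixed-distance-band"
    band: float = 1.5
    include_self: bool = True

    def neighbor_offsets(self) -> list[tuple[int, int]]:
        band = 1.5 if self.kind == "contiguity" else self.band
        radius = int(math.floor(band + 1e-9))
        offsets = []
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                if dr == 0 and dc == 0:
                    if self.include_self:
                        offsets.append((0, 0))
                    continue
                if math.hypot(dr, dc) <= band + 1e-9:
                    offsets.append((dr, dc))
        return offsets


@dataclass(frozen=True)
class Hotspot:
    """A maximal connected set of significant cells."""

    name: str
    member_cells: frozenset[CellId]
    area_km2: float
    summary: IncidenceSummary | None = None


def gi_star(
    counts: Mapping[CellId, int],
    scheme: WeightsScheme = WeightsScheme(),
) -> pd.DataFrame:
    """Getis-Ord Gi* standard scores over per-cell counts.

    ``counts`` must cover every retained cell of the study area, zeros
    included; cells absent from the map are outside the study area and are
    not anyone's neighbors.  Returns a frame with columns
    ``cell, count, z, p`` (two-sided normal p).  If the counts are constant
    (zero variance) every z is defined as 0 and nothing is significant.
    """
    cells = sorted(counts)
    x = np.array([counts[c] for c in cells], dtype=float)
    n = len(cells)
    if n == 0:
        return pd.DataFrame(columns=["cell", "count", "z", "p"])
    xbar = x.mean()
    s = math.sqrt(max((x * x).mean() - xbar * xbar, 0.0))

    index = {cell: i for i, cell in enumerate(cells)}
    offsets = scheme.neighbor_offsets()
    neigh_sum = np.zeros(n)
    neigh_n = np.zeros(n)
    for i, cell in enumerate(cells):
        for dr, dc in offsets:
            j = index.get((cell.row + dr, cell.col + dc))
            if j is not None:
                neigh_sum[i] += x[j]
                neigh_n[i] += 1

    z = np.zeros(n)
    if s > 0 and n > 1:
        denom = s * np.sqrt(np.maximum(n * neigh_n - neigh_n**2, 0.0) / (n - 1))
        ok = denom > 0
        z[ok] = (neigh_sum[ok] - xbar * neigh_n[ok]) / denom[ok]
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"cell": [CellId(*c) for c in cells], "count": x.astype(int), "z": z, "p": p})


def significant_cells(
    results: pd.DataFrame,
    confidence: float = 0.99,
    fdr: bool = True,
) -> set[CellId]:
    """Cells significantly hot at the given confidence level.

    Only positive z qualifies (coldspots are ignored).  With ``fdr`` the
    Benjamini-Hochberg correction is applied across all cells first and the
    adjusted p is compared to alpha = 1 - confidence.
    """
    if len(results) == 0:
        return set()
    alpha = 1.0 - confidence
    p = results["p"].to_numpy(float)
    if fdr:
        p = multipletests(p, alpha=alpha, method="fdr_bh")[1]
    hot = (results["z"].to_numpy(float) > 0) & (p < alpha)
    return {CellId(*c) for c in results.loc[hot, "cell"]}


def merge_contiguous(
    cells: Iterable[CellId],
    spec: GridSpec = GridSpec(),
) -> list[Hotspot]:
    """Merge cells into hotspots: connected components under queen contiguity.

    Each hotspot is named after its southwestern-most member (lowest row,
    then lowest column), which makes naming deterministic; the list is
    sorted by name.  Areas are spherical-Earth sums over member cells.
    """
    cell_set = {CellId(*c) for c in cells}
    graph = nx.Graph()
    graph.add_nodes_from(cell_set)
    for cell in cell_set:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                other = CellId(cell.row + dr, cell.col + dc)
                if other in cell_set:
                    graph.add_edge(cell, other)
    hotspots = []
    for component in nx.connected_components(graph):
        members = frozenset(component)
        anchor = min(members)  # lowest row, then lowest col
        lat, lon = spec.cell_center(anchor)
        name = f"hotspot_{lat:.3f}_{lon:.3f}"
        area = sum(cell_area_km2(c, spec) for c in members)
        hotspots.append(Hotspot(name=name, member_cells=members, area_km2=area))
    return sorted(hotspots, key=lambda h: h.name)


def hotspot_completeness(
    events: pd.DataFrame, hotspot: Hotspot
) -> IncidenceSummary | None:
    """Incidence summary and completeness of one hotspot.

    Takes every event whose place key is a member cell or the hotspot's own
    name (the key rescued non-georeferenced events carry), collapses to
    unique species x date combinations — two events of one species on one
    day in different member cells are a single hotspot event — and computes
    Chao2 completeness.  Returns ``None`` for a hotspot with no events.
    """
    keys = set(hotspot.member_cells) | {hotspot.name}
    inside = events.loc[[k in keys for k in events["place_key"]]]
    unique = inside.drop_duplicates(subset=["taxon", "date_key"])
    return summarize_incidence(unique, hotspot.name)
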