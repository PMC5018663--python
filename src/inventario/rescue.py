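"""Rescue of non-georeferenced records via locality-name synonymy.

Many historical occurrence records carry a textual locality but no
coordinates.  Two recovery passes make them usable:

1. *Rescue into hotspots* — locality strings attached to georeferenced
   events inside a hotspot become that hotspot's synonymy; non-georeferenced
   records whose locality matches are pulled into the hotspot, provided any
   distance offset in the descriptor ("10 km N of X") does not exceed the
   configured limit.  Strings seen in more than one hotspot are ambiguous
   and excluded.
2. *Standalone localities* — whatever remains is grouped by normalized
   locality string, and localities with enough unique species x date events
   are summarized with the same Chao2 completeness index as grid cells.

Rescue only ever adds events keyed by hotspot name; everything computed from
georeferenced cells alone is invariant under it.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .hotspot import Hotspot
from .occurrence import EVENT_COLUMNS, deduplicate, normalize_text
from .richness import SelectionCriteria, summarize_by_unit

logger = logging.getLogger(__name__)

__all__ = [
    "LocalitySynonymy",
    "RescueReport",
    "parse_offset",
    "build_synonymy",
    "match_ungeoreferenced",
    "standalone_localities",
]

MI_PER_KM = 1.609


@dataclass(frozen=True)
class LocalitySynonymy:
    """Mapping normalized locality string -> hotspot name (at most one)."""

    mapping: Mapping[str, str]
    ambiguous: frozenset[str] = frozenset()
    provenance: str = "derived-from-georeferenced"

    def lookup(self, normalized: str) -> str | None:
        return self.mapping.get(normalized)


@dataclass
class RescueReport:
    """Bookkeeping for one rescue pass."""

    n_candidates: int = 0
    n_rescued: int = 0
    n_rejected_offset: int = 0
    n_unmatched: int = 0
    n_offset_unparsed: int = 0
    per_hotspot: Counter = field(default_factory=Counter)
    rescued_row_ids: list = field(default_factory=list)


_OFFSET_RE = re.compile(
    r"""^\s*(?:ca\.?\s+|about\s+)?
        (\d+(?:[.,]\d+)?)\s*
        (km|mi|mile|miles|kilometers?)\.?\s+
        (?:(?:[nsew]{1,3}|north|south|east|west|northeast|northwest|
            southeast|southwest)\.?\s+)?
        (?:of\s+|by\s+road\s+|from\s+)?
        (.+)$""",
    re.IGNORECASE | re.VERBOSE,
)


def parse_offset(locality: str) -> tuple[float, str, bool]:
    """Split a locality descriptor into (offset_km, base_name, parsed).

    Recognizes prefixes like ``"12 km W La Trinitaria"``, ``"1 mi SW Valle
    Nacional"`` or ``"26 km N by road Ocozocuautla"``.  A descriptor without
    such a prefix is the base name itself at offset 0.  ``parsed`` is False
    only when a distance-like prefix was present but could not be
    interpreted; callers treat that as offset 0 but flag it.
    """
    text = locality.strip()
    match = _OFFSET_RE.match(text)
    if not match:
        looks_offset = bool(re.match(r"^\s*\d+(?:[.,]\d+)?\s*\S+\s+", text))
        return 0.0, text, not looks_offset
    distance = float(match.group(1).replace(",", "."))
    unit = match.group(2).lower()
    if unit.startswith("mi"):
        distance *= MI_PER_KM
    return distance, match.group(3).strip(), True


def build_synonymy(
    geo_events: pd.DataFrame, hotspots: Sequence[Hotspot]
) -> LocalitySynonymy:
    """Derive the locality -> hotspot synonymy from georeferenced events.

    Every normalized locality string attached to at least one georeferenced
    event inside a hotspot maps to that hotspot; strings appearing inside
    two or more hotspots are excluded as ambiguous (a false assignment
    would corrupt the hotspot's completeness) and logged.
    """
    cell_to_hotspot = {
        cell: h.name for h in hotspots for cell in h.member_cells
    }
    seen: dict[str, set[str]] = {}
    for _, event in geo_events.iterrows():
        hotspot_name = cell_to_hotspot.get(event["place_key"])
        if hotspot_name is None:
            continue
        name = normalize_text(event.get("locality", ""))
        if not name:
            continue
        seen.setdefault(name, set()).add(hotspot_name)
    ambiguous = frozenset(n for n, hs in seen.items() if len(hs) > 1)
    mapping = {n: next(iter(hs)) for n, hs in seen.items() if len(hs) == 1}
    if ambiguous:
        logger.info(
            "build_synonymy: %d ambiguous locality strings excluded: %s",
            len(ambiguous),
            sorted(ambiguous)[:10],
        )
    return LocalitySynonymy(mapping=mapping, ambiguous=ambiguous)


def match_ungeoreferenced(
    records: pd.DataFrame,
    synonymy: LocalitySynonymy,
    max_offset_km: float = 5.0,
) -> tuple[pd.DataFrame, RescueReport]:
    """Rescue non-georeferenced records into hotspots by locality name.

    A record is a candidate when the base name of its locality descriptor
    (offset prefix stripped) or the full descriptor matches the synonymy.
    Candidates whose offset exceeds ``max_offset_km`` are rejected; the rest
    become events keyed by hotspot name, deduplicated on species x date x
    hotspot.  Returns the rescued event frame and a :class:`RescueReport`.
    """
    report = RescueReport()
    ungeo = records.loc[records["lat"].isna() | records["lon"].isna()].copy()
    assignments = []
    for idx, record in ungeo.iterrows():
        raw = str(record.get("locality", ""))
        offset_km, base, parsed = parse_offset(raw)
        target = synonymy.lookup(normalize_text(raw))
        if target is None:
            target = synonymy.lookup(normalize_text(base))
        if target is None:
            report.n_unmatched += 1
            continue
        report.n_candidates += 1
        if not parsed:
            report.n_offset_unparsed += 1
            offset_km = 0.0
        if offset_km > max_offset_km:
            report.n_rejected_offset += 1
            continue
        assignments.append((idx, target))

    if not assignments:
        empty = pd.DataFrame(columns=list(records.columns) + EVENT_COLUMNS)
        return empty, report

    idxs, targets = zip(*assignments)
    report.rescued_row_ids = list(idxs)
    matched = ungeo.loc[list(idxs)].copy()
    matched["_hotspot"] = targets
    rescued = deduplicate(matched, lambda rec: rec["_hotspot"])
    rescued = rescued.drop(columns="_hotspot")
    report.n_rescued = int(len(rescued))
    report.per_hotspot.update(rescued["place_key"].tolist())
    logger.info(
        "rescue: %d candidates, %d rescued events, %d rejected by offset, %d unmatched",
        report.n_candidates,
        report.n_rescued,
        report.n_rejected_offset,
        report.n_unmatched,
    )
    return rescued, report


def standalone_localities(
    records: pd.DataFrame,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> pd.DataFrame:
    """Chao2 summaries for non-georeferenced localities left after rescue.

    Records are keyed by normalized locality descriptor, collapsed to unique
    species x date x locality events, and summarized per locality.  Only
    localities with at least ``criteria.min_N`` events are returned (smaller
    samples cannot be judged); the caller applies the completeness threshold
    via :func:`inventario.richness.select_well_inventoried`.
    """
    ungeo = records.loc[records["lat"].isna() | records["lon"].isna()]
    if len(ungeo) == 0:
        return pd.DataFrame(columns=["unit_id", "N", "S_obs", "a", "b", "S_exp", "C"])
    events = deduplicate(
        ungeo, lambda rec: normalize_text(rec["locality"]) or None
    )
    summaries = summarize_by_unit(events, by="place_key")
    return summaries.loc[summaries["N"] >= criteria.min_N].reset_index(drop=True)
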