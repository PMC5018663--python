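"""End-to-end orchestration: raw occurrence table to completeness catalog.

Stage order is fixed: ingest -> harmonize -> temporal filter -> split
georeferenced / non-georeferenced -> boundary clip -> grid assignment ->
deduplicate -> per-cell completeness -> Gi* -> merge hotspots -> locality
synonymy -> rescue -> hotspot completeness -> standalone localities ->
report.  Every stage logs its input and output record counts, and the
ledger of drops reconciles exactly against the ingested total.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import grid as _grid
from . import hotspot as _hotspot
from . import occurrence as _occ
from . import rescue as _rescue
from . import richness as _richness
from .grid import GridSpec
from .hotspot import WeightsScheme
from .richness import SelectionCriteria

logger = logging.getLogger(__name__)

#: Column order of the per-cell catalog (matches the grid-cell report table).
CELL_TABLE_COLUMNS = ["name", "latitude", "longitude", "N", "S_obs", "a", "b", "S_exp", "C"]
#: Column order of the hotspot catalog.
HOTSPOT_TABLE_COLUMNS = ["name", "area_km2", "N", "S_obs", "a", "b", "S_exp", "C"]
#: Column order of the standalone-locality catalog.
LOCALITY_TABLE_COLUMNS = ["name", "N", "S_obs", "a", "b", "S_exp", "C"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run depends on."""

    grid: GridSpec = GridSpec()
    criteria: SelectionCriteria = SelectionCriteria()
    weights: WeightsScheme = WeightsScheme()
    cutoff_year: int = 1980
    buffer: float = 0.05
    max_offset_km: float = 5.0
    confidence: float = 0.99
    fdr: bool = True


@dataclass
class PipelineResult:
    """Tables, geometries and bookkeeping from one run."""

    cell_table: pd.DataFrame
    locality_table: pd.DataFrame
    hotspot_table: pd.DataFrame
    cell_summaries: pd.DataFrame
    gi_results: pd.DataFrame
    hotspots: list
    rescue_report: object
    geojson_layers: dict[str, dict]
    log: list[dict] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cell_table.to_csv(out / "well_inventoried_cells.csv", index=False)
        self.locality_table.to_csv(out / "standalone_localities.csv", index=False)
        self.hotspot_table.to_csv(out / "hotspots.csv", index=False)
        self.gi_results.to_csv(out / "gi_star_cells.csv", index=False)
        for name, layer in self.geojson_layers.items():
            (out / f"{name}.geojson").write_text(json.dumps(layer))
        lines = [
            f"{entry['stage']}: in={entry['n_in']} out={entry['n_out']} {entry.get('note', '')}".rstrip()
            for entry in self.log
        ]
        (out / "run_log.txt").write_text("\n".join(lines) + "\n")


def _empty_result(log: list[dict]) -> PipelineResult:
    return PipelineResult(
        cell_table=pd.DataFrame(columns=CELL_TABLE_COLUMNS),
        locality_table=pd.DataFrame(columns=LOCALITY_TABLE_COLUMNS),
        hotspot_table=pd.DataFrame(columns=HOTSPOT_TABLE_COLUMNS),
        cell_summaries=pd.DataFrame(columns=["unit_id", "N", "S_obs", "a", "b", "S_exp", "C"]),
        gi_results=pd.DataFrame(columns=["cell", "count", "z", "p"]),
        hotspots=[],
        rescue_report=_rescue.RescueReport(),
        geojson_layers={},
        log=log,
    )


def run_pipeline(
    records: pd.DataFrame,
    boundary,
    config: PipelineConfig = PipelineConfig(),
    synonyms: dict | None = None,
) -> PipelineResult:
    """Run the whole analysis on an already-loaded record frame.

    ``records`` is the canonical record frame from
    :func:`inventario.occurrence.read_occurrences` (or the synthetic
    generator's table passed through :func:`records_from_frame`);
    ``boundary`` a shapely polygon.  Returns every deliverable table plus a
    stage-by-stage count log.
    """
    log: list[dict] = []

    def stage(name: str, n_in: int, n_out: int, **extra) -> None:
        entry = {"stage": name, "n_in": n_in, "n_out": n_out, **extra}
        log.append(entry)
        logger.info("stage %-22s in=%-8d out=%-8d %s", name, n_in, n_out, extra or "")

    n0 = len(records)
    stage("ingest", n0, n0)
    if n0 == 0:
        return _empty_result(log)

    harmonized = _occ.harmonize_taxonomy(records, synonyms)
    resolved = harmonized.loc[harmonized["taxon_resolved"]]
    stage("harmonize", n0, len(resolved), note="unresolved dropped")

    dated = _occ.filter_temporal(resolved, config.cutoff_year)
    stage("temporal_filter", len(resolved), len(dated))

    geo = dated.loc[dated["lat"].notna() & dated["lon"].notna()]
    ungeo = dated.loc[dated["lat"].isna() | dated["lon"].isna()]
    stage("split_geo", len(dated), len(geo), n_ungeoreferenced=len(ungeo))

    clipped = _grid.clip_to_boundary(geo, boundary, config.buffer)
    stage("clip_boundary", len(geo), len(clipped))

    retained = _grid.clip_cells(config.grid, boundary, config.buffer)
    stage("clip_cells", len(retained), len(retained), note="retained grid cells")

    resolver = _grid.cell_place_resolver(config.grid)
    events = _occ.deduplicate(clipped, resolver)
    events = events.loc[[c in retained for c in events["place_key"]]]
    stage("deduplicate", len(clipped), len(events))

    counts = _grid.count_events_per_cell(events, retained)
    summaries = _richness.summarize_by_unit(events, by="place_key")
    stage("cell_completeness", len(events), len(summaries))

    gi = _hotspot.gi_star(counts, config.weights)
    hot_cells = _hotspot.significant_cells(gi, config.confidence, config.fdr)
    stage("gi_star", len(gi), len(hot_cells), note="significant cells")

    hotspots = _hotspot.merge_contiguous(hot_cells, config.grid)
    stage("merge_hotspots", len(hot_cells), len(hotspots))

    synonymy = _rescue.build_synonymy(events, hotspots)
    stage("synonymy", len(events), len(synonymy.mapping))

    rescued, report = _rescue.match_ungeoreferenced(ungeo, synonymy, config.max_offset_km)
    stage("rescue", len(ungeo), len(rescued), rejected_offset=report.n_rejected_offset)

    merged_events = pd.concat([events, rescued], ignore_index=True) if len(rescued) else events
    hotspot_rows = []
    enriched = []
    for h in hotspots:
        summary = _hotspot.hotspot_completeness(merged_events, h)
        enriched.append(
            _hotspot.Hotspot(h.name, h.member_cells, h.area_km2, summary)
        )
        if summary is not None:
            hotspot_rows.append(
                {
                    "name": h.name,
                    "area_km2": round(h.area_km2, 1),
                    "N": summary.N,
                    "S_obs": summary.S_obs,
                    "a": summary.a,
                    "b": summary.b,
                    "S_exp": summary.S_exp,
                    "C": summary.C,
                }
            )
    stage("hotspot_completeness", len(hotspots), len(hotspot_rows))

    remaining = ungeo.drop(index=report.rescued_row_ids) if len(ungeo) else ungeo
    standalone = _rescue.standalone_localities(remaining, config.criteria)
    stage("standalone_localities", len(remaining), len(standalone))

    # --- report tables ---------------------------------------------------
    cell_tiers = _richness.select_well_inventoried(summaries, config.criteria)
    selected_cells = pd.concat([cell_tiers["excellent"], cell_tiers["good"]])
    cell_rows = []
    for row in selected_cells.itertuples():
        lat, lon = config.grid.cell_center(row.unit_id)
        cell_rows.append(
            {
                "name": f"cell_{row.unit_id.row}_{row.unit_id.col}",
                "latitude": round(lat, 3),
                "longitude": round(lon, 3),
                "N": row.N,
                "S_obs": row.S_obs,
                "a": row.a,
                "b": row.b,
                "S_exp": round(row.S_exp, 1),
                "C": round(row.C, 2),
            }
        )
    cell_table = pd.DataFrame(cell_rows, columns=CELL_TABLE_COLUMNS).sort_values(
        "name", ignore_index=True
    ) if cell_rows else pd.DataFrame(columns=CELL_TABLE_COLUMNS)

    hotspot_table = pd.DataFrame(hotspot_rows, columns=HOTSPOT_TABLE_COLUMNS)
    if len(hotspot_table):
        tiers = _richness.select_well_inventoried(
            hotspot_table.rename(columns={"name": "unit_id"}), config.criteria
        )
        keep_names = set(
            pd.concat([tiers["excellent"], tiers["good"]])["unit_id"]
        )
        hotspot_table = hotspot_table.loc[hotspot_table["name"].isin(keep_names)]
        hotspot_table = hotspot_table.assign(
            S_exp=hotspot_table["S_exp"].round(1), C=hotspot_table["C"].round(2)
        ).reset_index(drop=True)

    if len(standalone):
        loc_tiers = _richness.select_well_inventoried(standalone, config.criteria)
        locality_table = (
            pd.concat([loc_tiers["excellent"], loc_tiers["good"]])
            .rename(columns={"unit_id": "name"})
            .assign(
                S_exp=lambda df: df["S_exp"].round(1), C=lambda df: df["C"].round(2)
            )[LOCALITY_TABLE_COLUMNS]
            .reset_index(drop=True)
        )
    else:
        locality_table = pd.DataFrame(columns=LOCALITY_TABLE_COLUMNS)

    layers = {
        "retained_cells": _grid.cells_to_geojson(retained, config.grid),
        "significant_cells": _grid.cells_to_geojson(hot_cells, config.grid),
    }
    stage("report", len(summaries), len(cell_table))

    return PipelineResult(
        cell_table=cell_table,
        locality_table=locality_table,
        hotspot_table=hotspot_table,
        cell_summaries=summaries,
        gi_results=gi,
        hotspots=enriched,
        rescue_report=report,
        geojson_layers=layers,
        log=log,
    )
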