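"""Synthetic occurrence datasets with known ground truth.

The generator emulates the statistical structure the completeness analysis
assumes, so every pipeline stage can be tested without portal downloads:

- a known species pool per site, with per-species *daily* detection
  probabilities drawn logit-normally (``logit p_i ~ Normal(mu, sigma)``),
  giving realistic singleton/doubleton tails;
- repeated survey days per site (incidence sampling: one day at one place
  is the sampling unit);
- spatially clustered effort: cluster sites receive an effort multiplier,
  so their grid cells accumulate disproportionate record counts;
- multi-source duplication: a fraction of records is re-emitted under a
  second portal tag;
- a georeferenced / non-georeferenced mix, with some blanked records
  carrying "<d> km <dir> <site>" offset descriptors;
- partial dates (day, or month and day, missing).

Everything the generator decides is exported as :class:`GroundTruth` so
tests can compare pipeline output with the planted structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .occurrence import MISSING_DATE

__all__ = ["ClusterSpec", "SimConfig", "GroundTruth", "simulate", "simulate_incidence"]

_DIRECTIONS = ["N", "S", "E", "W", "NE", "NW", "SE", "SW"]


@dataclass(frozen=True)
class ClusterSpec:
    """A planted concentration of sampling effort."""

    center_lat: float
    center_lon: float
    radius_deg: float = 0.05
    n_sites: int = 4
    intensity: float = 4.0  # effort (survey-day) multiplier


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_background_sites: int = 12
    clusters: tuple[ClusterSpec, ...] = (
        ClusterSpec(18.30, -97.30),
        ClusterSpec(20.10, -99.60),
    )
    s_true: int = 150           # species pool per site
    pool_size: int = 400        # countrywide species pool
    days: int = 60              # survey days per background site
    mu: float = -2.0            # logit-normal location of daily detection p
    sigma: float = 1.5          # logit-normal scale
    duplication_rate: float = 0.12
    frac_ungeoreferenced: float = 0.30
    offset_rate: float = 0.10   # of blanked records, get an offset prefix
    partial_date_rate: float = 0.05
    region: tuple[float, float, float, float] = (16.0, 22.0, -101.0, -95.0)
    years: tuple[int, int] = (1950, 1979)
    seed: int = 0

    def __post_init__(self) -> None:
        n_sites = self.n_background_sites + sum(c.n_sites for c in self.clusters)
        if n_sites < 1:
            raise ValueError("need at least one site")
        if self.days < 1:
            raise ValueError("need at least one survey day (D >= 1)")
        if self.s_true < 1 or self.s_true > self.pool_size:
            raise ValueError("need 1 <= s_true <= pool_size")
        for name in ("duplication_rate", "frac_ungeoreferenced", "offset_rate", "partial_date_rate"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    sites: pd.DataFrame                 # name, lat, lon, cluster, s_true, n_days
    true_events: set[tuple[str, str, str]] = field(default_factory=set)
    n_base_records: int = 0
    n_duplicates: int = 0
    n_ungeoreferenced: int = 0
    n_ungeo_in_clusters: int = 0
    n_offset_over_limit: int = 0
    locality_to_cluster: dict[str, int | None] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "sites": self.sites.to_dict(orient="records"),
            "true_events": sorted(list(e) for e in self.true_events),
            "n_base_records": self.n_base_records,
            "n_duplicates": self.n_duplicates,
            "n_ungeoreferenced": self.n_ungeoreferenced,
            "n_ungeo_in_clusters": self.n_ungeo_in_clusters,
            "n_offset_over_limit": self.n_offset_over_limit,
            "locality_to_cluster": self.locality_to_cluster,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def simulate_incidence(
    s_true: int, days: int, mu: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-species incidence counts over ``days`` survey days.

    Species ``i`` is detected on each day independently with probability
    ``p_i = expit(Normal(mu, sigma))``; the result is the vector of
    detection-day counts, the raw material of the Chao2 estimator.
    """
    p = expit(rng.normal(mu, sigma, size=s_true))
    return rng.binomial(days, p)


def _species_pool(pool_size: int) -> list[str]:
    return [f"Simulavis species{k:04d}" for k in range(pool_size)]


def simulate(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one raw occurrence table plus its ground truth.

    The table uses the Darwin Core input dialect the occurrence reader
    expects; rerunning with the same config is byte-identical.
    """
    rng = np.random.default_rng(config.seed)
    pool = _species_pool(config.pool_size)
    lat0, lat1, lon0, lon1 = config.region

    # --- sites ---------------------------------------------------------
    site_rows = []
    for ci, cluster in enumerate(config.clusters):
        for _ in range(cluster.n_sites):
            angle = rng.uniform(0, 2 * np.pi)
            radius = cluster.radius_deg * np.sqrt(rng.uniform())
            site_rows.append(
                (
                    cluster.center_lat + radius * np.sin(angle),
                    cluster.center_lon + radius * np.cos(angle),
                    ci,
                    max(1, round(config.days * cluster.intensity)),
                )
            )
    for _ in range(config.n_background_sites):
        site_rows.append(
            (rng.uniform(lat0, lat1), rng.uniform(lon0, lon1), None, config.days)
        )
    sites = pd.DataFrame(site_rows, columns=["lat", "lon", "cluster", "n_days"])
    sites.insert(0, "name", [f"Sitio Sintetico {i:03d}" for i in range(len(sites))])
    sites["s_true"] = config.s_true

    start = date(config.years[0], 1, 1).toordinal()
    end = date(config.years[1], 12, 31).toordinal()

    # --- detections ----------------------------------------------------
    rows: list[tuple] = []
    true_events: set[tuple[str, str, str]] = set()
    for site in sites.itertuples():
        species = rng.choice(config.pool_size, size=config.s_true, replace=False)
        p = expit(rng.normal(config.mu, config.sigma, size=config.s_true))
        day_ordinals = rng.choice(
            np.arange(start, end + 1), size=min(site.n_days, end - start + 1), replace=False
        )
        for ordinal in day_ordinals:
            when = date.fromordinal(int(ordinal))
            year, month, day = when.year, when.month, when.day
            mask_roll = rng.uniform()
            if mask_roll < config.partial_date_rate / 2:
                month = day = None          # year only
            elif mask_roll < config.partial_date_rate:
                day = None                  # year and month
            detected = np.flatnonzero(rng.uniform(size=config.s_true) < p)
            for k in detected:
                taxon = pool[species[k]]
                dkey = "_".join(
                    MISSING_DATE if v is None else str(v) for v in (year, month, day)
                )
                true_events.add((taxon, dkey, site.name))
                rows.append((taxon, year, month, day, site.lat, site.lon, site.name))

    base = pd.DataFrame(
        rows, columns=["taxon", "year", "month", "day", "lat", "lon", "locality"]
    )
    base["source"] = "portal_a"

    # --- cross-source duplication ---------------------------------------
    dup_mask = rng.uniform(size=len(base)) < config.duplication_rate
    dups = base.loc[dup_mask].copy()
    dups["source"] = "portal_b"
    table = pd.concat([base, dups], ignore_index=True)

    # --- georeferencing loss and offset descriptors ---------------------
    ungeo_mask = rng.uniform(size=len(table)) < config.frac_ungeoreferenced
    cluster_sites = {
        row.name for row in sites.itertuples() if not pd.isna(row.cluster)
    }
    n_ungeo_in_clusters = int(
        table.loc[ungeo_mask, "locality"].isin(cluster_sites).sum()
    )
    n_offset_over = 0
    localities = table["locality"].tolist()
    lats = table["lat"].to_numpy(float).copy()
    lons = table["lon"].to_numpy(float).copy()
    for i in np.flatnonzero(ungeo_mask):
        lats[i] = np.nan
        lons[i] = np.nan
        if rng.uniform() < config.offset_rate:
            dist = int(rng.integers(1, 13))  # 1..12 km; beyond 5 must be rejected
            direction = _DIRECTIONS[rng.integers(len(_DIRECTIONS))]
            localities[i] = f"{dist} km {direction} {localities[i]}"
            if dist > 5:
                n_offset_over += 1
    table["lat"] = lats
    table["lon"] = lons
    table["locality"] = localities

    # --- shuffle and emit in the input dialect --------------------------
    order = rng.permutation(len(table))
    table = table.iloc[order].reset_index(drop=True)
    genus = table["taxon"].str.split(" ").str[0]
    epithet = table["taxon"].str.split(" ").str[1]
    out = pd.DataFrame(
        {
            "scientificName": table["taxon"],
            "order": "Simuliformes",
            "family": "Simulavidae",
            "genus": genus,
            "specificEpithet": epithet,
            "year": table["year"].map(lambda v: "" if pd.isna(v) else str(int(v))),
            "month": table["month"].map(lambda v: "" if v is None or pd.isna(v) else str(int(v))),
            "day": table["day"].map(lambda v: "" if v is None or pd.isna(v) else str(int(v))),
            "decimalLatitude": table["lat"].map(lambda v: "" if pd.isna(v) else f"{v:.5f}"),
            "decimalLongitude": table["lon"].map(lambda v: "" if pd.isna(v) else f"{v:.5f}"),
            "stateProvince": "Estado Sintetico",
            "municipality": "",
            "locality": table["locality"],
            "source": table["source"],
        }
    )

    truth = GroundTruth(
        sites=sites,
        true_events=true_events,
        n_base_records=int(len(base)),
        n_duplicates=int(dup_mask.sum()),
        n_ungeoreferenced=int(ungeo_mask.sum()),
        n_ungeo_in_clusters=n_ungeo_in_clusters,
        n_offset_over_limit=n_offset_over,
        locality_to_cluster={
            row.name: (None if pd.isna(row.cluster) else int(row.cluster))
            for row in sites.itertuples()
        },
    )
    return out, truth
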