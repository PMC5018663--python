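"""Reading, normalizing, filtering and deduplicating occurrence records.

Occurrence records live in a fixed-schema :class:`pandas.DataFrame` whose
columns are listed in :data:`RECORD_COLUMNS`.  The unit of analysis downstream
is the *event*: one unique combination of species x date x place, held in an
event frame with the columns in :data:`EVENT_COLUMNS` plus the representative
record's original columns.

Dates may be partial (e.g. year and month but no day); a partial date is a
distinct time event, keyed by a ``"Y_M_D"`` string with missing elements
rendered as ``"NA"`` (``1964_7_16``, ``1964_7_NA``).  Records with every date
element missing carry no temporal information and are dropped by
:func:`filter_temporal`.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Logical record columns, in canonical order.
RECORD_COLUMNS = [
    "taxon_raw",
    "taxon",
    "year",
    "month",
    "day",
    "lat",
    "lon",
    "state",
    "municipality",
    "locality",
    "source",
]

#: Event-frame key columns produced by :func:`deduplicate`.
EVENT_COLUMNS = ["taxon", "date_key", "place_key"]

#: Default mapping logical field -> input column (Darwin Core terms).
DEFAULT_SCHEMA: dict[str, str] = {
    "scientific_name": "scientificName",
    "order": "order",
    "family": "family",
    "genus": "genus",
    "specific_epithet": "specificEpithet",
    "year": "year",
    "month": "month",
    "day": "day",
    "lat": "decimalLatitude",
    "lon": "decimalLongitude",
    "state": "stateProvince",
    "municipality": "municipality",
    "locality": "locality",
    "source": "source",
}

MISSING_DATE = "NA"


class SchemaError(ValueError):
    """A mandatory input column is absent from the file."""


# --- text and number normalization -----------------------------------------

_DASHES = dict.fromkeys(map(ord, "−‐‑‒–—―"), "-")
_WS_RE = re.compile(r"\s+")


def normalize_text(value: object) -> str:
    """Normalize a free-text string for keying.

    Trims, collapses internal whitespace, case-folds and strips diacritics,
    so that portal-dump variants of one locality string compare equal.
    Missing values normalize to the empty string.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    text = str(value).strip()
    if not text or text.lower() in {"nan", "none"}:
        return ""
    text = _WS_RE.sub(" ", text)
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    return text.casefold()


def parse_coordinate(value: object) -> float:
    """Parse one decimal coordinate, tolerating portal-dump quirks.

    Handles the Unicode minus sign and its dash cousins, comma decimal
    separators and stray whitespace.  Anything unparseable becomes NaN
    (records are never rejected for a bad coordinate, they just lose it).
    """
    if value is None:
        return np.nan
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip().translate(_DASHES)
    if not text:
        return np.nan
    if "," in text and "." not in text:
        text = text.replace(",", ".")
    try:
        return float(text)
    except ValueError:
        return np.nan


def _parse_int_in_range(value: object, lo: int, hi: int) -> float:
    if value is None:
        return np.nan
    text = str(value).strip()
    if not text or text.lower() in {"nan", "none", "na"}:
        return np.nan
    try:
        number = int(float(text))
    except ValueError:
        return np.nan
    return float(number) if lo <= number <= hi else np.nan


# --- reading ----------------------------------------------------------------

def read_occurrences(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited occurrence table into the canonical record frame.

    Parameters
    ----------
    path
        CSV (default) or TSV file.  The delimiter is taken from the file
        extension unless ``sep`` is given.
    schema
        Mapping from logical field names (keys of :data:`DEFAULT_SCHEMA`) to
        the file's column names; unspecified fields fall back to the Darwin
        Core defaults.

    Every input row yields exactly one record.  Unparseable coordinates or
    date elements become missing values, never dropped rows.

    Raises
    ------
    SchemaError
        If no taxon column (scientific name or genus+epithet) or no locality
        column can be found.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return records_from_frame(raw, schema=schema)


def records_from_frame(
    raw: pd.DataFrame, schema: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Normalize an already-loaded raw table into the canonical record frame."""
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)

    def col(field: str) -> pd.Series:
        name = cols[field]
        if name in raw.columns:
            return raw[name]
        return pd.Series([""] * len(raw), index=raw.index, dtype=object)

    has_binomial = cols["scientific_name"] in raw.columns
    has_parts = cols["genus"] in raw.columns and cols["specific_epithet"] in raw.columns
    if not has_binomial and not has_parts:
        raise SchemaError(
            "no taxon column: need %r or %r+%r"
            % (cols["scientific_name"], cols["genus"], cols["specific_epithet"])
        )
    if cols["locality"] not in raw.columns:
        raise SchemaError("no locality column %r" % cols["locality"])

    if has_binomial:
        taxon_raw = col("scientific_name").astype(str).str.strip()
    else:
        taxon_raw = (
            col("genus").astype(str).str.strip()
            + " "
            + col("specific_epithet").astype(str).str.strip()
        ).str.strip()

    out = pd.DataFrame(
        {
            "taxon_raw": taxon_raw,
            "taxon": taxon_raw,
            "year": col("year").map(lambda v: _parse_int_in_range(v, 1, 9999)),
            "month": col("month").map(lambda v: _parse_int_in_range(v, 1, 12)),
            "day": col("day").map(lambda v: _parse_int_in_range(v, 1, 31)),
            "lat": col("lat").map(parse_coordinate),
            "lon": col("lon").map(parse_coordinate),
            "state": col("state").astype(str),
            "municipality": col("municipality").astype(str),
            "locality": col("locality").astype(str),
            "source": col("source").astype(str),
        }
    )
    # a coordinate is only usable as a pair
    half = out["lat"].isna() ^ out["lon"].isna()
    out.loc[half, ["lat", "lon"]] = np.nan
    out.index = pd.RangeIndex(len(out))
    return out


# --- taxonomy ---------------------------------------------------------------

def load_synonyms(path: str | Path) -> dict[str, str]:
    """Load a two-column (raw,canonical) CSV into a synonym mapping.

    Canonical names are added as identity entries so the mapping is
    idempotent by construction.
    """
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw_col, canon_col = table.columns[:2]
    mapping = dict(zip(table[raw_col].str.strip(), table[canon_col].str.strip()))
    for canonical in list(mapping.values()):
        mapping.setdefault(canonical, canonical)
    return mapping


def harmonize_taxonomy(
    records: pd.DataFrame, synonyms: Mapping[str, str] | None
) -> pd.DataFrame:
    """Map raw taxon names onto a closed canonical set.

    Records whose raw name is absent from the synonym table are flagged
    (``taxon_resolved == False``) rather than dropped here; downstream
    operations exclude them.  With no table, every raw name is its own
    canonical name.  Harmonization never increases the number of distinct
    taxa.
    """
    out = records.copy()
    if not synonyms:
        out["taxon"] = out["taxon_raw"]
        out["taxon_resolved"] = out["taxon"].str.len() > 0
        return out
    mapped = out["taxon_raw"].map(synonyms)
    # canonical names pass through even if absent as raw keys
    canonical = set(synonyms.values())
    passthrough = out["taxon_raw"].isin(canonical)
    out["taxon"] = mapped.where(~mapped.isna(), out["taxon_raw"].where(passthrough))
    out["taxon_resolved"] = ~out["taxon"].isna()
    out["taxon"] = out["taxon"].fillna(out["taxon_raw"])
    n_unresolved = int((~out["taxon_resolved"]).sum())
    if n_unresolved:
        logger.info("harmonize_taxonomy: %d records unresolved", n_unresolved)
    return out


# --- temporal filter --------------------------------------------------------

def filter_temporal(records: pd.DataFrame, cutoff_year: int = 1980) -> pd.DataFrame:
    """Keep records usable as pre-cutoff time events.

    Dropped are: records with all three date elements missing (no temporal
    information), records with a missing year (the cutoff cannot be
    verified), and records from years after ``cutoff_year``.  Year equal to
    the cutoff is kept.  Partial dates with a year survive as distinct time
    events.  The operation is idempotent; removal counts are logged.
    """
    no_date = records["year"].isna() & records["month"].isna() & records["day"].isna()
    no_year = records["year"].isna() & ~no_date
    too_late = records["year"] > cutoff_year
    keep = ~(no_date | no_year | too_late)
    logger.info(
        "filter_temporal: dropped %d dateless, %d yearless, %d after %d; kept %d",
        int(no_date.sum()),
        int(no_year.sum()),
        int(too_late.sum()),
        cutoff_year,
        int(keep.sum()),
    )
    return records.loc[keep].copy()


# --- event keys and deduplication -------------------------------------------

def date_key(year: object, month: object, day: object) -> str:
    """Render a (possibly partial) date as a ``"Y_M_D"`` event key.

    Missing elements become ``"NA"``; a fully missing date has no key and
    raises ``ValueError``.
    """
    parts = []
    for element in (year, month, day):
        if element is None or (isinstance(element, float) and np.isnan(element)):
            parts.append(MISSING_DATE)
        else:
            parts.append(str(int(element)))
    if all(p == MISSING_DATE for p in parts):
        raise ValueError("a fully missing date has no event key")
    return "_".join(parts)


def _date_keys(records: pd.DataFrame) -> pd.Series:
    def render(element: pd.Series) -> pd.Series:
        return element.map(lambda v: MISSING_DATE if pd.isna(v) else str(int(v)))

    return (
        render(records["year"])
        + "_"
        + render(records["month"])
        + "_"
        + render(records["day"])
    )


def locality_place_resolver(record: pd.Series) -> object:
    """Place key for the non-georeferenced path: the normalized locality string."""
    key = normalize_text(record["locality"])
    return key if key else None


def deduplicate(
    records: pd.DataFrame,
    place_resolver: Callable[[pd.Series], object],
) -> pd.DataFrame:
    """Collapse records into unique species x date x place events.

    ``place_resolver`` maps one record to its place key (a grid cell id for
    georeferenced records, a normalized locality string otherwise); records
    resolving to ``None`` are excluded.  Unresolved-taxon records (from
    :func:`harmonize_taxonomy`) are excluded with a logged count.  The
    representative record of each duplicate group is the first in a stable
    sort by (source, original row order), so the result is deterministic and
    the operation idempotent.
    """
    work = records
    if "taxon_resolved" in work.columns:
        n_bad = int((~work["taxon_resolved"]).sum())
        if n_bad:
            logger.info("deduplicate: excluding %d unresolved-taxon records", n_bad)
        work = work.loc[work["taxon_resolved"]]
    work = work.copy()
    work["date_key"] = _date_keys(work)
    work["place_key"] = work.apply(place_resolver, axis=1)
    work = work.loc[~work["place_key"].isna()]
    work["_row"] = np.arange(len(work))
    work = work.sort_values(["source", "_row"], kind="stable")
    events = work.drop_duplicates(subset=EVENT_COLUMNS, keep="first")
    events = events.drop(columns="_row")
    front = EVENT_COLUMNS + [c for c in events.columns if c not in EVENT_COLUMNS]
    return events[front].reset_index(drop=True)
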