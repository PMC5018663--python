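"""Reading, taxonomic harmonization, temporal filtering and deduplication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inventario import occurrence as occ
from inventario.grid import GridSpec, cell_place_resolver
from inventario.synthetic import SimConfig, simulate

from conftest import make_records


class TestRead:
    def test_row_count_preserved_and_bad_fields_become_missing(self, tmp_path):
        path = tmp_path / "occ.csv"
        path.write_text(
            "scientificName,year,month,day,decimalLatitude,decimalLongitude,locality,source\n"
            "Aus primus,1960,7,16,19.5,-99.5,La Loma,a\n"
            "Aus primus,1960,7,17,,-99.5,La Loma,a\n"
            "Bus secundus,1960,13,16,−28.208,−115.244,Isla,a\n"
        )
        records = occ.read_occurrences(path)
        assert len(records) == 3
        # blank latitude: the pair is unusable, both become missing
        assert records["lat"].isna().tolist() == [False, True, False]
        assert records["lon"].isna().tolist() == [False, True, False]
        # Unicode minus parses; month 13 is out of range, not a dropped row
        assert records.loc[2, "lon"] == pytest.approx(-115.244)
        assert np.isnan(records.loc[2, "month"])

    def test_comma_decimal_separator(self):
        assert occ.parse_coordinate("19,525") == pytest.approx(19.525)

    def test_missing_mandatory_column_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("year,month,day\n1960,7,16\n")
        with pytest.raises(occ.SchemaError):
            occ.read_occurrences(path)

    def test_synthetic_dump_count_preserved(self, tmp_path):
        table, _ = simulate(SimConfig(n_background_sites=3, clusters=(), days=10, seed=5))
        path = tmp_path / "dump.csv"
        table.to_csv(path, index=False)
        assert len(occ.read_occurrences(path)) == len(table)


class TestHarmonize:
    def test_synonym_merge_collapses_confused_pair(self):
        records = make_records(
            [{"taxon_raw": "Empidonax alnorum"}, {"taxon_raw": "Empidonax traillii"}]
        )
        synonyms = {
            "Empidonax alnorum": "Empidonax traillii",
            "Empidonax traillii": "Empidonax traillii",
        }
        out = occ.harmonize_taxonomy(records, synonyms)
        assert out["taxon"].nunique() == 1
        assert set(out["taxon"]) == {"Empidonax traillii"}

    def test_canonical_name_is_fixed_point(self):
        records = make_records([{"taxon_raw": "Aus primus"}])
        out = occ.harmonize_taxonomy(records, {"Aus primus": "Aus primus"})
        assert out.loc[0, "taxon"] == "Aus primus"

    def test_variant_cardinality(self):
        variants = ["A one", "A uno", "A 1", "B two", "B dos"]
        synonyms = {v: ("A" if v.startswith("A") else "B") for v in variants}
        out = occ.harmonize_taxonomy(make_records([{"taxon_raw": v} for v in variants]), synonyms)
        assert out["taxon"].nunique() == 2

    def test_unknown_names_flagged_not_dropped(self):
        records = make_records([{"taxon_raw": "Ignotus x"}, {"taxon_raw": "Aus primus"}])
        out = occ.harmonize_taxonomy(records, {"Aus primus": "Aus primus"})
        assert len(out) == 2
        assert out["taxon_resolved"].tolist() == [False, True]

    @given(
        raw=st.lists(st.sampled_from(["a", "b", "c", "d", "e"]), min_size=1, max_size=30),
        canon=st.dictionaries(
            st.sampled_from(["a", "b", "c", "d", "e"]),
            st.sampled_from(["x", "y"]),
        ),
    )
    @settings(deadline=None, max_examples=50)
    def test_never_increases_distinct_taxa(self, raw, canon):
        records = make_records([{"taxon_raw": r} for r in raw])
        out = occ.harmonize_taxonomy(records, canon or None)
        resolved = out.loc[out["taxon_resolved"]]
        assert resolved["taxon"].nunique() <= records["taxon_raw"].nunique()


class TestFilterTemporal:
    @pytest.mark.parametrize(
        "row, kept",
        [
            ({"year": 1981.0}, False),            # after the cutoff
            ({"year": 1980.0}, True),             # cutoff year itself is kept
            ({"year": np.nan, "month": np.nan, "day": np.nan}, False),  # dateless
            ({"year": 1964.0, "month": 7.0, "day": np.nan}, True),      # partial date
            ({"year": np.nan, "month": 7.0, "day": 2.0}, False),        # unverifiable year
        ],
    )
    def test_cutoff_rules(self, row, kept):
        out = occ.filter_temporal(make_records([row]), cutoff_year=1980)
        assert (len(out) == 1) is kept

    def test_idempotent(self):
        records = make_records(
            [{"year": y} for y in (1950.0, 1980.0, 1981.0, np.nan)]
        )
        once = occ.filter_temporal(records, 1980)
        twice = occ.filter_temporal(once, 1980)
        pd.testing.assert_frame_equal(once, twice)


class TestDateKey:
    def test_partial_and_full_keys(self):
        assert occ.date_key(1964, 7, 16) == "1964_7_16"
        assert occ.date_key(1964, 7, np.nan) == "1964_7_NA"

    def test_fully_missing_date_disallowed(self):
        with pytest.raises(ValueError):
            occ.date_key(np.nan, np.nan, np.nan)


class TestDeduplicate:
    def test_cross_source_duplicate_collapses(self):
        spec = GridSpec()
        records = make_records(
            [
                {"lat": 19.51, "lon": -99.51, "source": "portal_b"},
                {"lat": 19.52, "lon": -99.52, "source": "portal_a"},
            ]
        )
        events = occ.deduplicate(records, cell_place_resolver(spec))
        assert len(events) == 1
        # representative is lexicographically first by (source, row order)
        assert events.loc[0, "source"] == "portal_a"

    def test_partial_date_is_a_distinct_event(self):
        records = make_records(
            [
                {"lat": 19.51, "lon": -99.51, "day": 16.0},
                {"lat": 19.51, "lon": -99.51, "day": np.nan},
            ]
        )
        events = occ.deduplicate(records, cell_place_resolver(GridSpec()))
        assert len(events) == 2
        assert set(events["date_key"]) == {"1960_7_16", "1960_7_NA"}

    def test_idempotent(self, rng):
        records = _random_records(rng, 500)
        resolver = cell_place_resolver(GridSpec())
        once = occ.deduplicate(records, resolver)
        twice = occ.deduplicate(once, resolver)
        assert len(once) == len(twice)
        assert set(map(tuple, once[occ.EVENT_COLUMNS].itertuples(index=False))) == set(
            map(tuple, twice[occ.EVENT_COLUMNS].itertuples(index=False))
        )

    def test_matches_hashset_oracle(self, rng):
        records = _random_records(rng, 3000)
        resolver = cell_place_resolver(GridSpec())
        events = occ.deduplicate(records, resolver)
        oracle = set()
        for row in records.itertuples():
            key = occ.date_key(row.year, row.month, row.day)
            cell = resolver(pd.Series({"lat": row.lat, "lon": row.lon}))
            oracle.add((row.taxon, key, cell))
        assert len(events) == len(oracle)
        assert set(zip(events["taxon"], events["date_key"], events["place_key"])) == oracle

    def test_generator_duplication_ground_truth(self):
        config = SimConfig(
            n_background_sites=4, clusters=(), days=15, s_true=40, pool_size=80,
            duplication_rate=0.12, frac_ungeoreferenced=0.0, offset_rate=0.0,
            partial_date_rate=0.0, seed=11,
        )
        table, truth = simulate(config)
        records = occ.records_from_frame(table)
        events = occ.deduplicate(records, occ.locality_place_resolver)
        assert len(table) == truth.n_base_records + truth.n_duplicates
        assert len(events) == len(truth.true_events)


def _random_records(rng, n):
    rows = []
    for _ in range(n):
        rows.append(
            {
                "taxon_raw": f"Aus sp{rng.integers(6)}",
                "year": 1960.0,
                "month": float(rng.integers(1, 4)),
                "day": float(rng.integers(1, 4)) if rng.uniform() > 0.2 else np.nan,
                "lat": float(19.0 + rng.uniform()),
                "lon": float(-100.0 + rng.uniform()),
                "source": str(rng.choice(["portal_a", "portal_b"])),
            }
        )
    records = make_records(rows)
    records["taxon"] = records["taxon_raw"]
    return records
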