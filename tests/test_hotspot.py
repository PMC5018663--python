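"""Getis-Ord Gi* scores, significance screening and hotspot merging."""

import math

import numpy as np
import pandas as pd
import pytest

from inventario import hotspot as h
from inventario.grid import CellId, GridSpec
from inventario.richness import chao2


def direct_gi_star(counts, band=1.5, include_self=True):
    """Textbook Gi* evaluated by brute force, independent of the library path."""
    cells = sorted(counts)
    x = [float(counts[c]) for c in cells]
    n = len(cells)
    xbar = sum(x) / n
    s = math.sqrt(sum(v * v for v in x) / n - xbar**2)
    out = {}
    for i, ci in enumerate(cells):
        wsum, wn = 0.0, 0.0
        for j, cj in enumerate(cells):
            d = math.hypot(ci.row - cj.row, ci.col - cj.col)
            if (i == j and include_self) or (i != j and d <= band + 1e-9):
                wsum += x[j]
                wn += 1
        denom = s * math.sqrt((n * wn - wn**2) / (n - 1))
        out[ci] = 0.0 if denom == 0 or s == 0 else (wsum - xbar * wn) / denom
    return out


def _grid_counts(values):
    """dict CellId -> count from a 2-D array."""
    values = np.asarray(values)
    return {
        CellId(r, c): int(values[r, c])
        for r in range(values.shape[0])
        for c in range(values.shape[1])
    }


class TestGiStar:
    def test_constant_counts_zero_variance_convention(self):
        counts = _grid_counts(np.full((4, 4), 7))
        results = h.gi_star(counts)
        assert (results["z"] == 0).all()
        assert h.significant_cells(results) == set()

    def test_center_spike_matches_direct_formula(self):
        values = np.zeros((5, 5), int)
        values[2, 2] = 100
        counts = _grid_counts(values)
        results = h.gi_star(counts).set_index("cell")
        oracle = direct_gi_star(counts)
        for cell, z in oracle.items():
            assert results.loc[cell, "z"] == pytest.approx(z, abs=1e-10)
        # the spike and its neighbors carry the largest scores
        top = results["z"].sort_values(ascending=False).index[:9]
        assert all(abs(c.row - 2) <= 1 and abs(c.col - 2) <= 1 for c in top)

    def test_relabeling_symmetry(self, rng):
        values = rng.poisson(3, size=(6, 7))
        counts = _grid_counts(values)
        z0 = sorted(h.gi_star(counts)["z"])
        # translate and mirror the lattice: weights move with the labels
        moved = {CellId(-c.row + 11, c.col - 5): v for c, v in counts.items()}
        z1 = sorted(h.gi_star(moved)["z"])
        assert np.allclose(z0, z1, atol=1e-12)


class TestSignificance:
    def test_threshold_arithmetic_at_99(self):
        results = pd.DataFrame(
            {
                "cell": [CellId(0, 0), CellId(5, 5)],
                "count": [10, 0],
                "z": [2.58, -4.0],
                "p": [0.00988, 6.3e-5],
            }
        )
        hot = h.significant_cells(results, confidence=0.99, fdr=False)
        assert CellId(0, 0) in hot
        assert CellId(5, 5) not in hot  # coldspots never qualify

    def test_higher_confidence_never_enlarges(self, rng):
        values = rng.poisson(2, size=(15, 15))
        values[4:7, 4:7] += 30
        results = h.gi_star(_grid_counts(values))
        strict = h.significant_cells(results, confidence=0.99)
        lax = h.significant_cells(results, confidence=0.95)
        assert strict <= lax

    def test_mean_z_near_zero_under_random_field(self, rng):
        values = rng.permutation(rng.poisson(5, size=10000)).reshape(100, 100)
        results = h.gi_star(_grid_counts(values))
        assert abs(results["z"].mean()) < 0.05


def flood_fill_components(cells):
    """Queen-contiguity components by brute-force flood fill."""
    remaining = set(cells)
    components = []
    while remaining:
        seed = remaining.pop()
        stack, comp = [seed], {seed}
        while stack:
            cur = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nxt = CellId(cur.row + dr, cur.col + dc)
                    if nxt in remaining:
                        remaining.remove(nxt)
                        comp.add(nxt)
                        stack.append(nxt)
        components.append(frozenset(comp))
    return set(components)


class TestMerge:
    def test_diagonal_touch_is_contiguous(self):
        spots = h.merge_contiguous({CellId(0, 0), CellId(1, 1)})
        assert len(spots) == 1

    def test_gap_splits(self):
        spots = h.merge_contiguous({CellId(0, 0), CellId(0, 2)})
        assert len(spots) == 2

    def test_matches_flood_fill_oracle_and_partitions(self, rng):
        for _ in range(20):
            cells = {
                CellId(int(r), int(c))
                for r, c in zip(rng.integers(0, 12, 40), rng.integers(0, 12, 40))
            }
            spots = h.merge_contiguous(cells)
            got = {frozenset(s.member_cells) for s in spots}
            assert got == flood_fill_components(cells)
            # partition: disjoint and covering
            union = set().union(*(s.member_cells for s in spots)) if spots else set()
            assert union == cells
            assert sum(len(s.member_cells) for s in spots) == len(cells)

    def test_deterministic_naming_and_area(self):
        spec = GridSpec(resolution=0.05)
        spots = h.merge_contiguous({CellId(400, -2000), CellId(400, -1999)}, spec)
        assert len(spots) == 1
        area_one_cell = 29.0  # ~0.05 deg square at lat 20
        assert spots[0].area_km2 == pytest.approx(2 * area_one_cell, rel=0.02)
        again = h.merge_contiguous({CellId(400, -1999), CellId(400, -2000)}, spec)
        assert again[0].name == spots[0].name


class TestHotspotCompleteness:
    @staticmethod
    def _planted_events(N, S_obs, a, b, cells, hotspot_name=None):
        """Event frame realizing exact incidence frequencies (N, S_obs, a, b)."""
        counts = [1] * a + [2] * b
        rest = S_obs - a - b
        remaining = N - a - 2 * b
        base = remaining // rest
        bump = remaining - base * rest
        counts += [base + (1 if i < bump else 0) for i in range(rest)]
        assert all(c >= 3 for c in counts[a + b:]) and sum(counts) == N
        rows = []
        for i, k in enumerate(counts):
            for d in range(k):
                place = cells[(i + d) % len(cells)] if hotspot_name is None else hotspot_name
                rows.append((f"sp{i:04d}", f"1960_1_{d + 1}", place))
        return pd.DataFrame(rows, columns=["taxon", "date_key", "place_key"])

    @pytest.mark.parametrize(
        "N, S_obs, a, b, s_exp",
        [(4884, 396, 41, 34, 419.4), (3821, 422, 79, 62, 470.9)],
    )
    def test_reference_hotspot_estimates(self, N, S_obs, a, b, s_exp):
        cells = [CellId(0, 0), CellId(0, 1), CellId(1, 0)]
        spot = h.Hotspot("spot", frozenset(cells), 90.0)
        events = self._planted_events(N, S_obs, a, b, cells)
        summary = h.hotspot_completeness(events, spot)
        assert summary.N == N and summary.S_obs == S_obs
        assert (summary.a, summary.b) == (a, b)
        assert summary.S_exp == pytest.approx(s_exp, abs=0.05)
        assert summary.C == pytest.approx(S_obs / chao2(N, S_obs, a, b), abs=1e-12)

    def test_same_species_same_day_in_two_member_cells_counts_once(self):
        spot = h.Hotspot("spot", frozenset({CellId(0, 0), CellId(0, 1)}), 60.0)
        events = pd.DataFrame(
            {
                "taxon": ["sp1", "sp1"],
                "date_key": ["1960_1_1", "1960_1_1"],
                "place_key": [CellId(0, 0), CellId(0, 1)],
            }
        )
        assert h.hotspot_completeness(events, spot).N == 1

    def test_no_singletons_is_complete(self):
        spot = h.Hotspot("spot", frozenset({CellId(0, 0)}), 30.0)
        events = self._planted_events(20, 5, 0, 1, [CellId(0, 0)])
        assert h.hotspot_completeness(events, spot).C == 1.0

    def test_empty_hotspot_emits_nothing(self):
        spot = h.Hotspot("spot", frozenset({CellId(9, 9)}), 30.0)
        events = pd.DataFrame(columns=["taxon", "date_key", "place_key"])
        assert h.hotspot_completeness(events, spot) is None
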