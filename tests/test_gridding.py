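import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Polygon, box

from fruitscape.gridding import (
    PRESENCE_THRESHOLD_KM2,
    build_grid,
    filter_cells,
    rasterize,
    split_large_counties,
)
from fruitscape.synthdata import (
    CountyMap,
    make_counties,
    make_landscape,
    make_occurrences,
    make_species_pool,
)

EXTENT = (0.0, 0.0, 200.0, 200.0)


def _counties(*boxes) -> CountyMap:
    units = [(f"c{i}", box(*b), box(*b).area) for i, b in enumerate(boxes)]
    return CountyMap(units=units)


def _occ(pairs) -> pd.DataFrame:
    return pd.DataFrame(pairs, columns=["species_id", "county_id"])


class TestBuildGrid:
    def test_exact_tiling_50km(self):
        g = build_grid(EXTENT, 50.0)
        assert len(g.cells) == 16
        np.testing.assert_allclose(g.land_areas(), 2500.0)

    def test_exact_tiling_100km(self):
        g = build_grid(EXTENT, 100.0)
        assert len(g.cells) == 4

    def test_halfplane_region_halves_boundary_cells(self):
        # study region covers x <= 125: cells in column 2 are split in half
        region = box(0, 0, 125, 200)
        g = build_grid(EXTENT, 50.0, study_region=region)
        areas = dict(zip(g.ids, g.land_areas()))
        assert areas["r0c2"] == pytest.approx(1250.0)
        assert areas["r0c0"] == pytest.approx(2500.0)
        assert "r0c3" not in areas  # zero-land cells dropped

    def test_empty_region_warns(self):
        with pytest.warns(UserWarning):
            g = build_grid(EXTENT, 50.0, study_region=box(900, 900, 950, 950))
        assert len(g.cells) == 0

    def test_bad_resolution(self):
        with pytest.raises(ValueError):
            build_grid(EXTENT, -1.0)


class TestRasterize:
    def test_full_cell_coverage_is_presence(self):
        # county contains the 50-km cell entirely: 2,500 km2 > threshold
        cm = _counties((0, 0, 100, 100))
        pm = rasterize(_occ([("s1", "c0")]), cm, build_grid(EXTENT, 50.0))
        t = pm.to_triplets()
        row = t[(t.species_id == "s1") & (t.cell_id == "r0c0")].iloc[0]
        assert row.coverage_km2 == pytest.approx(2500.0)
        assert row.presence == 1

    def test_1000_km2_overlap_is_absence(self):
        # county covers a 20 x 50 km strip of the cell: below 1,106.66
        cm = _counties((0, 0, 20, 50))
        pm = rasterize(_occ([("s1", "c0")]), cm, build_grid(EXTENT, 50.0))
        t = pm.to_triplets()
        row = t[(t.species_id == "s1") & (t.cell_id == "r0c0")].iloc[0]
        assert row.coverage_km2 == pytest.approx(1000.0)
        assert row.presence == 0

    def test_coverage_sums_across_counties(self):
        # two occupied counties, 600 km2 each in the same cell -> presence
        cm = _counties((0, 0, 12, 50), (12, 0, 24, 50))
        pm = rasterize(_occ([("s1", "c0"), ("s1", "c1")]), cm,
                       build_grid(EXTENT, 50.0))
        t = pm.to_triplets()
        row = t[(t.species_id == "s1") & (t.cell_id == "r0c0")].iloc[0]
        assert row.coverage_km2 == pytest.approx(1200.0)
        assert row.presence == 1

    def test_threshold_is_strict(self):
        cm = _counties((0, 0, 22.1332, 50))  # exactly 1,106.66 km2
        pm = rasterize(_occ([("s1", "c0")]), cm, build_grid(EXTENT, 50.0))
        assert pm.presence.sum() == 0

    def test_unknown_county_is_hard_error(self):
        cm = _counties((0, 0, 100, 100))
        with pytest.raises(KeyError, match="nowhere"):
            rasterize(_occ([("s1", "nowhere")]), cm, build_grid(EXTENT, 50.0))

    def test_split_large_counties_preserves_coverage(self):
        cm = _counties((0, 0, 150, 150), (150, 0, 200, 200))
        occ = _occ([("s1", "c0"), ("s2", "c1")])
        grid = build_grid(EXTENT, 50.0)
        a = rasterize(occ, cm, grid).coverage.toarray()
        b = rasterize(occ, cm, grid, max_county_km2=10000.0).coverage.toarray()
        np.testing.assert_allclose(a, b, atol=1e-9)
        parts = split_large_counties(cm, 10000.0)
        assert len(parts.units) == 4 + 1  # big county quartered


class TestFilterCells:
    def _presence(self, richness_per_cell):
        grid = build_grid(EXTENT, 50.0)
        n_sp = max(richness_per_cell)
        rows = []
        for j, r in enumerate(richness_per_cell):
            for i in range(r):
                rows.append((f"s{i}", grid.ids[j]))
        occ = pd.DataFrame(rows, columns=["species_id", "cell_id"])
        # direct construction of a PresenceMatrix via full-coverage counties
        from scipy import sparse

        from fruitscape.gridding import PresenceMatrix

        cov = np.zeros((n_sp, len(grid.cells)))
        for sp, cid in occ.itertuples(index=False):
            cov[int(sp[1:]), grid.ids.index(cid)] = 2500.0
        return grid, PresenceMatrix(
            species_ids=[f"s{i}" for i in range(n_sp)],
            cell_ids=grid.ids,
            coverage=sparse.csr_matrix(cov),
            threshold_km2=PRESENCE_THRESHOLD_KM2,
        )

    def test_min_species_is_strict(self):
        grid, pm = self._presence([5, 6] + [0] * 14)
        retained, tallies = filter_cells(grid, pm, min_species=5)
        assert retained == ["r0c1"]  # 5 species excluded, 6 retained
        assert tallies["excluded_richness"] == 15

    @pytest.mark.parametrize("strip_km,expect_retained", [(48, 4), (24, 0)])
    def test_land_area_bound(self, strip_km, expect_retained):
        # cells on a coastal strip keep land_area = 50 * strip; the half-area
        # rule (1,250 km2 at 50 km) excludes them only below 25 km of land
        region = Polygon([(0, 0), (200, 0), (200, strip_km), (0, strip_km)])
        grid = build_grid(EXTENT, 50.0, study_region=region)
        cm = _counties((0, 0, 200, 200))
        occ = _occ([(f"s{i}", "c0") for i in range(10)])
        pm = rasterize(occ, cm, grid)
        retained, tallies = filter_cells(grid, pm, min_species=0)
        assert len(retained) == expect_retained
        if expect_retained == 0:
            assert tallies["excluded_land"] == len(grid.cells)

    def test_group_richness_uses_growth_form(self):
        grid, pm = self._presence([8] * 16)
        species = pd.DataFrame(
            {"species_id": [f"s{i}" for i in range(8)],
             "growth_form": ["tree"] * 3 + ["herb"] * 5}
        )
        r_tree, _ = filter_cells(grid, pm, species, min_species=5, group="tree")
        r_herb, _ = filter_cells(grid, pm, species, min_species=4, group="herb")
        assert r_tree == []  # only 3 trees anywhere
        assert len(r_herb) == 16


@pytest.fixture(scope="module")
def synthetic_system():
    L = make_landscape(16, 16, 25.0, noise_sd=0.5, seed=21)
    C = make_counties(L, 80, 0.6, seed=21)
    sp, _ = make_species_pool(120, seed=21)
    occ = make_occurrences(sp, C, L, seed=21)
    return L, C, sp, occ


class TestInvariants:
    def test_threshold_monotonicity(self, synthetic_system):
        L, C, sp, occ = synthetic_system
        grid = build_grid(L.extent, 50.0)
        lo = rasterize(occ, C, grid, presence_threshold_km2=500.0)
        hi = rasterize(occ, C, grid, presence_threshold_km2=1500.0)
        assert (lo.presence.toarray() >= hi.presence.toarray()).all()

    def test_min_species_monotonicity(self, synthetic_system):
        L, C, sp, occ = synthetic_system
        grid = build_grid(L.extent, 50.0)
        pm = rasterize(occ, C, grid)
        r5, _ = filter_cells(grid, pm, sp, min_species=5)
        r10, _ = filter_cells(grid, pm, sp, min_species=10)
        assert set(r10) <= set(r5)

    def test_resolution_coherence(self, synthetic_system):
        # presence in a 100-km cell implies presence in >= 1 of its four
        # 50-km children when the threshold scales with cell area
        L, C, sp, occ = synthetic_system
        g100 = build_grid(L.extent, 100.0)
        g50 = build_grid(L.extent, 50.0)
        t100 = PRESENCE_THRESHOLD_KM2
        p100 = rasterize(occ, C, g100, presence_threshold_km2=t100)
        p50 = rasterize(occ, C, g50, presence_threshold_km2=t100 / 4)
        d100 = p100.presence.toarray()
        d50 = p50.presence.toarray()
        idx50 = {cid: j for j, cid in enumerate(p50.cell_ids)}
        for i in range(d100.shape[0]):
            for j in np.flatnonzero(d100[i]):
                r, c = (int(v) for v in p100.cell_ids[j][1:].split("c"))
                children = [f"r{2*r+dr}c{2*c+dc}" for dr in (0, 1) for dc in (0, 1)]
                assert any(
                    d50[i, idx50[ch]] for ch in children if ch in idx50
                ), (i, p100.cell_ids[j])

    def test_coverage_against_monte_carlo(self, synthetic_system, rng):
        L, C, sp, occ = synthetic_system
        grid = build_grid(L.extent, 50.0)
        pm = rasterize(occ, C, grid)
        polys = C.polygons()
        species = rng.choice(pm.species_ids, size=20, replace=False)
        cell_area = grid.resolution_km**2
        for s in species:
            i = pm.species_ids.index(s)
            occupied = [polys[c] for c in occ.loc[occ.species_id == s, "county_id"]]
            union = shapely.union_all(occupied)
            row = pm.coverage[i].toarray().ravel()
            j = int(np.argmax(row))
            if row[j] == 0:
                continue
            x0, y0, x1, y1 = grid.cells[j][1].bounds
            pts_x = rng.uniform(x0, x1, 30000)
            pts_y = rng.uniform(y0, y1, 30000)
            frac = shapely.contains_xy(union, pts_x, pts_y).mean()
            assert abs(frac * cell_area - row[j]) <= 0.01 * cell_area
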