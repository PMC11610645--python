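import numpy as np
import pytest

from conftest import catchment_oracle

from stygoscale.buffers import (
    BufferSpec,
    compute_proportions_table,
    delineate_catchment_buffer,
    extract_proportions,
    make_round_buffer,
)
from stygoscale.errors import ExtractionError, GeometryError
from stygoscale.rasters import CLASS_CODES, Raster


def flat_dem(n=60, res=10.0):
    return Raster(np.zeros((n, n)), res)


class TestRoundBuffer:
    def test_degenerate_radius_is_site_cell(self):
        dem = flat_dem()
        region = make_round_buffer(255.0, 255.0, 4.0, dem)
        assert region.cell_set() == {dem.cell_at(255.0, 255.0)}

    def test_matches_exhaustive_distance_test(self):
        dem = flat_dem()
        site = (305.0, 305.0)  # a cell center
        region = make_round_buffer(*site, 50.0, dem)
        brute = set()
        for r in range(dem.ny):
            for c in range(dem.nx):
                x, y = dem.cell_center(r, c)
                if (x - site[0]) ** 2 + (y - site[1]) ** 2 <= 50.0**2:
                    brute.add((r, c))
        assert region.cell_set() == brute

    def test_area_approximates_circle(self):
        dem = Raster(np.zeros((500, 500)), 10.0)
        region = make_round_buffer(2505.0, 2505.0, 200.0, dem)
        assert abs(region.area / (np.pi * 200.0**2) - 1.0) < 0.05

    def test_truncation_flag(self):
        dem = flat_dem()
        region = make_round_buffer(30.0, 30.0, 100.0, dem)
        assert region.truncated


class TestCatchment:
    def test_flat_dem_equals_round(self):
        dem = flat_dem()
        catch = delineate_catchment_buffer(255.0, 255.0, 150.0, dem)
        rnd = make_round_buffer(255.0, 255.0, 150.0, dem)
        assert catch.cell_set() == rnd.cell_set()

    def test_uphill_everywhere_equals_round(self):
        n = 60
        rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        site = (305.0, 305.0)
        dem0 = Raster(np.zeros((n, n)), 10.0)
        sr, sc = dem0.cell_at(*site)
        dist = np.hypot(rows - sr, cols - sc)
        dem = Raster(dist * 2.0, 10.0)  # strictly increasing away from site
        catch = delineate_catchment_buffer(*site, 150.0, dem)
        rnd = make_round_buffer(*site, 150.0, dem)
        assert catch.cell_set() == rnd.cell_set()

    def test_valley_blocks_far_hill(self):
        """A second hill across a deep valley joins only if the valley is
        narrower than the 50 m gap threshold."""
        n = 50
        elev = np.zeros((n, n))
        dem = Raster(elev, 10.0)
        site = (105.0, 245.0)
        sr, sc = dem.cell_at(*site)
        # valley: a vertical strip 6 cells (60 m) wide, 20 m deep
        wide = elev.copy()
        wide[:, 15:21] = -20.0
        deep_wide = Raster(wide, 10.0)
        region = delineate_catchment_buffer(*site, 200.0, deep_wide)
        cols = {c for _, c in region.cell_set()}
        assert max(cols) < 15  # site hill only; far hill (cols >= 21) discarded
        # narrow the valley to 4 cells (40 m gap + 10 m = 50 m hop): reconnects
        narrow = elev.copy()
        narrow[:, 17:21] = -20.0
        region2 = delineate_catchment_buffer(*site, 200.0, Raster(narrow, 10.0))
        cols2 = {c for _, c in region2.cell_set()}
        assert max(cols2) > 20

    def test_matches_bruteforce_oracle(self, random_dem_factory):
        rng = np.random.default_rng(7)
        for seed in range(20):
            dem = random_dem_factory(seed)
            sx = float(rng.uniform(150, 350))
            sy = float(rng.uniform(150, 350))
            size = float(rng.choice([80.0, 120.0, 180.0]))
            region = delineate_catchment_buffer(sx, sy, size, dem)
            assert region.cell_set() == catchment_oracle(sx, sy, size, dem)

    def test_infinite_drop_reduces_to_round(self, random_dem_factory):
        dem = random_dem_factory(3)
        catch = delineate_catchment_buffer(255.0, 255.0, 150.0, dem,
                                           drop_m=np.inf)
        rnd = make_round_buffer(255.0, 255.0, 150.0, dem)
        assert catch.cell_set() == rnd.cell_set()

    def test_infinite_gap_keeps_all_qualifying(self, random_dem_factory):
        dem = random_dem_factory(4)
        site = (255.0, 255.0)
        inf_gap = delineate_catchment_buffer(*site, 150.0, dem, gap_m=np.inf)
        rnd = make_round_buffer(*site, 150.0, dem)
        sr, sc = dem.cell_at(*site)
        expect = {
            (r, c)
            for (r, c) in rnd.cell_set()
            if dem.values[r, c] >= dem.values[sr, sc] - 5.0 or (r, c) == (sr, sc)
        }
        assert inf_gap.cell_set() == expect

    def test_subset_and_monotonicity(self, random_dem_factory):
        dem = random_dem_factory(5)
        site = (255.0, 255.0)
        prev_round, prev_catch = set(), set()
        for size in (50.0, 100.0, 200.0):
            rnd = make_round_buffer(*site, size, dem).cell_set()
            catch = delineate_catchment_buffer(*site, size, dem).cell_set()
            assert catch <= rnd
            assert dem.cell_at(*site) in catch
            assert prev_round <= rnd and prev_catch <= catch
            prev_round, prev_catch = rnd, catch


class TestProportions:
    def test_uniform_forest(self):
        dem = flat_dem()
        lu = Raster(np.zeros((60, 60), dtype=np.uint8), 10.0)
        region = make_round_buffer(255.0, 255.0, 100.0, dem)
        props = extract_proportions(region, lu)
        assert props.forest == 1.0 and props.crop == 0.0

    def test_counting(self):
        lu_vals = np.zeros((60, 60), dtype=np.uint8)
        region = make_round_buffer(255.0, 255.0, 100.0, flat_dem())
        rows, cols = region.rows, region.cols
        lu_vals[rows[:4], cols[:4]] = CLASS_CODES["forest"]
        lu_vals[rows[4:], cols[4:]] = CLASS_CODES["crop"]
        props = extract_proportions(region, Raster(lu_vals, 10.0))
        assert props.forest == pytest.approx(4 / region.n_cells)
        assert props.crop == pytest.approx(1 - 4 / region.n_cells)
        assert sum(props.as_dict().values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_exhaustive_tally(self, rng):
        lu = Raster(rng.integers(0, 5, (60, 60)).astype(np.uint8), 10.0)
        region = make_round_buffer(305.0, 305.0, 60.0, flat_dem())
        props = extract_proportions(region, lu)
        tally = {k: 0 for k in range(5)}
        for r, c in region.cell_set():
            tally[int(lu.values[r, c])] += 1
        for code, name in enumerate(("forest", "pasture", "crop",
                                     "construction", "other")):
            assert getattr(props, name) == pytest.approx(
                tally[code] / region.n_cells)

    def test_empty_region_rejected(self):
        region = make_round_buffer(255.0, 255.0, 50.0, flat_dem())
        region.rows = region.rows[:0]
        region.cols = region.cols[:0]
        with pytest.raises(ExtractionError):
            extract_proportions(region, Raster(np.zeros((60, 60)), 10.0))


def test_proportions_table_long_format(small_study):
    props = small_study["proportions"]
    assert set(props.columns) == {"site_id", "size_m", "buffer_type",
                                  "class", "proportion"}
    sums = props.groupby(["site_id", "size_m", "buffer_type"])["proportion"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_mismatched_grids_rejected(small_study):
    import pandas as pd

    sites = small_study["sites"].head(2)
    dem = small_study["dem"]
    other = Raster(np.zeros((10, 10)), 5.0)
    with pytest.raises(GeometryError):
        compute_proportions_table(sites, dem, other, sizes=(100,))
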