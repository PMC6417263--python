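import numpy as np
import pytest
from shapely.geometry import box

from conftest import brute_force_window_mean
from fuzzyhab.landscape import (
    PolygonTieError,
    SuitabilityLookup,
    UnknownCodeError,
    atkis_lookup,
    corine_lookup,
    grid_polygons,
    merge_overrides,
    select_window_size,
    sliding_window_mean,
    suitability_from_landuse,
)
from fuzzyhab.evaluation import PresencePoints
from fuzzyhab.raster_core import GridAlignmentError, GridRaster, GridSpec


def suit(vals, nodata=-1.0, cell=100.0, origin=(0.0, None)):
    vals = np.asarray(vals, dtype=float)
    x0 = origin[0]
    y0 = vals.shape[0] * cell if origin[1] is None else origin[1]
    return GridRaster(vals, cell, (x0, y0), nodata=nodata,
                      semantics="suitability")


class TestShippedLookups:
    @pytest.mark.parametrize("code,expected", [
        (23, 0.9),   # broad-leaved forest
        (24, 0.1),   # coniferous forest
        (12, 0.0),   # non-irrigated arable land
        (2, 1.0),    # discontinuous urban fabric
        (5, 0.8),    # port areas
    ])
    def test_corine_scores(self, code, expected):
        assert corine_lookup().entries[code] == expected

    def test_not_applicable_classes_absent(self):
        # e.g. rice fields, olive groves: no score in the source table
        entries = corine_lookup().entries
        for absent in (13, 14, 17, 19, 22, 28, 33, 38):
            assert absent not in entries

    def test_atkis_scores(self):
        lut = atkis_lookup()
        scores = {lbl: s for lbl, s in zip(
            ("Cemeteries", "Landfill sites", "Garden centres", "Gardens",
             "Zoological gardens"), (1.0, 0.2, 1.0, 1.0, 1.0))}
        import pandas as pd
        from fuzzyhab.landscape import _packaged_csv
        df = pd.read_csv(_packaged_csv("atkis_suitability.csv"))
        for row in df.itertuples():
            assert lut.entries[row.code] == scores[row.label]

    def test_lookup_rejects_out_of_range_scores(self):
        with pytest.raises(ValueError):
            SuitabilityLookup({1: 1.2})


class TestReclassification:
    def test_cellwise_lookup_and_nodata(self):
        landuse = GridRaster(np.array([[23.0, 24.0], [12.0, -9999.0]]),
                             100.0, (0.0, 200.0), nodata=-9999.0,
                             semantics="categorical")
        out = suitability_from_landuse(landuse, corine_lookup())
        np.testing.assert_allclose(out.values[0], [0.9, 0.1])
        assert out.values[1, 0] == 0.0
        assert out.values[1, 1] == -9999.0
        assert out.semantics == "suitability"

    def test_unknown_code_strict_lists_codes(self):
        landuse = GridRaster(np.array([[23.0, 999.0]]), 100.0, (0.0, 100.0),
                             semantics="categorical")
        with pytest.raises(UnknownCodeError, match="999"):
            suitability_from_landuse(landuse, corine_lookup())

    def test_unknown_code_permissive_maps_to_nodata(self):
        landuse = GridRaster(np.array([[23.0, 999.0]]), 100.0, (0.0, 100.0),
                             nodata=-9999.0, semantics="categorical")
        out = suitability_from_landuse(landuse, corine_lookup(), strict=False)
        assert out.values[0, 1] == -9999.0

    def test_nodata_count_preserved_with_full_coverage(self):
        rng = np.random.default_rng(5)
        codes = rng.choice([23, 24, 12, 2], size=(6, 6)).astype(float)
        codes[rng.random((6, 6)) < 0.2] = -9999.0
        landuse = GridRaster(codes, 100.0, (0.0, 600.0), nodata=-9999.0,
                             semantics="categorical")
        out = suitability_from_landuse(landuse, corine_lookup())
        assert out.nodata_mask().sum() == landuse.nodata_mask().sum()


class TestMergeOverrides:
    def test_override_semantics(self):
        base = suit([[0.2, 0.2], [-1.0, -1.0]])
        override = suit([[1.0, -1.0], [0.5, -1.0]])
        out = merge_overrides(base, override)
        assert out.values[0, 0] == 1.0     # override wins
        assert out.values[0, 1] == 0.2     # base kept where override nodata
        assert out.values[1, 0] == 0.5
        assert out.values[1, 1] == -1.0    # both nodata -> nodata

    def test_idempotent(self):
        base = suit([[0.2, 0.4]])
        override = suit([[1.0, -1.0]])
        once = merge_overrides(base, override)
        twice = merge_overrides(once, override)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_misaligned_grids_rejected(self):
        base = suit([[0.2]])
        override = suit([[0.2]], origin=(50.0, 100.0))
        with pytest.raises(GridAlignmentError):
            merge_overrides(base, override)


class TestSlidingWindowMean:
    def test_constant_raster_unchanged(self):
        r = suit(np.full((6, 6), 0.4))
        for w in (1, 3, 5):
            np.testing.assert_allclose(sliding_window_mean(r, w).values, 0.4)

    def test_center_and_corner_of_single_spike(self):
        r = suit([[0, 0, 0], [0, 0.9, 0], [0, 0, 0]])
        out = sliding_window_mean(r, 3)
        assert out.values[1, 1] == pytest.approx(0.1)
        # the corner window is truncated to its 4 in-bounds cells
        assert out.values[0, 0] == pytest.approx(0.225)

    def test_window_one_is_identity(self, small_raster):
        out = sliding_window_mean(small_raster, 1)
        np.testing.assert_array_equal(out.values, small_raster.values)

    def test_even_window_rejected(self, small_raster):
        with pytest.raises(ValueError, match="odd"):
            sliding_window_mean(small_raster, 4)

    def test_nodata_cells_stay_nodata(self, small_raster):
        out = sliding_window_mean(small_raster, 3)
        np.testing.assert_array_equal(out.nodata_mask(),
                                      small_raster.nodata_mask())

    def test_matches_brute_force_on_seeded_instances(self):
        rng = np.random.default_rng(2024)
        for case in range(100):
            nr, nc = rng.integers(2, 21, size=2)
            vals = rng.random((nr, nc)).round(3)
            vals[rng.random((nr, nc)) < 0.15] = -1.0
            if (vals == -1.0).all():
                vals[0, 0] = 0.5
            r = suit(vals)
            w = int(rng.choice([1, 3, 5]))
            got = sliding_window_mean(r, w).values
            want = brute_force_window_mean(vals, -1.0, w)
            np.testing.assert_allclose(got, want, atol=1e-12,
                                       err_msg=f"case {case}, window {w}")

    def test_output_within_input_bounds(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0.2, 0.8, size=(15, 15))
        r = suit(vals)
        out = sliding_window_mean(r, 5).values
        assert out.min() >= vals.min() - 1e-12
        assert out.max() <= vals.max() + 1e-12


class TestGridPolygons:
    target = GridSpec(100.0, (0.0, 0.0, 300.0, 300.0))

    def test_majority_fill_assigns_category(self):
        # covers 60% of cell (2, 0)
        poly = box(0.0, 0.0, 60.0, 100.0)
        out = grid_polygons([(poly, 7)], self.target)
        assert out.values[2, 0] == 7

    def test_minority_fill_stays_nodata(self):
        poly = box(0.0, 0.0, 30.0, 100.0)  # 30%
        out = grid_polygons([(poly, 7)], self.target)
        assert out.values[2, 0] == out.nodata

    def test_exact_cover_and_zero_cover(self):
        poly = box(100.0, 100.0, 200.0, 200.0)  # exactly cell (1, 1)
        out = grid_polygons([(poly, 3)], self.target)
        assert out.values[1, 1] == 3
        assert (out.values == out.nodata).sum() == 8

    def test_threshold_boundary_is_inclusive(self):
        poly = box(0.0, 0.0, 51.0, 100.0)  # exactly 51%
        out = grid_polygons([(poly, 7)], self.target)
        assert out.values[2, 0] == 7

    def test_tie_raises_without_priority(self):
        a = box(0.0, 0.0, 100.0, 100.0)
        b = box(0.0, 0.0, 100.0, 100.0)
        with pytest.raises(PolygonTieError):
            grid_polygons([(a, 1), (b, 2)], self.target)
        out = grid_polygons([(a, 1), (b, 2)], self.target, priority=[2, 1])
        assert out.values[2, 0] == 2


class TestWindowSelection:
    def test_constant_raster_degenerate_histogram(self):
        r = suit(np.full((10, 10), 0.5))
        pts = PresencePoints([150.0, 450.0], [350.0, 650.0])
        diag = select_window_size(r, pts, [100.0])
        assert diag.modality == [1]
        assert diag.skewness == [0.0]

    def test_default_edge_lengths_valid_on_100m_cells(self):
        r = suit(np.full((12, 12), 0.5))
        pts = PresencePoints([250.0], [250.0])
        diag = select_window_size(r, pts,
                                  [100, 300, 500, 700, 900, 1100])
        assert diag.window_px == [1, 3, 5, 7, 9, 11]

    def test_even_pixel_edge_rejected(self):
        r = suit(np.full((5, 5), 0.5))
        pts = PresencePoints([150.0], [150.0])
        with pytest.raises(ValueError, match="odd multiple"):
            select_window_size(r, pts, [200.0])

    def test_modality_transition_on_patchy_landscape(self, small_bundle):
        """Raw patchy suitability gives a multimodal point histogram;
        smoothing produces a unimodal, left-skewed one (the window
        selection signal)."""
        from fuzzyhab.landscape import suitability_from_landuse
        raw = suitability_from_landuse(small_bundle["landuse"],
                                       small_bundle["lookup"])
        pts = small_bundle["presences"]
        diag = select_window_size(raw, pts, [100, 300, 500, 700, 900])
        assert diag.modality[0] > 1, "unsmoothed histogram should be multimodal"
        assert diag.recommended is not None
        k = diag.window_edge_lengths.index(diag.recommended)
        assert diag.modality[k] == 1
        assert diag.skewness[k] < 0
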