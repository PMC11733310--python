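import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from batscape import (
    CLASSES,
    CLASS_TO_TYPE,
    Grid,
    LandCoverLayer,
    LandCoverSummarizer,
    Parcel,
    class_summaries,
    extract_parcel_totals,
    harmonize,
    rank_and_ratios,
)
from batscape.landcover import STUDY_WIDE, default_mapping
from batscape.synthetic import LandscapeConfig, simulate_activity, simulate_landcover
from batscape.presence import to_rate
from batscape.roost import DecayParams, correct_activity


def test_every_class_maps_to_exactly_one_of_four_types():
    assert len(CLASSES) == 13
    assert set(CLASS_TO_TYPE.values()) == {"agricultural", "natural", "urban/other", "water"}
    # mapping is total over the vocabulary
    assert set(CLASS_TO_TYPE) == set(CLASSES)


def test_default_mapping_targets_are_valid_and_include_both_sources():
    mapping = default_mapping()
    assert set(mapping.values()) <= set(CLASSES)
    assert mapping["agriculture"] == "miscellaneous"  # natural-layer remnants
    assert mapping["rice"] == "rice"
    assert mapping["almonds"] == "fruits/nuts/vineyards"


class TestHarmonize:
    def test_crop_label_takes_precedence_over_natural(self):
        natural = [(box(0, 0, 100, 100), "grassland")]
        crop = [(box(0, 0, 100, 100), "rice")]
        layer = harmonize(natural, crop)
        assert len(layer) == 1
        assert layer.parcels[0].lc_class == "rice"
        assert layer.parcels[0].lc_type == "agricultural"

    def test_uncovered_natural_agriculture_becomes_miscellaneous(self):
        layer = harmonize([(box(0, 0, 100, 100), "agriculture")], [])
        assert layer.parcels[0].lc_class == "miscellaneous"

    def test_disjoint_layers_conserve_area(self):
        natural = [(box(0, 0, 100, 100), "conifer")]
        crop = [(box(200, 0, 300, 100), "rice")]
        layer = harmonize(natural, crop)
        assert layer.total_area_ha == pytest.approx(2 * 100 * 100 / 1e4)
        assert {p.lc_class for p in layer.parcels} == {"conifer", "rice"}

    def test_partial_overlap_splits_the_natural_parcel(self):
        natural = [(box(0, 0, 200, 100), "grassland")]
        crop = [(box(100, 0, 200, 100), "tomatoes")]
        layer = harmonize(natural, crop)
        by_class = {p.lc_class: p.area_ha for p in layer.parcels}
        assert by_class["row/field crops"] == pytest.approx(1.0)
        assert by_class["grassland"] == pytest.approx(1.0)

    def test_unmapped_label_is_a_hard_error_naming_it(self):
        with pytest.raises(ValueError, match="spaceport"):
            harmonize([(box(0, 0, 1, 1), "spaceport")], [])


def _pixel_layer(grid: Grid, assignments: dict[str, list[tuple[int, int]]]) -> LandCoverLayer:
    """Build one parcel per class from explicit (row, col) pixel lists."""
    from shapely.ops import unary_union

    ps = grid.pixel_size
    parcels = []
    for cls, pixels in assignments.items():
        boxes = [
            box(c * ps, (grid.nrows - r - 1) * ps, (c + 1) * ps, (grid.nrows - r) * ps)
            for r, c in pixels
        ]
        parcels.append(Parcel(geometry=unary_union(boxes), raw_label=cls, lc_class=cls))
    return LandCoverLayer(parcels)


class TestExtractParcelTotals:
    def test_four_pixel_parcel_mean(self):
        g = Grid(nrows=2, ncols=2, pixel_size=70.0)
        layer = _pixel_layer(g, {"rice": [(0, 0), (0, 1), (1, 0), (1, 1)]})
        rate = np.array([[1.0, 1.0], [3.0, 3.0]])
        table = extract_parcel_totals(rate, g, layer)
        assert table["mean_rate"].iloc[0] == pytest.approx(2.0)
        assert table["area_ha"].iloc[0] == pytest.approx(4 * 0.49)

    def test_fully_masked_parcel_is_missing(self):
        g = Grid(nrows=2, ncols=2, pixel_size=70.0)
        layer = _pixel_layer(g, {"rice": [(0, 0), (0, 1)], "urban": [(1, 0), (1, 1)]})
        rate = np.array([[np.nan, np.nan], [2.0, 4.0]])
        table = extract_parcel_totals(rate, g, layer).set_index("lc_class")
        assert np.isnan(table.loc["rice", "mean_rate"])
        assert table.loc["urban", "mean_rate"] == pytest.approx(3.0)

    def test_matches_brute_force_zonal_oracle(self, rng):
        cfg = LandscapeConfig(
            grid_width=30, grid_height=30, n_nights=5, scans_per_night=10,
            n_patches=100, mosquito_coupling=0.0, seed=11,
        )
        layer = simulate_landcover(cfg)
        raster = simulate_activity(cfg, layer)
        rate = to_rate(raster)
        table = extract_parcel_totals(rate, cfg.grid, layer)
        pid = layer.rasterize(cfg.grid)
        for _, row in table.iterrows():
            vals = [
                rate[i, j]
                for i in range(cfg.grid.nrows)
                for j in range(cfg.grid.ncols)
                if pid[i, j] == row["parcel_id"] and np.isfinite(rate[i, j])
            ]
            if vals:
                assert row["mean_rate"] == pytest.approx(np.mean(vals), rel=1e-12)
            else:
                assert np.isnan(row["mean_rate"])

    def test_total_occurrences_backed_out_from_rate(self):
        g = Grid(nrows=1, ncols=2, pixel_size=70.0)
        layer = _pixel_layer(g, {"rice": [(0, 0), (0, 1)]})
        rate = np.array([[2.0, 4.0]])
        table = extract_parcel_totals(rate, g, layer, n_nights=10)
        assert table["total_occurrences"].iloc[0] == pytest.approx(3.0 * 0.98 * 10)


def _parcel_frame(rows):
    return pd.DataFrame(
        rows, columns=["lc_class", "mean_rate", "area_ha"]
    ).assign(lc_type=lambda d: d["lc_class"].map(CLASS_TO_TYPE))


class TestClassSummaries:
    def test_equal_area_parcels_average_evenly(self):
        table = _parcel_frame([("rice", 10.0, 2.0), ("rice", 20.0, 2.0)])
        out = class_summaries(table, n_boot=50, seed=0)
        rice = out[out["lc_class"] == "rice"].iloc[0]
        assert rice["mean_rate"] == pytest.approx(15.0)

    def test_hand_weighted_average(self):
        table = _parcel_frame([("rice", 10.0, 1.0), ("rice", 20.0, 3.0)])
        out = class_summaries(table, n_boot=50, seed=0)
        assert out[out["lc_class"] == "rice"]["mean_rate"].iloc[0] == pytest.approx(17.5)

    def test_ci_brackets_mean_and_singleton_class_has_no_ci(self):
        table = _parcel_frame(
            [("rice", 10.0, 1.0), ("rice", 20.0, 3.0), ("urban", 5.0, 1.0)]
        )
        out = class_summaries(table, n_boot=200, seed=1).set_index("lc_class")
        assert out.loc["rice", "ci_lo"] <= out.loc["rice", "mean_rate"] <= out.loc["rice", "ci_hi"]
        assert np.isnan(out.loc["urban", "ci_lo"]) and np.isnan(out.loc["urban", "ci_hi"])

    def test_study_wide_mean_consistent_with_total_over_area(self):
        """The area-weighted study mean equals total occurrences divided by
        (total area x nights) — the two aggregation paths must agree."""
        cfg = LandscapeConfig(
            grid_width=25, grid_height=25, n_nights=6, scans_per_night=12,
            mosquito_coupling=0.0, seed=5, n_patches=40,
        )
        layer = simulate_landcover(cfg)
        raster = simulate_activity(cfg, layer)
        rate = to_rate(raster)
        table = extract_parcel_totals(rate, cfg.grid, layer, n_nights=cfg.n_nights)
        out = class_summaries(table, n_boot=10, seed=0)
        study = out[out["lc_class"] == STUDY_WIDE].iloc[0]
        direct = raster.counts.sum() / (table["area_ha"].sum() * cfg.n_nights)
        assert study["mean_rate"] == pytest.approx(direct, rel=1e-9)

    def test_seeded_bootstrap_is_reproducible(self):
        table = _parcel_frame([("rice", 10.0, 1.0), ("rice", 20.0, 3.0), ("rice", 12.0, 2.0)])
        a = class_summaries(table, n_boot=100, seed=42)
        b = class_summaries(table, n_boot=100, seed=42)
        pd.testing.assert_frame_equal(a, b)


class TestRankAndRatios:
    def test_rice_to_barren_ratio(self):
        table = _parcel_frame(
            [("rice", 28.56, 1.0), ("barren/other", 19.04, 1.0)]
        )
        ranked = rank_and_ratios(class_summaries(table, n_boot=10, seed=0))
        assert ranked.iloc[0]["lc_class"] == "rice"
        assert ranked.iloc[0]["ratio_to_next"] == pytest.approx(1.5)

    def test_single_class_ratio_to_self(self):
        table = _parcel_frame([("rice", 10.0, 1.0)])
        ranked = rank_and_ratios(class_summaries(table, n_boot=10, seed=0))
        assert len(ranked) == 1
        assert ranked.iloc[0]["ratio_to_next"] == 1.0

    def test_all_equal_means_are_alphabetical_with_unit_ratios(self):
        table = _parcel_frame(
            [("urban", 7.0, 1.0), ("conifer", 7.0, 1.0), ("rice", 7.0, 1.0)]
        )
        ranked = rank_and_ratios(class_summaries(table, n_boot=10, seed=0))
        assert list(ranked["lc_class"]) == ["conifer", "rice", "urban"]
        assert np.allclose(ranked["ratio_to_next"], 1.0)


def test_rice_ranks_first_when_simulated_twice_as_attractive():
    """With rice foraging weight 2x every other class, the area-weighted
    ranking should recover rice on top in nearly every replicate."""
    weights = {c: 1.0 for c in LandscapeConfig().class_weights}
    weights["rice"] = 2.0
    wins = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = LandscapeConfig(
            grid_width=30, grid_height=30, n_nights=10, scans_per_night=30,
            class_weights=weights, commute_amplitude=0.0,
            mosquito_coupling=0.0, seed=seed, n_patches=50,
        )
        layer = simulate_landcover(cfg)
        rate = to_rate(simulate_activity(cfg, layer))
        table = extract_parcel_totals(rate, cfg.grid, layer)
        ranked = rank_and_ratios(class_summaries(table, n_boot=10, seed=seed))
        wins += ranked.iloc[0]["lc_class"] == "rice"
    assert wins >= int(0.95 * n_seeds)


def test_summarizer_estimator_on_corrected_surface():
    cfg = LandscapeConfig(
        grid_width=25, grid_height=25, n_nights=8, scans_per_night=20,
        mosquito_coupling=0.0, seed=2, n_patches=40,
    )
    layer = simulate_landcover(cfg)
    raster = simulate_activity(cfg, layer)
    corrected = correct_activity(raster, cfg.roost_set, DecayParams())
    est = LandCoverSummarizer(layer=layer, n_boot=100, seed=3).fit((corrected, cfg.grid))
    assert est.study_mean_ > 0
    assert est.ranking_["rank"].iloc[0] == 1
    assert set(est.summaries_["lc_class"]) - {STUDY_WIDE} <= set(CLASSES)
    assert est.get_params()["n_boot"] == 100


def test_geojson_roundtrip(tmp_path):
    layer = _pixel_layer(
        Grid(nrows=2, ncols=2, pixel_size=70.0),
        {"rice": [(0, 0), (0, 1)], "urban": [(1, 0), (1, 1)]},
    )
    path = tmp_path / "lc.geojson"
    layer.to_geojson(path)
    back = LandCoverLayer.from_geojson(path)
    assert {p.lc_class for p in back.parcels} == {"rice", "urban"}
    assert back.total_area_ha == pytest.approx(layer.total_area_ha)
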