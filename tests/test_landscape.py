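"""Synthetic landscape generator: placement, partition, generative truth."""

import numpy as np
import pytest
import shapely
from scipy.optimize import brentq
from scipy.stats import spearmanr

from chacoedge import (
    GenerativeParams,
    LandscapeConfig,
    PlacementError,
    generate_landscape,
    simulate_structure,
)
from chacoedge.constants import LAND_USES
from chacoedge.landscape import cell_predictors

from .conftest import SMALL_CFG

TINY = dict(SMALL_CFG, n_rows=60, n_cols=60, n_plots=5, placement_margin=600.0)


def _flat_params(**over):
    base = dict(
        intercept=dict.fromkeys(LAND_USES, 0.0),
        b_dist=dict.fromkeys(LAND_USES, 0.0),
        b_age=dict.fromkeys(LAND_USES, 0.0),
        b_int=dict.fromkeys(LAND_USES, 0.0),
        noise_sd=1e-12,
        response_log_mean=4.0,
        response_log_sd=0.3,
    )
    base.update(over)
    return GenerativeParams(**base)


def test_zero_plots_gives_all_forest():
    land, plots = generate_landscape(LandscapeConfig(**dict(TINY, n_plots=0)), seed=0)
    assert plots == []
    assert land.forest_mask.all()


def test_plot_cells_and_forest_cells_partition_the_grid(small_landscape):
    land, plots = small_landscape
    X, Y = land.cell_centers()
    in_any_plot = np.zeros(land.shape, dtype=bool)
    for p in plots:
        in_any_plot |= shapely.contains_xy(p.polygon, X, Y)
    assert not (in_any_plot & land.forest_mask).any()
    assert (in_any_plot | land.forest_mask).all()


def test_plots_pairwise_disjoint(small_landscape):
    _, plots = small_landscape
    for i, a in enumerate(plots):
        for b in plots[i + 1 :]:
            assert not a.polygon.intersects(b.polygon)


def test_same_seed_reproduces_bit_identical_landscape():
    cfg = LandscapeConfig(**TINY)
    a_land, a_plots = generate_landscape(cfg, seed=9)
    b_land, b_plots = generate_landscape(cfg, seed=9)
    assert np.array_equal(a_land.forest_mask, b_land.forest_mask)
    for k in a_land.covariates:
        assert np.array_equal(a_land.covariates[k], b_land.covariates[k])
    assert [p.year_cleared for p in a_plots] == [p.year_cleared for p in b_plots]
    assert [p.land_use for p in a_plots] == [p.land_use for p in b_plots]
    assert all(a.polygon.equals(b.polygon) for a, b in zip(a_plots, b_plots))


def test_unsatisfiable_placement_raises():
    cfg = LandscapeConfig(
        **dict(TINY, n_plots=60, plot_side_range=(900.0, 1400.0), max_placement_attempts=30)
    )
    with pytest.raises(PlacementError, match="could not place"):
        generate_landscape(cfg, seed=0)


def test_all_land_uses_represented(small_landscape):
    _, plots = small_landscape
    assert {p.land_use for p in plots} == set(LAND_USES)


def test_null_model_structure_is_constant():
    """All slopes zero and vanishing noise: every forest cell sits at the
    back-transformed intercept."""
    land, plots = generate_landscape(LandscapeConfig(**TINY), seed=3)
    simulate_structure(land, plots, _flat_params(), seed=4, variables=("agb",))
    vals = land.structure["agb"][land.forest_mask]
    expected = np.exp(4.0) - 1.0
    assert np.allclose(vals, expected, atol=1e-6)


def test_positive_distance_slope_gives_positive_rank_correlation():
    land, plots = generate_landscape(LandscapeConfig(**TINY), seed=5)
    params = _flat_params(b_dist=dict.fromkeys(LAND_USES, 0.5), noise_sd=0.05)
    simulate_structure(land, plots, params, seed=6, variables=("agb",))
    preds = cell_predictors(land, plots)
    vals = land.structure["agb"][preds["rows"], preds["cols"]]
    sub = np.random.default_rng(0).choice(vals.size, 500, replace=False)
    rho, _ = spearmanr(preds["distance"][sub], vals[sub])
    assert rho > 0.5


def test_model_matched_equals_per_cell_oracle():
    """Noise sd -> 0: raster equals an independently coded per-cell linear
    predictor on the log scale to 1e-9."""
    land, plots = generate_landscape(LandscapeConfig(**TINY), seed=7)
    params = _flat_params(
        intercept={"cropland": 0.2, "pasture": 0.0, "silvopasture": -0.2},
        b_dist={"cropland": 0.4, "pasture": 0.2, "silvopasture": 0.1},
        b_age={"cropland": -0.1, "pasture": -0.05, "silvopasture": 0.0},
        b_int={"cropland": 0.05, "pasture": 0.02, "silvopasture": 0.0},
        cov_slopes={"temp": -0.1, "precip": 0.15, "dist_time": 0.1, "dist_home": 0.05,
                    "dist_roads": 0.05},
    )
    simulate_structure(land, plots, params, seed=8, variables=("agb",))

    # independent oracle: explicit per-cell loop, own standardization
    rows, cols = np.nonzero(land.forest_mask)
    X, Y = land.cell_centers()
    survey = 2020
    geoms = [p.polygon for p in plots]
    years = [p.year_cleared for p in plots]
    uses = [p.land_use for p in plots]
    raw = {k: [] for k in ("distance", "age", "lc", "temp", "precip", "dist_time",
                           "dist_home", "dist_roads")}
    for r, c in zip(rows, cols):
        pt = shapely.Point(X[r, c], Y[r, c])
        ds = [pt.distance(g) for g in geoms]
        j = int(np.argmin(ds))
        raw["distance"].append(ds[j])
        raw["age"].append(survey - years[j])
        raw["lc"].append(uses[j])
        raw["temp"].append(land.covariates["temp"][r, c])
        raw["precip"].append(land.covariates["precip"][r, c])
        first = min(years)
        dt = 0.0
        for yr in range(first, 2021):
            dt += min(d for d, y in zip(ds, years) if y <= yr)
        raw["dist_time"].append(dt)
        raw["dist_home"].append(min(np.hypot(pt.x - h[0], pt.y - h[1]) for h in land.homesteads))
        raw["dist_roads"].append(min(pt.distance(rd) for rd in land.roads))

    dist = np.array(raw["distance"])
    ref = dist <= params.reference_distance

    def z(x, log=False):
        x = np.asarray(x, dtype=float)
        if log:
            x = np.log(x + 1.0)
        return (x - x[ref].mean()) / x[ref].std()

    zd, za = z(raw["distance"], log=True), z(raw["age"], log=True)
    eta = np.array([params.intercept[lu] for lu in raw["lc"]])
    eta += np.array([params.b_dist[lu] for lu in raw["lc"]]) * zd
    eta += np.array([params.b_age[lu] for lu in raw["lc"]]) * za
    eta += np.array([params.b_int[lu] for lu in raw["lc"]]) * zd * za
    for term in ("temp", "precip", "dist_time", "dist_home", "dist_roads"):
        eta += params.cov_slopes[term] * z(raw[term])
    expected_log = eta * 0.3 + 4.0

    got_log = np.log(land.structure["agb"][rows, cols] + 1.0)
    assert np.abs(got_log - expected_log).max() < 1e-9


def test_mechanistic_ninety_percent_point_matches_closed_form():
    """M=0.5, lambda=200 m, saturated age lag: the profile reaches 90% of the
    far-field value at -200 ln(0.2) ~ 321.9 m (verified by root-finding)."""
    d_star = brentq(lambda d: (1 - 0.5 * np.exp(-d / 200.0)) - 0.9, 1.0, 2000.0)
    assert abs(d_star - (-200.0 * np.log(0.2))) < 1e-9

    land, plots = generate_landscape(LandscapeConfig(**TINY), seed=9)
    params = GenerativeParams(
        mode="mechanistic",
        fs_far=80.0,
        magnitude=dict.fromkeys(LAND_USES, 0.5),
        efold=dict.fromkeys(LAND_USES, 200.0),
        lag_rate=1e6,
        noise_sd=1e-12,
    )
    simulate_structure(land, plots, params, seed=10, variables=("agb",))
    preds = cell_predictors(land, plots)
    vals = land.structure["agb"][preds["rows"], preds["cols"]]
    aged = preds["age"] >= 1
    expected = 80.0 * (1 - 0.5 * np.exp(-preds["distance"][aged] / 200.0))
    assert np.allclose(vals[aged], expected, rtol=1e-9)
    # cells just beyond d* sit above 90% of far field, cells before it below
    below = preds["distance"][aged] < d_star
    assert (vals[aged][below] < 0.9 * 80.0 + 1e-9).all()


def test_mechanistic_far_field_within_one_percent():
    land, plots = generate_landscape(LandscapeConfig(**TINY), seed=11)
    params = GenerativeParams(
        mode="mechanistic",
        fs_far=80.0,
        magnitude=dict.fromkeys(LAND_USES, 0.6),
        efold=dict.fromkeys(LAND_USES, 60.0),
        lag_rate=1.0,
        noise_sd=0.02,
    )
    simulate_structure(land, plots, params, seed=12, variables=("agb",))
    preds = cell_predictors(land, plots)
    far = preds["distance"] > 600.0  # 10 e-folding lengths
    assert far.sum() > 50
    far_vals = land.structure["agb"][preds["rows"], preds["cols"]][far]
    assert abs(far_vals.mean() - 80.0) / 80.0 < 0.01


def test_structure_survey_year_before_all_clearings_raises(small_landscape):
    land, plots = small_landscape
    with pytest.raises(ValueError, match="survey_year"):
        simulate_structure(land, plots, survey_year=1900, seed=0)


def test_cover_variables_bounded(small_landscape):
    land, _ = small_landscape
    for var in ("tree_cover", "shrub_cover"):
        vals = land.structure[var][land.forest_mask]
        assert vals.min() >= 0.0 and vals.max() <= 100.0
    assert land.structure["agb"][land.forest_mask].min() >= 0.0
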