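"""Edge curves, penetration depth, magnitude, and the age surface."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from chacoedge import (
    EdgeCurve,
    EdgeEffectsRegressor,
    GenerativeParams,
    LandscapeConfig,
    age_surface,
    conditional_curve,
    curve_metrics,
    edge_magnitude,
    generate_landscape,
    penetration_depth,
    sample_points,
    simulate_structure,
    standardize,
)
from chacoedge.constants import LAND_USES
from chacoedge.metrics import default_grid

from .helpers import make_design, make_draws, penetration_depth_bruteforce


def _curve(mean, grid=None, **kw):
    grid = default_grid() if grid is None else grid
    mean = np.asarray(mean, dtype=float)
    return EdgeCurve(
        variable=kw.get("variable", "agb"),
        land_use=kw.get("land_use", "cropland"),
        age=kw.get("age"),
        grid=grid,
        mean=mean,
        lo95=mean,
        hi95=mean,
    )


class TestPenetrationDepth:
    def test_flat_positive_curve_has_zero_depth(self):
        c = _curve(np.full(2001, 55.0))
        assert penetration_depth(c) == 0.0
        assert edge_magnitude(c) == 0.0

    def test_log_curve_matches_closed_form_within_one_meter(self):
        """FS(d) = ln(1+d) crosses 0.9 FS(2000) at 2001^0.9 - 1, confirmed by
        independent root-finding."""
        grid = default_grid()
        c = _curve(np.log1p(grid))
        want = brentq(lambda d: np.log1p(d) - 0.9 * np.log(2001.0), 1.0, 2000.0)
        assert want == pytest.approx(2001.0**0.9 - 1.0, abs=1e-9)
        assert abs(penetration_depth(c) - want) <= 1.0

    def test_grid_scan_equals_bruteforce_on_random_smooth_curves(self, rng):
        grid = np.arange(0.0, 2001.0, 1.0)
        for _ in range(20):
            base = rng.uniform(20, 100)
            depth = rng.uniform(0.05, 0.6)
            scale = rng.uniform(50, 900)
            mean = base * (1.0 - depth * np.exp(-grid / scale))
            got = penetration_depth(_curve(mean, grid))
            assert got == penetration_depth_bruteforce(grid, mean)

    def test_fraction_one_is_at_least_fraction_point_nine(self, rng):
        grid = default_grid()
        mean = 80.0 * (1.0 - 0.4 * np.exp(-grid / 300.0))
        c = _curve(mean, grid)
        assert penetration_depth(c, fraction=1.0) >= penetration_depth(c, fraction=0.9)

    def test_nonpositive_reference_raises(self):
        c = _curve(np.linspace(10.0, 0.0, 2001))
        with pytest.raises(ValueError, match="FS\\(2000\\)"):
            penetration_depth(c)
        with pytest.raises(ValueError, match="FS\\(2000\\)"):
            edge_magnitude(c)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.floats(min_value=0.01, max_value=100.0),
        st.floats(min_value=0.0, max_value=0.8),
        st.floats(min_value=30.0, max_value=1500.0),
    )
    def test_scale_invariance(self, factor, depth, efold):
        grid = default_grid(step=10.0)
        mean = 1.0 - depth * np.exp(-grid / efold)
        a, b = _curve(mean, grid), _curve(factor * mean, grid)
        assert penetration_depth(a) == penetration_depth(b)
        assert edge_magnitude(a) == pytest.approx(edge_magnitude(b), abs=1e-9)


class TestMagnitude:
    def test_forty_percent_reduction(self):
        mean = np.linspace(60.0, 100.0, 2001)
        assert edge_magnitude(_curve(mean)) == pytest.approx(40.0)

    def test_signed_negative_when_edge_exceeds_interior(self):
        mean = np.linspace(120.0, 100.0, 2001)
        assert edge_magnitude(_curve(mean)) == pytest.approx(-20.0)


class TestConditionalCurve:
    def test_point_mass_zero_slopes_gives_flat_curve_at_intercept(self):
        design = make_design()
        draws = make_draws(include_age=False, alpha=0.5, b_dist=0.0)
        c = conditional_curve(draws, design, "pasture")
        want = np.exp(0.5 * 0.3 + 4.0) - 1.0
        np.testing.assert_allclose(c.mean, want, rtol=1e-12)
        np.testing.assert_allclose(c.lo95, c.hi95, rtol=1e-12)

    def test_positive_distance_slopes_give_strictly_increasing_curve(self):
        design = make_design()
        draws = make_draws(include_age=False, alpha=0.0, b_dist=0.4, jitter=0.03, seed=2)
        assert (draws.column("b_dist[cropland]") > 0).all()
        c = conditional_curve(draws, design, "cropland")
        assert (np.diff(c.mean) > 0).all()

    def test_age_request_mismatch_raises(self):
        design = make_design()
        no_age = make_draws(include_age=False)
        with_age = make_draws(include_age=True)
        with pytest.raises(ValueError, match="include_age=False"):
            conditional_curve(no_age, design, "cropland", age=10.0)
        with pytest.raises(ValueError, match="marginal curve"):
            conditional_curve(with_age, design, "cropland", age=None)

    def test_band_encloses_truth_for_model_matched_fit(self, small_landscape):
        """The 95% band of a fitted curve covers the true generative curve at
        most grid distances."""
        land, plots = small_landscape
        pts = sample_points(land, plots, n=400, max_distance=800.0,
                            boundary_buffer=1000.0, seed=21)
        tp = land.meta["generative_transform"]["agb"]
        design = standardize(pts, "agb", frozen_transform=tp)
        est = EdgeEffectsRegressor(include_age=False, iterations=1000, warmup=300,
                                   seed=22).fit(design)
        grid = default_grid(step=10.0, max_distance=800.0)
        c = conditional_curve(est.draws_, design, "cropland", grid=grid)
        gp = land.meta["generative_params"]["agb"]
        zd = tp.standardize_predictor("distance", grid)
        # marginal truth: distance-only part of the generative predictor at
        # mean age/covariates (standardized 0)
        eta = gp.intercept["cropland"] + gp.b_dist["cropland"] * zd
        truth = tp.inverse_response(eta)
        frac = np.mean((c.lo95 <= truth) & (truth <= c.hi95))
        assert frac >= 0.9


class TestAgeSurface:
    def test_zero_age_terms_reduce_to_marginal_curve(self):
        design = make_design()
        kw = dict(alpha=0.2, b_dist=0.35, seed=5)
        aged = make_draws(include_age=True, b_age=0.0, b_distage=0.0, **kw)
        marginal = make_draws(include_age=False, **kw)
        (c0, m0), = age_surface(aged, design, "pasture", ages=[0.0])
        cm = conditional_curve(marginal, design, "pasture")
        np.testing.assert_allclose(c0.mean, cm.mean, rtol=1e-12)
        assert m0.penetration_depth_m == curve_metrics(cm).penetration_depth_m

    def test_interaction_sign_sets_trend_direction(self):
        """Positive distance-age interaction (effect deepening with age)
        raises magnitude with age; flipping the sign flips the trend."""
        design = make_design()
        for sign in (+1.0, -1.0):
            draws = make_draws(
                include_age=True, alpha=0.0, b_dist=0.3,
                b_age=-0.1 * sign, b_distage=0.08 * sign,
            )
            out = age_surface(draws, design, "cropland", ages=[2.0, 40.0])
            mags = [m.magnitude_pct for _, m in out]
            if sign > 0:
                assert mags[1] > mags[0]
            else:
                assert mags[1] < mags[0]

    def test_requires_age_fit(self):
        with pytest.raises(ValueError, match="include_age"):
            age_surface(make_draws(include_age=False), make_design(), "cropland", ages=[1.0])

    def test_fitted_surface_recovers_deepening_trend(self):
        """Data generated with a deepening interaction: fitted penetration
        depth is non-decreasing in age in a majority of seeded replicates."""
        wins = 0
        for s in range(3):
            cfg = LandscapeConfig(
                n_rows=160, n_cols=160, cell_size=50.0, n_plots=14,
                plot_side_range=(300.0, 800.0), placement_margin=1500.0,
                n_homesteads=10, n_roads=3,
            )
            land, plots = generate_landscape(cfg, seed=500 + s)
            params = GenerativeParams(
                intercept=dict.fromkeys(LAND_USES, 0.0),
                b_dist=dict.fromkeys(LAND_USES, 0.3),
                b_age=dict.fromkeys(LAND_USES, -0.12),
                b_int=dict.fromkeys(LAND_USES, 0.06),
                noise_sd=0.4,
            )
            simulate_structure(land, plots, params, seed=600 + s)
            pts = sample_points(land, plots, n=1000, max_distance=1200.0,
                                boundary_buffer=1200.0, seed=700 + s)
            design = standardize(pts, "agb")
            est = EdgeEffectsRegressor(include_age=True, iterations=1000, warmup=300,
                                       seed=800 + s).fit(design)
            grid = default_grid(step=2.0, max_distance=1200.0)
            out = age_surface(est.draws_, design, "pasture", ages=[5.0, 40.0], grid=grid)
            depths = [m.penetration_depth_m for _, m in out]
            wins += depths[1] >= depths[0]
        assert wins >= 2
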