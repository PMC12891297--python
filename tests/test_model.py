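"""Multilevel model: density oracles, diagnostics, pooling, posterior checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime
from scipy.stats import norm

from chacoedge import (
    EdgeEffectsRegressor,
    EdgeModelSpec,
    build_model,
    posterior_predictive_check,
    standardize,
)
from chacoedge.constants import COVARIATE_TERMS, LAND_USES
from chacoedge.model import effective_sample_size, rhat
from chacoedge.standardize import StandardizedDesign

from .helpers import joint_logp_oracle, make_design, make_draws, make_transform


def _toy_design(n=60, seed=0, sd_noise=0.4, slopes=None) -> StandardizedDesign:
    rng = np.random.default_rng(seed)
    z_dist = rng.standard_normal(n)
    z_age = rng.standard_normal(n)
    x_fixed = rng.standard_normal((n, len(COVARIATE_TERMS)))
    lc = rng.integers(0, 3, n)
    slopes = slopes or {}
    y = (
        np.array(slopes.get("alpha", [0.0] * 3))[lc]
        + np.array(slopes.get("b_dist", [0.0] * 3))[lc] * z_dist
        + sd_noise * rng.standard_normal(n)
    )
    return StandardizedDesign(
        y=y, z_dist=z_dist, z_age=z_age, x_fixed=x_fixed, lc_idx=lc, transform=make_transform()
    )


class TestDensity:
    def test_null_parameters_give_standard_normal_loglik(self):
        design = _toy_design()
        den = build_model(design, EdgeModelSpec(include_age=False))
        theta = np.zeros(den.dim)  # all coefficients 0, sigma = e^0 = 1
        want = norm.logpdf(design.y).sum()
        assert den.log_likelihood(theta) == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize(
        "include_age,n_named", [(False, 16), (True, 26)]
    )
    def test_parameter_vector_structure(self, include_age, n_named, agb_design):
        """Distance-only model: 3 intercepts + 3 distance slopes + 5 fixed
        slopes + sigma + 4 hyperparameters = 16 named parameters."""
        den = build_model(agb_design, EdgeModelSpec(include_age=include_age))
        est = EdgeEffectsRegressor(
            include_age=include_age, iterations=60, warmup=30, seed=0
        ).fit(agb_design)
        assert len(est.draws_.names) == n_named
        n_varying = 2 + (2 if include_age else 0)
        assert den.dim == 5 * n_varying + len(COVARIATE_TERMS) + 1

    @pytest.mark.parametrize("include_age", [False, True])
    def test_logp_matches_bruteforce_oracle(self, include_age):
        design = _toy_design(n=40, seed=3)
        den = build_model(design, EdgeModelSpec(include_age=include_age))
        rng = np.random.default_rng(11)
        for _ in range(10):
            theta = rng.normal(0.0, 0.7, den.dim)
            want = joint_logp_oracle(design, include_age, theta)
            assert den.logp(theta) == pytest.approx(want, abs=1e-8)

    @pytest.mark.parametrize("include_age", [False, True])
    def test_gradients_match_finite_differences(self, include_age):
        design = _toy_design(n=50, seed=4)
        den = build_model(design, EdgeModelSpec(include_age=include_age))
        rng = np.random.default_rng(5)
        theta = rng.normal(0.0, 0.5, den.dim)
        _, g = den.logp_grad(theta)
        gn = approx_fprime(theta, den.logp, 1e-6)
        np.testing.assert_allclose(g, gn, atol=1e-3)
        phi = rng.normal(0.0, 0.5, den.marginal_dim)
        _, gm = den.marginal_logp_grad(phi)
        gmn = approx_fprime(phi, lambda p: den.marginal_logp_grad(p)[0], 1e-6)
        np.testing.assert_allclose(gm, gmn, atol=1e-3)

    def test_missing_group_level_raises(self):
        design = _toy_design(n=40)
        design.lc_idx[:] = 0  # only cropland present
        with pytest.raises(ValueError, match="silvopasture"):
            build_model(design, EdgeModelSpec())


class TestFit:
    def test_default_settings_retain_3000_draws(self, fast_fit):
        # fixture uses reduced iterations; default settings checked arithmetically
        assert EdgeModelSpec().n_draws == 2 * (2000 - 500)
        assert fast_fit.draws_.n_draws == 2 * (600 - 200)

    def test_collapsed_and_joint_samplers_agree(self):
        """Dual-route check: the analytically collapsed sampler and plain
        joint NUTS target the same posterior."""
        design = _toy_design(
            n=300, seed=6, slopes={"alpha": [0.4, 0.0, -0.4], "b_dist": [0.5, 0.3, 0.1]}
        )
        a = EdgeEffectsRegressor(
            include_age=False, iterations=1500, warmup=500, sampler="collapsed", seed=1
        ).fit(design)
        b = EdgeEffectsRegressor(
            include_age=False, iterations=1500, warmup=500, sampler="joint",
            target_accept=0.95, seed=2,
        ).fit(design)
        for nm in ("alpha[cropland]", "b_dist[pasture]", "beta_temp", "sigma"):
            assert a.draws_.mean(nm) == pytest.approx(b.draws_.mean(nm), abs=0.05)

    def test_partial_pooling_shrinks_group_intercepts(self):
        """Each group intercept lies between its no-pooling least-squares
        value and the complete-pooling global value, on unbalanced groups."""
        rng = np.random.default_rng(8)
        n_per = [160, 40, 8]
        lc = np.repeat([0, 1, 2], n_per)
        n = lc.size
        truth = np.array([0.8, -0.2, -1.2])
        y = truth[lc] + 0.5 * rng.standard_normal(n)
        design = StandardizedDesign(
            y=y,
            z_dist=np.zeros(n) + 1e-8 * rng.standard_normal(n),
            z_age=np.zeros(n),
            x_fixed=1e-8 * rng.standard_normal((n, len(COVARIATE_TERMS))),
            lc_idx=lc,
            transform=make_transform(),
        )
        est = EdgeEffectsRegressor(include_age=False, iterations=1500, warmup=500, seed=3).fit(
            design
        )
        pooled = y.mean()
        for k, lu in enumerate(LAND_USES):
            no_pool = y[lc == k].mean()
            post = est.draws_.mean(f"alpha[{lu}]")
            lo, hi = sorted([no_pool, pooled])
            assert lo - 0.05 <= post <= hi + 0.05
        # shrinkage is strongest for the smallest group
        gap = [
            abs(est.draws_.mean(f"alpha[{lu}]") - y[lc == k].mean())
            for k, lu in enumerate(LAND_USES)
        ]
        assert gap[2] > gap[0]

    def test_row_permutation_leaves_posterior_means_stable(self, small_points):
        base = standardize(small_points, "agb")
        perm = np.random.default_rng(9).permutation(len(small_points))
        shuffled = standardize(small_points.iloc[perm].reset_index(drop=True), "agb")
        a = EdgeEffectsRegressor(include_age=False, iterations=800, warmup=300, seed=4).fit(base)
        b = EdgeEffectsRegressor(include_age=False, iterations=800, warmup=300, seed=4).fit(
            shuffled
        )
        for nm in ("b_dist[cropland]", "b_dist[pasture]", "sigma"):
            assert a.draws_.mean(nm) == pytest.approx(b.draws_.mean(nm), abs=0.03)


class TestRhat:
    def test_well_mixed_chains_near_one(self, rng):
        chains = rng.standard_normal((2, 2000))
        assert 0.99 <= rhat(chains) <= 1.02

    def test_separated_chains_flag_nonconvergence(self, rng):
        chains = np.stack([rng.standard_normal(500) - 5.0, rng.standard_normal(500) + 5.0])
        assert rhat(chains) > 1.1

    def test_invariant_under_monotone_rescaling(self, rng):
        chains = rng.standard_normal((2, 800)) * 0.3
        assert rhat(np.exp(chains)) == pytest.approx(rhat(chains), abs=1e-10)

    def test_single_chain_raises(self, rng):
        with pytest.raises(ValueError, match="2 chains"):
            rhat(rng.standard_normal((1, 100)))
        with pytest.raises(ValueError, match="2 chains"):
            effective_sample_size(rng.standard_normal((1, 100)))

    def test_fit_attaches_rhat_for_every_parameter(self, fast_fit):
        assert set(fast_fit.rhat_) == set(fast_fit.draws_.names)
        assert np.isfinite(list(fast_fit.rhat_.values())).all()


class TestPosteriorPredictive:
    def test_zero_sigma_replicates_equal_mu(self):
        design = _toy_design(n=30, seed=10)
        draws = make_draws(include_age=False, sigma=1e-12, alpha=0.3, b_dist=0.5)
        ppc = posterior_predictive_check(draws, design, n_rep=5, seed=0)
        mu = 0.3 + 0.5 * design.z_dist
        for rep in ppc.replicates:
            np.testing.assert_allclose(rep, mu, atol=1e-9)

    def test_zero_reps_flagged_unavailable(self):
        design = _toy_design(n=10)
        draws = make_draws(include_age=False)
        ppc = posterior_predictive_check(draws, design, n_rep=0)
        assert ppc.replicates.shape == (0, 10)
        assert ppc.summary() == {"available": False}

    def test_observed_mean_within_central_95_when_model_true(self, agb_design, fast_fit):
        ppc = posterior_predictive_check(fast_fit.draws_, agb_design, n_rep=300, seed=1)
        s = ppc.summary()
        assert s["available"]
        assert s["observed_within_95"]


class TestLongFormat:
    def test_round_trip_through_long_dataframe(self, fast_fit, tmp_path):
        from chacoedge.pipeline import load_draws, save_draws

        save_draws(fast_fit.draws_, tmp_path / "d.csv", tmp_path / "d.json")
        back = load_draws(tmp_path / "d.csv", tmp_path / "d.json")
        assert back.names == fast_fit.draws_.names
        np.testing.assert_allclose(back.array, fast_fit.draws_.array, rtol=1e-9)
        assert back.include_age == fast_fit.draws_.include_age
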