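"""Independent oracles and builders used across the test suite.

Everything here is deliberately written without reusing the package's
vectorized implementations: explicit loops, scipy densities, and direct
formula transcriptions, so that agreement is a genuine two-route check.
"""

import numpy as np
from scipy.stats import norm
from scipy.stats import t as tdist

from chacoedge.constants import COVARIATE_TERMS, LAND_USES
from chacoedge.model import PosteriorDraws
from chacoedge.standardize import StandardizedDesign, TransformParams


def joint_logp_oracle(design: StandardizedDesign, include_age: bool, theta: np.ndarray) -> float:
    """Brute-force log posterior: scipy densities, per-observation loop."""
    terms = ["alpha", "b_dist"] + (["b_age", "b_distage"] if include_age else [])
    t = len(terms)
    pos = 0
    coef = {}
    logp = 0.0
    for term in terms:
        mu_t = theta[pos]
        lsd = theta[pos + 1]
        z = theta[pos + 2 : pos + 5]
        sd = np.exp(lsd)
        coef[term] = [mu_t + sd * z[k] for k in range(3)]
        logp += norm.logpdf(mu_t)
        logp += sum(norm.logpdf(zk) for zk in z)
        logp += np.log(2.0) + tdist.logpdf(sd, df=3) + lsd
        pos += 5
    beta = theta[pos : pos + len(COVARIATE_TERMS)]
    for b in beta:
        logp += norm.logpdf(b)
    ls = theta[-1]
    sigma = np.exp(ls)
    logp += np.log(2.0) + tdist.logpdf(sigma, df=3) + ls

    for i in range(design.n):
        g = design.lc_idx[i]
        m = coef["alpha"][g] + coef["b_dist"][g] * design.z_dist[i]
        if include_age:
            m += coef["b_age"][g] * design.z_age[i]
            m += coef["b_distage"][g] * design.z_dist[i] * design.z_age[i]
        for j, _ in enumerate(COVARIATE_TERMS):
            m += beta[j] * design.x_fixed[i, j]
        logp += norm.logpdf(design.y[i], loc=m, scale=sigma)
    return float(logp)


def penetration_depth_bruteforce(grid, mean, fraction=0.9) -> float:
    """Literal scan of the definition, one grid point at a time."""
    ref = mean[-1]
    assert ref > 0
    if mean[0] >= fraction * ref:
        return 0.0
    d_star = None
    for i in range(len(grid)):
        if mean[i] < fraction * ref:
            if all(mean[j] < fraction * ref for j in range(i + 1)):
                d_star = grid[i]
        else:
            break
    step = grid[1] - grid[0]
    return float(d_star + step)


def dist_time_bruteforce(point, plots, year_range) -> float:
    """Per-year loop over all point-plot distances (shapely, no vectorization)."""
    import shapely

    p = shapely.Point(point)
    first = min(pl.year_cleared for pl in plots if pl.year_cleared <= year_range[1])
    first = max(first, year_range[0])
    total = 0.0
    for year in range(first, year_range[1] + 1):
        ds = [p.distance(pl.polygon) for pl in plots if pl.year_cleared <= year]
        total += min(ds)
    return total


def make_transform(
    variable="agb", response_mean=4.0, response_sd=0.3, dist_mean=5.5, dist_sd=1.3,
    age_mean=2.5, age_sd=0.8,
) -> TransformParams:
    means = {"distance": dist_mean, "age": age_mean}
    sds = {"distance": dist_sd, "age": age_sd}
    for t in COVARIATE_TERMS:
        means[t] = 0.0
        sds[t] = 1.0
    return TransformParams(
        variable=variable,
        response_mean=response_mean,
        response_sd=response_sd,
        response_offset=1.0,
        predictor_means=means,
        predictor_sds=sds,
    )


def make_design(transform=None, n=4) -> StandardizedDesign:
    """Minimal design carrying a transform (for curve evaluation)."""
    if transform is None:
        transform = make_transform()
    return StandardizedDesign(
        y=np.zeros(n),
        z_dist=np.zeros(n),
        z_age=np.zeros(n),
        x_fixed=np.zeros((n, len(COVARIATE_TERMS))),
        lc_idx=np.arange(n) % 3,
        transform=transform,
    )


def make_draws(include_age=False, n_draws=400, seed=0, jitter=0.0, **values) -> PosteriorDraws:
    """Hand-built posterior: constant (or jittered) values per parameter.

    ``values`` maps parameter names (``alpha``, ``b_dist``, ... applied to all
    land uses, or exact names like ``b_dist[cropland]``) to scalars.
    """
    terms = ["alpha", "b_dist"] + (["b_age", "b_distage"] if include_age else [])
    names = []
    for term in terms:
        names += [f"{term}[{lu}]" for lu in LAND_USES] + [f"mu_{term}", f"sd_{term}"]
    names += [f"beta_{t}" for t in COVARIATE_TERMS] + ["sigma"]
    rng = np.random.default_rng(seed)
    arr = np.zeros((2, n_draws // 2, len(names)))
    for j, nm in enumerate(names):
        base = nm.split("[")[0]
        val = values.get(nm, values.get(base, 1.0 if nm.startswith("sd") or nm == "sigma" else 0.0))
        arr[:, :, j] = val + (jitter * rng.standard_normal(arr.shape[:2]) if jitter else 0.0)
    return PosteriorDraws(
        names=names,
        array=arr,
        rhat={},
        ess={},
        seed=seed,
        spec_hash="synthetic",
        include_age=include_age,
    )
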