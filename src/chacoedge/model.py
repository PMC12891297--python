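"""Bayesian multilevel edge-effect model.

The model regresses standardized log forest structure on log distance to the
nearest deforestation plot, log edge age, and their interaction — all four
terms varying by post-deforestation land use with partial pooling — plus five
fixed control slopes (temperature, precipitation, the deforestation-legacy
statistic, distance to homesteads, distance to roads):

    FS_i ~ Normal(mu_i, sigma)
    mu_i = alpha_{LC[i]} + b_dist_{LC[i]} d_i + b_age_{LC[i]} a_i
           + b_distage_{LC[i]} d_i a_i + X_fixed beta
    alpha_k ~ Normal(mu_alpha, sd_alpha)          (and likewise per term)
    mu_* ~ Normal(0, 1);  sd_*, sigma ~ half-Student-t(3, 0, 1)

Group-level terms are modeled as independent (three levels cannot inform a
correlation structure).  Because the likelihood is Gaussian-linear, the sum
of squares is precomputed as Gram matrices, making each log-posterior or
gradient evaluation O(p^2)-O(p^3) regardless of sample size.

Sampling uses a collapsed scheme by default: the regression coefficients
(group effects and fixed slopes) are Gaussian given the hyperparameters, so
they are integrated out analytically and NUTS explores only the
hyperparameter space (group means and sds, residual sd) — geometry without
the funnel that frustrates joint sampling of few-group hierarchies.  Each
retained hyperparameter draw is then completed with an exact draw of the
coefficients from their conjugate Gaussian conditional.  A joint
(non-centered) NUTS path is kept as a cross-check.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import arviz as az
import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import COVARIATE_TERMS, LAND_USES
from .nuts import ChainDiagnostics, sample_chain
from .standardize import StandardizedDesign

#: Normalizing constant of the half-Student-t(df=3, scale=1) density.
_HALF_T3_CONST = float(np.log(2.0) + gammaln(2.0) - gammaln(1.5) - 0.5 * np.log(3.0 * np.pi))
_LOG_2PI = float(np.log(2.0 * np.pi))


def _half_t3_logpdf(x):
    return _HALF_T3_CONST - 2.0 * np.log1p(x * x / 3.0)


def _half_t3_dlogpdf(x):
    return -4.0 * x / (3.0 + x * x)


@dataclass
class EdgeModelSpec:
    """Model structure and MCMC settings.

    ``include_age=False`` drops the age main effect and the distance-age
    interaction (the snapshot model); ``True`` keeps all four varying terms.
    Default MCMC settings retain 2 chains x (2000 - 500) = 3000 draws.
    """

    include_age: bool = True
    chains: int = 2
    iterations: int = 2000
    warmup: int = 500
    target_accept: float = 0.9
    max_treedepth: int = 10
    sampler: str = "collapsed"  # or "joint"
    seed: int = 0

    @property
    def varying_terms(self) -> tuple[str, ...]:
        if self.include_age:
            return ("alpha", "b_dist", "b_age", "b_distage")
        return ("alpha", "b_dist")

    @property
    def n_draws(self) -> int:
        return self.chains * (self.iterations - self.warmup)

    def validate(self):
        if self.chains < 1 or self.iterations <= self.warmup or self.warmup < 1:
            raise ValueError("need chains >= 1 and iterations > warmup >= 1")
        if self.sampler not in ("collapsed", "joint"):
            raise ValueError(f"unknown sampler {self.sampler!r}")
        return self

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def design_matrix(design: StandardizedDesign, include_age: bool) -> tuple[np.ndarray, list[str]]:
    """Expanded design matrix: per-land-use one-hot blocks per varying term,
    then the fixed covariate columns.  Column names match the derived
    parameter names of the posterior."""
    onehot = np.zeros((design.n, len(LAND_USES)))
    onehot[np.arange(design.n), design.lc_idx] = 1.0
    blocks = [onehot, onehot * design.z_dist[:, None]]
    names = [f"alpha[{lu}]" for lu in LAND_USES] + [f"b_dist[{lu}]" for lu in LAND_USES]
    if include_age:
        blocks += [onehot * design.z_age[:, None], onehot * (design.z_dist * design.z_age)[:, None]]
        names += [f"b_age[{lu}]" for lu in LAND_USES]
        names += [f"b_distage[{lu}]" for lu in LAND_USES]
    blocks.append(design.x_fixed)
    names += [f"beta_{t}" for t in COVARIATE_TERMS]
    return np.hstack(blocks), names


class EdgeModelDensity:
    """Evaluable log posterior (and gradient) on the unconstrained scale.

    Unconstrained layout: per varying term ``[mu, log_sd, z_0, z_1, z_2]``
    with non-centered group coefficients ``c_k = mu + exp(log_sd) * z_k``,
    then the 5 fixed slopes, then ``log_sigma``.
    """

    def __init__(self, design: StandardizedDesign, spec: EdgeModelSpec):
        spec.validate()
        counts = np.bincount(design.lc_idx, minlength=len(LAND_USES))
        missing = [LAND_USES[i] for i in range(len(LAND_USES)) if counts[i] < 2]
        if missing:
            raise ValueError(f"need >= 2 observations per land use; short levels: {missing}")
        self.design = design
        self.spec = spec
        self.terms = spec.varying_terms
        self.n_lc = len(LAND_USES)
        self.A, self.coef_names = design_matrix(design, spec.include_age)
        y = design.y
        self.n = y.size
        self.AtA = self.A.T @ self.A
        self.Aty = self.A.T @ y
        self.yty = float(y @ y)
        self.n_coef = self.A.shape[1]
        self.dim = 5 * len(self.terms) + len(COVARIATE_TERMS) + 1

    # ---- parameter packing -------------------------------------------------
    def unpack(self, theta: np.ndarray) -> dict:
        t = len(self.terms)
        out: dict = {}
        for i, term in enumerate(self.terms):
            base = 5 * i
            out[f"mu_{term}"] = theta[base]
            out[f"log_sd_{term}"] = theta[base + 1]
            out[f"z_{term}"] = theta[base + 2 : base + 5]
        out["beta"] = theta[5 * t : 5 * t + len(COVARIATE_TERMS)]
        out["log_sigma"] = theta[-1]
        return out

    def coefficients(self, theta: np.ndarray) -> np.ndarray:
        """Derived regression coefficients in design-matrix column order."""
        p = self.unpack(theta)
        parts = [
            p[f"mu_{term}"] + np.exp(p[f"log_sd_{term}"]) * p[f"z_{term}"]
            for term in self.terms
        ]
        parts.append(p["beta"])
        return np.concatenate(parts)

    # ---- density -----------------------------------------------------------
    def log_likelihood(self, theta: np.ndarray) -> float:
        c = self.coefficients(theta)
        ssr = self.yty - 2.0 * c @ self.Aty + c @ (self.AtA @ c)
        ls = theta[-1]
        return float(-0.5 * self.n * _LOG_2PI - self.n * ls - 0.5 * ssr * np.exp(-2.0 * ls))

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        t = len(self.terms)
        nb = len(COVARIATE_TERMS)
        c = self.coefficients(theta)
        ls = theta[-1]
        sigma = np.exp(ls)
        AtAc = self.AtA @ c
        ssr = self.yty - 2.0 * c @ self.Aty + c @ AtAc
        inv_s2 = np.exp(-2.0 * ls)
        logp = -0.5 * self.n * _LOG_2PI - self.n * ls - 0.5 * ssr * inv_s2
        dc = (self.Aty - AtAc) * inv_s2  # d loglik / d coefficients

        grad = np.empty(self.dim)
        for i, term in enumerate(self.terms):
            base = 5 * i
            mu = theta[base]
            lsd = theta[base + 1]
            z = theta[base + 2 : base + 5]
            sd = np.exp(lsd)
            dct = dc[3 * i : 3 * i + 3]
            logp += -0.5 * (_LOG_2PI + mu * mu)  # hypermean prior
            logp += float(np.sum(-0.5 * (_LOG_2PI + z * z)))
            logp += _half_t3_logpdf(sd) + lsd  # + log-Jacobian
            grad[base] = float(np.sum(dct)) - mu
            grad[base + 1] = sd * float(dct @ z) + _half_t3_dlogpdf(sd) * sd + 1.0
            grad[base + 2 : base + 5] = dct * sd - z
        beta = theta[5 * t : 5 * t + nb]
        logp += float(np.sum(-0.5 * (_LOG_2PI + beta * beta)))
        grad[5 * t : 5 * t + nb] = dc[3 * t : 3 * t + nb] - beta
        logp += _half_t3_logpdf(sigma) + ls
        grad[-1] = (-self.n + ssr * inv_s2) + _half_t3_dlogpdf(sigma) * sigma + 1.0
        return float(logp), grad

    def mu(self, theta: np.ndarray) -> np.ndarray:
        """Linear predictor per observation (standardized scale)."""
        return self.A @ self.coefficients(theta)

    # ---- collapsed (location-marginalized) density --------------------------
    #
    # Every location parameter is Gaussian-linear: writing the group
    # coefficients as c = M mu + dev with dev ~ N(0, Lambda) and stacking
    # gamma = [dev; beta; mu] ~ N(0, diag(sd^2 blocks, 1, 1)), the response is
    # y = A_ext gamma + eps with A_ext = [A, A M].  Marginalizing gamma gives
    # y ~ N(0, sigma^2 I + A_ext Lambda_ext A_ext^T), so NUTS only explores
    # the scale parameters phi = [log_sd per term, log_sigma] (no
    # location-scale funnels), and gamma is recovered per retained draw from
    # its conjugate Gaussian conditional.

    @property
    def marginal_dim(self) -> int:
        return len(self.terms) + 1

    def _extended_gram(self):
        if not hasattr(self, "_ext"):
            t = len(self.terms)
            nv = 3 * t
            M = np.zeros((self.n_coef, t))
            M[np.arange(nv), np.repeat(np.arange(t), 3)] = 1.0
            AtAM = self.AtA @ M
            ext_AtA = np.block([[self.AtA, AtAM], [AtAM.T, M.T @ AtAM]])
            ext_Aty = np.concatenate([self.Aty, M.T @ self.Aty])
            self._ext = (M, ext_AtA, ext_Aty)
        return self._ext

    def _lambda_ext(self, phi: np.ndarray) -> np.ndarray:
        t = len(self.terms)
        lam = np.ones(self.n_coef + t)
        lam[: 3 * t] = np.exp(2.0 * phi[:t])[np.repeat(np.arange(t), 3)]
        return lam

    def marginal_logp_grad(self, phi: np.ndarray) -> tuple[float, np.ndarray]:
        from scipy.linalg import cho_factor, cho_solve

        t = len(self.terms)
        nv = 3 * t
        if np.any(np.abs(phi) > 40.0):  # overflow guard for warmup excursions
            return -np.inf, np.zeros(self.marginal_dim)
        _, ext_AtA, ext_Aty = self._extended_gram()
        pext = ext_AtA.shape[0]
        lam = self._lambda_ext(phi)
        ls = phi[-1]
        s2 = np.exp(2.0 * ls)

        B = ext_AtA + s2 * np.diag(1.0 / lam)
        if not np.all(np.isfinite(B)):
            return -np.inf, np.zeros(self.marginal_dim)
        try:
            cf = cho_factor(B, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros(self.marginal_dim)
        u = cho_solve(cf, ext_Aty)
        quad = (self.yty - ext_Aty @ u) / s2  # y^T Sigma^-1 y
        logdet_b = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        logdet_sigma = (self.n - pext) * np.log(s2) + logdet_b + float(np.sum(np.log(lam)))
        logp = -0.5 * self.n * _LOG_2PI - 0.5 * logdet_sigma - 0.5 * quad

        v = (ext_Aty - ext_AtA @ u) / s2  # A_ext^T Sigma^-1 y
        binv_diag = np.diag(cho_solve(cf, np.eye(pext)))
        # d logp / d lambda_j for the sd-governed entries
        dlam = -0.5 / lam + 0.5 * s2 * binv_diag / lam**2 + 0.5 * v * v

        grad = np.empty(self.marginal_dim)
        for i in range(t):
            sd = np.exp(phi[i])
            sl = slice(3 * i, 3 * i + 3)
            logp += _half_t3_logpdf(sd) + phi[i]
            grad[i] = 2.0 * float(np.sum(dlam[sl] * lam[sl])) + _half_t3_dlogpdf(sd) * sd + 1.0
        sigma = np.exp(ls)
        sig_inv_y_sq = (self.yty - 2.0 * ext_Aty @ u + u @ (ext_AtA @ u)) / s2**2
        ds2 = (
            -0.5 * (self.n - pext) / s2
            - 0.5 * float(np.sum(binv_diag / lam))
            + 0.5 * sig_inv_y_sq
        )
        logp += _half_t3_logpdf(sigma) + ls
        grad[-1] = ds2 * 2.0 * s2 + _half_t3_dlogpdf(sigma) * sigma + 1.0
        return float(logp), grad

    def draw_coefficients(self, phi: np.ndarray, rng: np.random.Generator):
        """Exact draw of (coefficients, group means) | y, scales.

        Returns ``(c, mus)`` where ``c`` follows the design-matrix column
        order (group coefficients then fixed slopes).
        """
        M, ext_AtA, ext_Aty = self._extended_gram()
        lam = self._lambda_ext(phi)
        s2 = np.exp(2.0 * phi[-1])
        prec = ext_AtA / s2 + np.diag(1.0 / lam)
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, ext_Aty / s2)
        gamma = mean + np.linalg.solve(L.T, rng.standard_normal(lam.size))
        dev_beta, mus = gamma[: self.n_coef], gamma[self.n_coef :]
        c = dev_beta + M @ mus
        return c, mus


def build_model(design: StandardizedDesign, spec: EdgeModelSpec) -> EdgeModelDensity:
    """Construct the evaluable model density for a standardized design."""
    return EdgeModelDensity(design, spec)


# ---- posterior container and diagnostics ------------------------------------


@dataclass
class PosteriorDraws:
    """Posterior draws on the derived (constrained) scale.

    ``array`` has shape (chains, draws_per_chain, n_params); ``names`` gives
    stable parameter names (e.g. ``b_dist[cropland]``, ``sd_alpha``,
    ``beta_temp``, ``sigma``).
    """

    names: list[str]
    array: np.ndarray
    rhat: dict[str, float]
    ess: dict[str, float]
    seed: int
    spec_hash: str
    include_age: bool
    n_divergent: int = 0
    chain_diagnostics: list[ChainDiagnostics] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_draws(self) -> int:
        return self.array.shape[0] * self.array.shape[1]

    @property
    def flat(self) -> np.ndarray:
        return self.array.reshape(-1, self.array.shape[2])

    def column(self, name: str) -> np.ndarray:
        return self.flat[:, self.names.index(name)]

    def mean(self, name: str) -> float:
        return float(self.column(name).mean())

    def ci(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        a = 100.0 * (1.0 - prob) / 2.0
        lo, hi = np.percentile(self.column(name), [a, 100.0 - a])
        return float(lo), float(hi)

    @property
    def converged(self) -> bool:
        return all(v < 1.01 for v in self.rhat.values())

    def to_long_dataframe(self):
        import pandas as pd

        chains, draws, _ = self.array.shape
        rows = []
        for j, name in enumerate(self.names):
            for ch in range(chains):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": ch,
                            "iteration": np.arange(draws),
                            "parameter": name,
                            "value": self.array[ch, :, j],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def diagnostics_dict(self) -> dict:
        return {
            "rhat": {k: float(v) for k, v in self.rhat.items()},
            "ess": {k: float(v) for k, v in self.ess.items()},
            "seed": int(self.seed),
            "spec_hash": self.spec_hash,
            "include_age": bool(self.include_age),
            "n_divergent": int(self.n_divergent),
            "converged": bool(self.converged),
        }


def rhat(array: np.ndarray) -> float:
    """Rank-normalized split-R-hat for one parameter, shape (chains, draws)."""
    array = np.asarray(array, dtype=float)
    if array.ndim != 2 or array.shape[0] < 2:
        raise ValueError("R-hat requires at least 2 chains, got shape %s" % (array.shape,))
    return float(az.rhat(az.convert_to_dataset(array))["x"].values)


def effective_sample_size(array: np.ndarray) -> float:
    array = np.asarray(array, dtype=float)
    if array.ndim != 2 or array.shape[0] < 2:
        raise ValueError("ESS requires at least 2 chains")
    return float(az.ess(az.convert_to_dataset(array))["x"].values)


def convergence_summary(draws: PosteriorDraws, threshold: float = 1.01):
    """(flag, offending parameters) under the R-hat < threshold rule."""
    bad = {k: v for k, v in draws.rhat.items() if not v < threshold}
    return (len(bad) == 0), bad


# ---- estimator ---------------------------------------------------------------


class EdgeEffectsRegressor(BaseEstimator, RegressorMixin):
    """Multilevel Bayesian regression of forest structure on edge distance.

    scikit-learn-style estimator: configure in ``__init__``, call
    :meth:`fit` with a :class:`~chacoedge.standardize.StandardizedDesign`,
    then read fitted attributes (``draws_``, ``rhat_``, ``ess_``,
    ``converged_``).  ``predict`` returns the posterior-mean linear predictor
    on the standardized scale.
    """

    def __init__(
        self,
        include_age: bool = True,
        chains: int = 2,
        iterations: int = 2000,
        warmup: int = 500,
        target_accept: float = 0.9,
        max_treedepth: int = 10,
        sampler: str = "collapsed",
        seed: int = 0,
    ):
        self.include_age = include_age
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.target_accept = target_accept
        self.max_treedepth = max_treedepth
        self.sampler = sampler
        self.seed = seed

    def _spec(self) -> EdgeModelSpec:
        return EdgeModelSpec(
            include_age=self.include_age,
            chains=self.chains,
            iterations=self.iterations,
            warmup=self.warmup,
            target_accept=self.target_accept,
            max_treedepth=self.max_treedepth,
            sampler=self.sampler,
            seed=self.seed,
        )

    def fit(self, X: StandardizedDesign, y=None):
        spec = self._spec().validate()
        density = EdgeModelDensity(X, spec)
        n_keep = spec.iterations - spec.warmup
        collapsed = spec.sampler == "collapsed"
        dim = density.marginal_dim if collapsed else density.dim
        logp_grad = density.marginal_logp_grad if collapsed else density.logp_grad
        raw = np.empty((spec.chains, n_keep, dim))
        n_terms = len(density.terms)
        coef = np.empty((spec.chains, n_keep, density.n_coef)) if collapsed else None
        mus = np.empty((spec.chains, n_keep, n_terms)) if collapsed else None
        diags = []
        for ch in range(spec.chains):
            rng = np.random.default_rng([spec.seed, ch])
            theta0 = rng.uniform(-1.0, 1.0, dim)
            draws, diag = sample_chain(
                logp_grad,
                theta0,
                spec.iterations,
                spec.warmup,
                rng,
                target_accept=spec.target_accept,
                max_treedepth=spec.max_treedepth,
            )
            raw[ch] = draws
            diags.append(diag)
            if collapsed:
                for i in range(n_keep):
                    coef[ch, i], mus[ch, i] = density.draw_coefficients(draws[i], rng)

        if not np.all(np.isfinite(raw)):
            raise RuntimeError("sampler produced non-finite draws; model is ill-conditioned")
        n_div = sum(d.n_divergent for d in diags)
        if n_div > 0.2 * spec.chains * n_keep:
            raise RuntimeError(
                f"{n_div} divergent transitions post-warmup "
                f"(step sizes {[d.step_size for d in diags]}); "
                "reparameterize or raise target_accept"
            )

        if collapsed:
            derived, names = self._derive_collapsed(raw, coef, mus, density)
        else:
            derived, names = self._derive(raw, density)
        rhat_d = {nm: rhat(derived[:, :, j]) for j, nm in enumerate(names)} if spec.chains > 1 else {}
        ess_d = (
            {nm: effective_sample_size(derived[:, :, j]) for j, nm in enumerate(names)}
            if spec.chains > 1
            else {}
        )
        self.density_ = density
        self.design_ = X
        self.draws_ = PosteriorDraws(
            names=names,
            array=derived,
            rhat=rhat_d,
            ess=ess_d,
            seed=spec.seed,
            spec_hash=spec.hash(),
            include_age=spec.include_age,
            n_divergent=n_div,
            chain_diagnostics=diags,
        )
        self.rhat_ = rhat_d
        self.ess_ = ess_d
        self.converged_ = all(v < 1.01 for v in rhat_d.values()) if rhat_d else False
        return self

    def _derive(self, raw: np.ndarray, density: EdgeModelDensity):
        """Map unconstrained draws to named, constrained parameters."""
        terms = density.terms
        t = len(terms)
        nb = len(COVARIATE_TERMS)
        names: list[str] = []
        cols: list[np.ndarray] = []
        for i, term in enumerate(terms):
            base = 5 * i
            mu = raw[:, :, base]
            sd = np.exp(raw[:, :, base + 1])
            for k, lu in enumerate(LAND_USES):
                names.append(f"{term}[{lu}]")
                cols.append(mu + sd * raw[:, :, base + 2 + k])
            names += [f"mu_{term}", f"sd_{term}"]
            cols += [mu, sd]
        for j, term in enumerate(COVARIATE_TERMS):
            names.append(f"beta_{term}")
            cols.append(raw[:, :, 5 * t + j])
        names.append("sigma")
        cols.append(np.exp(raw[:, :, -1]))
        return np.stack(cols, axis=2), names

    def _derive_collapsed(
        self, phi: np.ndarray, coef: np.ndarray, mus: np.ndarray, density: EdgeModelDensity
    ):
        """Derived parameters from scale + conjugate location draws."""
        terms = density.terms
        t = len(terms)
        names: list[str] = []
        cols: list[np.ndarray] = []
        for i, term in enumerate(terms):
            for k, lu in enumerate(LAND_USES):
                names.append(f"{term}[{lu}]")
                cols.append(coef[:, :, 3 * i + k])
            names += [f"mu_{term}", f"sd_{term}"]
            cols += [mus[:, :, i], np.exp(phi[:, :, i])]
        for j, term in enumerate(COVARIATE_TERMS):
            names.append(f"beta_{term}")
            cols.append(coef[:, :, 3 * t + j])
        names.append("sigma")
        cols.append(np.exp(phi[:, :, -1]))
        return np.stack(cols, axis=2), names

    def predict(self, X: StandardizedDesign | None = None) -> np.ndarray:
        if not hasattr(self, "draws_"):
            raise RuntimeError("EdgeEffectsRegressor is not fitted")
        density = self.density_ if X is None else EdgeModelDensity(X, self._spec())
        coef_mean = np.array(
            [self.draws_.mean(nm) for nm in density.coef_names]
        )
        return density.A @ coef_mean


def fit(design: StandardizedDesign, spec: EdgeModelSpec) -> PosteriorDraws:
    """Functional wrapper: fit the model under ``spec`` and return the draws."""
    est = EdgeEffectsRegressor(**spec.__dict__)
    return est.fit(design).draws_


# ---- posterior predictive ----------------------------------------------------


@dataclass
class PPCResult:
    replicates: np.ndarray  # (n_rep, n) replicated response vectors
    replicate_means: np.ndarray
    observed_mean: float
    available: bool

    def summary(self) -> dict:
        if not self.available:
            return {"available": False}
        lo, hi = np.percentile(self.replicate_means, [2.5, 97.5])
        return {
            "available": True,
            "observed_mean": float(self.observed_mean),
            "replicated_mean": float(self.replicate_means.mean()),
            "replicated_sd": float(self.replicate_means.std(ddof=1))
            if self.replicate_means.size > 1
            else 0.0,
            "central_95": (float(lo), float(hi)),
            "observed_within_95": bool(lo <= self.observed_mean <= hi),
        }


def posterior_predictive_check(
    draws: PosteriorDraws,
    design: StandardizedDesign,
    n_rep: int = 200,
    seed: int = 0,
) -> PPCResult:
    """Draw ``n_rep`` replicated response vectors from Normal(mu(theta), sigma).

    Each replicate uses one posterior draw (sampled without replacement when
    possible).  ``n_rep == 0`` yields an empty, flagged-unavailable result.
    """
    if n_rep < 0:
        raise ValueError("n_rep must be >= 0")
    observed_mean = float(design.y.mean())
    if n_rep == 0:
        return PPCResult(
            replicates=np.empty((0, design.n)),
            replicate_means=np.empty(0),
            observed_mean=observed_mean,
            available=False,
        )
    A, coef_names = design_matrix(design, draws.include_age)
    rng = np.random.default_rng(seed)
    total = draws.n_draws
    idx = rng.choice(total, size=n_rep, replace=n_rep > total)
    coef_cols = np.column_stack([draws.column(nm) for nm in coef_names])
    sigma = draws.column("sigma")
    reps = np.empty((n_rep, design.n))
    for r, i in enumerate(idx):
        mu = A @ coef_cols[i]
        reps[r] = mu + sigma[i] * rng.standard_normal(design.n)
    return PPCResult(
        replicates=reps,
        replicate_means=reps.mean(axis=1),
        observed_mean=observed_mean,
        available=True,
    )
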