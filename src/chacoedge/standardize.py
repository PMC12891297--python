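"""Design-matrix construction: log transforms and z-scoring with exact inverses.

The model operates entirely on a standardized scale: the response is
``z(log(FS + offset))`` and the predictors are ``z(log(x + 1))`` for distance
and edge age and ``z(x)`` for the control covariates.  :class:`TransformParams`
records every offset, mean and standard deviation so that model output can be
mapped back to natural units (%, t/ha) exactly; the conditional-effect curves
depend on this inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import COVARIATE_TERMS, LAND_USES

#: CSV column holding each structure variable (natural units).
RESPONSE_COLUMNS = {"tree_cover": "fs_tree", "shrub_cover": "fs_shrub", "agb": "fs_agb"}

#: CSV column holding each predictor (natural units).
PREDICTOR_COLUMNS = {
    "distance": "distance_m",
    "age": "age_yr",
    "temp": "temp_c",
    "precip": "precip_mm",
    "dist_time": "dist_time_myr",
    "dist_home": "dist_home_m",
    "dist_roads": "dist_roads_m",
}

#: Predictors entering on the log(x + 1) scale.
LOG_PREDICTORS = ("distance", "age")


@dataclass
class TransformParams:
    """Offsets, means and sds defining the standardization, per response variable."""

    variable: str
    response_mean: float
    response_sd: float
    response_offset: float
    predictor_means: dict[str, float]
    predictor_sds: dict[str, float]
    distance_offset: float = 1.0

    def forward_response(self, fs):
        """Natural units -> standardized log scale."""
        fs = np.asarray(fs, dtype=float)
        return (np.log(fs + self.response_offset) - self.response_mean) / self.response_sd

    def inverse_response(self, z):
        """Standardized log scale -> natural units (exact inverse of forward)."""
        z = np.asarray(z, dtype=float)
        return np.exp(z * self.response_sd + self.response_mean) - self.response_offset

    def standardize_predictor(self, name: str, x):
        x = np.asarray(x, dtype=float)
        if name in LOG_PREDICTORS:
            x = np.log(x + self.distance_offset)
        return (x - self.predictor_means[name]) / self.predictor_sds[name]

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "response_mean": float(self.response_mean),
            "response_sd": float(self.response_sd),
            "response_offset": float(self.response_offset),
            "distance_offset": float(self.distance_offset),
            "predictor_means": {k: float(v) for k, v in self.predictor_means.items()},
            "predictor_sds": {k: float(v) for k, v in self.predictor_sds.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformParams":
        return cls(
            variable=d["variable"],
            response_mean=d["response_mean"],
            response_sd=d["response_sd"],
            response_offset=d["response_offset"],
            predictor_means=dict(d["predictor_means"]),
            predictor_sds=dict(d["predictor_sds"]),
            distance_offset=d.get("distance_offset", 1.0),
        )


@dataclass
class StandardizedDesign:
    """Response and predictors on the standardized scale, plus the transform.

    ``x_fixed`` columns follow :data:`chacoedge.constants.COVARIATE_TERMS`;
    ``lc_idx`` indexes :data:`chacoedge.constants.LAND_USES`.
    """

    y: np.ndarray
    z_dist: np.ndarray
    z_age: np.ndarray
    x_fixed: np.ndarray
    lc_idx: np.ndarray
    transform: TransformParams
    lc_levels: tuple[str, ...] = LAND_USES
    fixed_terms: tuple[str, ...] = COVARIATE_TERMS

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def standardize_distance(self, d):
        return self.transform.standardize_predictor("distance", d)

    def standardize_age(self, a):
        return self.transform.standardize_predictor("age", a)

    def inverse_response(self, z):
        return self.transform.inverse_response(z)


class DesignStandardizer(BaseEstimator, TransformerMixin):
    """Fit/transform estimator mapping a sample-point table to a design.

    Parameters
    ----------
    variable : str
        Response variable, one of ``tree_cover``, ``shrub_cover``, ``agb``.
    log_offset_response : float
        Offset inside the response log; the default ``1.0`` keeps near-zero
        cover finite without a separate hurdle component.
    log_offset_distance : float
        Offset inside the distance/age logs (handles age 0 at the edge).
    frozen_transform : TransformParams, optional
        Use externally supplied transform parameters instead of estimating
        them from the sample (the synthetic generator exposes its own
        transform this way, making parameter recovery exactly well-posed).
    """

    def __init__(
        self,
        variable: str = "tree_cover",
        log_offset_response: float = 1.0,
        log_offset_distance: float = 1.0,
        frozen_transform: TransformParams | None = None,
    ):
        self.variable = variable
        self.log_offset_response = log_offset_response
        self.log_offset_distance = log_offset_distance
        self.frozen_transform = frozen_transform

    def _columns(self, points: pd.DataFrame):
        if self.variable not in RESPONSE_COLUMNS:
            raise ValueError(f"unknown variable {self.variable!r}")
        resp_col = RESPONSE_COLUMNS[self.variable]
        needed = [resp_col, "land_use"] + [PREDICTOR_COLUMNS[p] for p in PREDICTOR_COLUMNS]
        missing = [c for c in needed if c not in points.columns]
        if missing:
            raise ValueError(f"point table is missing columns: {missing}")
        return resp_col

    def fit(self, points: pd.DataFrame, y=None):
        resp_col = self._columns(points)
        if len(points) < 2:
            raise ValueError("need at least 2 points to standardize")
        if self.frozen_transform is not None:
            self.transform_params_ = self.frozen_transform
            return self

        fs = points[resp_col].to_numpy(dtype=float)
        if np.any(fs + self.log_offset_response <= 0):
            raise ValueError(f"non-positive values after offset in column {resp_col!r}")
        log_fs = np.log(fs + self.log_offset_response)

        means: dict[str, float] = {}
        sds: dict[str, float] = {}
        for name, col in PREDICTOR_COLUMNS.items():
            x = points[col].to_numpy(dtype=float)
            if name in LOG_PREDICTORS:
                if np.any(x + self.log_offset_distance <= 0):
                    raise ValueError(f"non-positive values after offset in column {col!r}")
                x = np.log(x + self.log_offset_distance)
            sd = float(np.std(x, ddof=1))
            if sd == 0.0 or not np.isfinite(sd):
                raise ValueError(f"zero variance in column {col!r}")
            means[name] = float(np.mean(x))
            sds[name] = sd

        resp_sd = float(np.std(log_fs, ddof=1))
        if resp_sd == 0.0 or not np.isfinite(resp_sd):
            raise ValueError(f"zero variance in column {resp_col!r}")
        self.transform_params_ = TransformParams(
            variable=self.variable,
            response_mean=float(np.mean(log_fs)),
            response_sd=resp_sd,
            response_offset=self.log_offset_response,
            predictor_means=means,
            predictor_sds=sds,
            distance_offset=self.log_offset_distance,
        )
        return self

    def transform(self, points: pd.DataFrame) -> StandardizedDesign:
        if not hasattr(self, "transform_params_"):
            raise RuntimeError("DesignStandardizer is not fitted")
        tp = self.transform_params_
        resp_col = self._columns(points)
        y = tp.forward_response(points[resp_col].to_numpy(dtype=float))
        z_dist = tp.standardize_predictor("distance", points["distance_m"].to_numpy(dtype=float))
        z_age = tp.standardize_predictor("age", points["age_yr"].to_numpy(dtype=float))
        x_fixed = np.column_stack(
            [
                tp.standardize_predictor(t, points[PREDICTOR_COLUMNS[t]].to_numpy(dtype=float))
                for t in COVARIATE_TERMS
            ]
        )
        lu = points["land_use"].to_numpy()
        unknown = set(lu) - set(LAND_USES)
        if unknown:
            raise ValueError(f"unknown land-use levels: {sorted(unknown)}")
        lc_idx = np.array([LAND_USES.index(v) for v in lu], dtype=int)
        return StandardizedDesign(
            y=y, z_dist=z_dist, z_age=z_age, x_fixed=x_fixed, lc_idx=lc_idx, transform=tp
        )


def standardize(
    points: pd.DataFrame,
    variable: str,
    log_offset_distance: float = 1.0,
    log_offset_response: float = 1.0,
    frozen_transform: TransformParams | None = None,
) -> StandardizedDesign:
    """One-shot convenience wrapper over :class:`DesignStandardizer`."""
    est = DesignStandardizer(
        variable=variable,
        log_offset_response=log_offset_response,
        log_offset_distance=log_offset_distance,
        frozen_transform=frozen_transform,
    )
    return est.fit(points).transform(points)
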