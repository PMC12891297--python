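"""Conditional-effect curves and the two headline edge metrics.

From a fitted posterior, :func:`conditional_curve` evaluates the expected
structure value over a distance grid (0-2000 m, 1-m steps) with the control
covariates held at their sample means (standardized 0), back-transforming
*per draw* to natural units before averaging.  From the posterior-mean curve:

* **penetration depth** — the distance at which the curve first (sustainedly)
  reaches 90% of its value at the 2000-m reference, i.e. the largest d* such
  that FS(d) < 0.9 FS(2000) for all d <= d*, plus one grid step; 0 when the
  edge value already meets the threshold.
* **edge magnitude** — the signed relative difference
  100 (FS(2000) - FS(0)) / FS(2000); negative when the edge value exceeds
  the interior value.

Both are relative measures and invariant under positive scaling of the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import LAND_USES, MAX_EDGE_DISTANCE
from .model import PosteriorDraws
from .standardize import StandardizedDesign


def default_grid(step: float = 1.0, max_distance: float = MAX_EDGE_DISTANCE) -> np.ndarray:
    return np.arange(0.0, max_distance + step / 2, step)


@dataclass
class EdgeCurve:
    variable: str
    land_use: str
    age: float | None  # None = marginal (distance-only model)
    grid: np.ndarray
    mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("distance grid must be strictly increasing")

    @property
    def reference_value(self) -> float:
        """Curve value at the far end of the grid (the 2000-m reference)."""
        return float(self.mean[-1])

    @property
    def edge_value(self) -> float:
        return float(self.mean[0])


@dataclass
class EdgeMetrics:
    variable: str
    land_use: str
    age: float | None
    penetration_depth_m: float
    magnitude_pct: float
    reference_value: float


def conditional_curve(
    draws: PosteriorDraws,
    design: StandardizedDesign,
    land_use: str,
    age: float | None = None,
    grid: np.ndarray | None = None,
) -> EdgeCurve:
    """Posterior conditional-effect curve in natural units.

    For each grid distance the standardized log-distance is combined with the
    draw's varying coefficients for ``land_use`` (age terms only for an
    age-aware fit), back-transformed draw-by-draw through the stored response
    transform, then summarized by the mean and the central 95% band.
    """
    if land_use not in LAND_USES:
        raise ValueError(f"unknown land use {land_use!r}")
    if age is not None and not draws.include_age:
        raise ValueError("age-specific curve requested from an include_age=False fit")
    if age is None and draws.include_age:
        raise ValueError(
            "marginal curve requires a distance-only fit; pass an age for this model"
        )
    if grid is None:
        grid = default_grid()
    zd = design.standardize_distance(grid)

    a = draws.column(f"alpha[{land_use}]")
    bd = draws.column(f"b_dist[{land_use}]")
    mu = a[:, None] + bd[:, None] * zd[None, :]
    if age is not None:
        if age < 0:
            raise ValueError("age must be >= 0")
        za = float(design.standardize_age(age))
        ba = draws.column(f"b_age[{land_use}]")
        bi = draws.column(f"b_distage[{land_use}]")
        mu = mu + ba[:, None] * za + bi[:, None] * (zd[None, :] * za)

    nat = design.inverse_response(mu)  # per-draw back-transform, then average
    lo, hi = np.percentile(nat, [2.5, 97.5], axis=0)
    return EdgeCurve(
        variable=design.transform.variable,
        land_use=land_use,
        age=age,
        grid=np.asarray(grid, dtype=float),
        mean=nat.mean(axis=0),
        lo95=lo,
        hi95=hi,
    )


def penetration_depth(curve: EdgeCurve, fraction: float = 0.9) -> float:
    """Depth (m) of the edge effect: first sustained crossing of
    ``fraction * FS(reference)``; 0 when the curve starts at or above it."""
    ref = curve.reference_value
    if ref <= 0:
        raise ValueError("reference value FS(2000) must be > 0")
    below = curve.mean < fraction * ref
    if not below[0]:
        return 0.0
    if below.all():  # cannot happen for fraction < 1 with ref > 0
        return float(curve.grid[-1])
    first_ok = int(np.argmin(below))  # first grid index not below threshold
    step = float(curve.grid[first_ok] - curve.grid[first_ok - 1])
    return float(curve.grid[first_ok - 1] + step)


def edge_magnitude(curve: EdgeCurve) -> float:
    """Signed magnitude (%) of the edge effect relative to the 2000-m value."""
    ref = curve.reference_value
    if ref <= 0:
        raise ValueError("reference value FS(2000) must be > 0")
    return float(100.0 * (ref - curve.edge_value) / ref)


def curve_metrics(curve: EdgeCurve, fraction: float = 0.9) -> EdgeMetrics:
    return EdgeMetrics(
        variable=curve.variable,
        land_use=curve.land_use,
        age=curve.age,
        penetration_depth_m=penetration_depth(curve, fraction),
        magnitude_pct=edge_magnitude(curve),
        reference_value=curve.reference_value,
    )


def age_surface(
    draws: PosteriorDraws,
    design: StandardizedDesign,
    land_use: str,
    ages: list[float],
    grid: np.ndarray | None = None,
    fraction: float = 0.9,
) -> list[tuple[EdgeCurve, EdgeMetrics]]:
    """One conditional curve plus metrics per requested edge age.

    Tracks how penetration depth and magnitude evolve with time since
    deforestation (the degradation-debt trajectory).  Requires an age-aware
    fit.
    """
    if not draws.include_age:
        raise ValueError("age surface requires an include_age=True fit")
    out = []
    for age in ages:
        curve = conditional_curve(draws, design, land_use, age=age, grid=grid)
        out.append((curve, curve_metrics(curve, fraction)))
    return out
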