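"""Space-for-time sampling of forest points.

Points are drawn uniformly without replacement over eligible forest cells —
forested, within ``max_distance`` of a deforestation plot, and at least
``boundary_buffer`` inside the study-region boundary — one point per cell, at
the cell center.  Each point carries the response values, the distance to and
attributes of its nearest plot (clearing year -> edge age, contemporary land
use), climate covariates, accessibility distances, and the deforestation
legacy statistic ``Dist_Time``: the area (m*yr) under the point's annual
series of distances to the nearest already-cleared plot.  Points that sat
close to deforestation for decades have small ``Dist_Time``.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .constants import LAND_USES, MAX_EDGE_DISTANCE, SURVEY_YEAR, YEAR_RANGE
from .geometry import (
    annual_min_distance,
    distance_to_lines,
    distance_to_points,
    plot_distance_matrix,
)
from .landscape import DeforestationPlot, GridLandscape

#: Column order of the sample-point table.
POINT_COLUMNS = [
    "point_id",
    "x",
    "y",
    "fs_tree",
    "fs_shrub",
    "fs_agb",
    "distance_m",
    "age_yr",
    "land_use",
    "temp_c",
    "precip_mm",
    "dist_time_myr",
    "dist_home_m",
    "dist_roads_m",
]


class NearestPlot(NamedTuple):
    plot_id: int | None
    distance: float


#: Sentinel returned when no plot exists under the ``as_of_year`` filter.
NO_PLOT = NearestPlot(plot_id=None, distance=float("inf"))


def nearest_plot(
    point: tuple[float, float],
    plots: list[DeforestationPlot],
    as_of_year: int | None = None,
) -> NearestPlot:
    """Nearest plot (optionally among those already cleared by ``as_of_year``).

    Ties are broken by the lowest ``plot_id``.  Returns :data:`NO_PLOT` when
    the filter leaves no plots.
    """
    if as_of_year is not None:
        plots = [p for p in plots if p.year_cleared <= as_of_year]
    if not plots:
        return NO_PLOT
    plots = sorted(plots, key=lambda p: p.plot_id)
    d = plot_distance_matrix([point[0]], [point[1]], plots)[0]
    i = int(np.argmin(d))
    return NearestPlot(plot_id=plots[i].plot_id, distance=float(d[i]))


def distance_time_area(
    point: tuple[float, float],
    plots: list[DeforestationPlot],
    year_range: tuple[int, int] = YEAR_RANGE,
) -> float:
    """Area (m*yr) under the annual distance-to-nearest-cleared-plot series.

    The series runs from the first year any plot exists to ``year_range[1]``
    and is integrated by the rectangle rule (one rectangle per year); years
    before the first clearing contribute nothing.
    """
    dmat = plot_distance_matrix([point[0]], [point[1]], plots)
    years = [p.year_cleared for p in plots]
    _, series = annual_min_distance(dmat, years, year_range)
    return float(series[0].sum())


def extract_covariates(
    point: tuple[float, float], landscape: GridLandscape
) -> tuple[float, float, float, float]:
    """(Temp, Precip, Dist_Home, Dist_Roads) at a point.

    Raster values are looked up at the containing cell; distances are
    Euclidean to the nearest homestead point / road line.  Raises on nodata.
    """
    r, c = landscape.cell_index(point[0], point[1])
    temp = float(landscape.covariates["temp"][r, c])
    precip = float(landscape.covariates["precip"][r, c])
    if not (np.isfinite(temp) and np.isfinite(precip)):
        raise ValueError(f"nodata covariate value at point {point}")
    dh = float(distance_to_points([point[0]], [point[1]], landscape.homesteads)[0])
    dr = float(distance_to_lines([point[0]], [point[1]], landscape.roads)[0])
    return temp, precip, dh, dr


def sample_points(
    landscape: GridLandscape,
    plots: list[DeforestationPlot],
    n: int = 3000,
    max_distance: float = MAX_EDGE_DISTANCE,
    boundary_buffer: float = 10_000.0,
    seed: int = 0,
    survey_year: int = SURVEY_YEAR,
    year_range: tuple[int, int] = YEAR_RANGE,
) -> pd.DataFrame:
    """Draw ``n`` sample points and assemble the full point table.

    Returns a DataFrame with :data:`POINT_COLUMNS`.  Raises ``ValueError``
    naming the binding constraint when fewer than ``n`` cells are eligible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    active = sorted(
        (p for p in plots if p.year_cleared <= survey_year), key=lambda p: p.plot_id
    )
    if not active:
        raise ValueError("no plots cleared by the survey year")

    rows, cols = np.nonzero(landscape.forest_mask)
    X, Y = landscape.cell_centers()
    xs, ys = X[rows, cols], Y[rows, cols]

    dmat = plot_distance_matrix(xs, ys, active)
    idx_near = np.argmin(dmat, axis=1)
    dist = dmat[np.arange(dmat.shape[0]), idx_near]

    x0, y0 = landscape.origin
    d_boundary = np.minimum.reduce(
        [xs - x0, x0 + landscape.width - xs, ys - y0, y0 + landscape.height - ys]
    )
    ok_dist = (dist > 0) & (dist <= max_distance)
    ok_buf = d_boundary >= boundary_buffer
    eligible = ok_dist & ok_buf
    n_el = int(eligible.sum())
    if n_el < n:
        detail = (
            f"{int(ok_dist.sum())} cells within {max_distance} m of a plot, "
            f"{int(ok_buf.sum())} cells at least {boundary_buffer} m inside the boundary, "
            f"{n_el} cells satisfying both"
        )
        raise ValueError(f"only {n_el} eligible forest cells for n={n} points ({detail})")

    rng = np.random.default_rng(seed)
    pick = rng.choice(np.nonzero(eligible)[0], size=n, replace=False)
    pick.sort()  # stable row order independent of draw order

    sel_rows, sel_cols = rows[pick], cols[pick]
    sx, sy = xs[pick], ys[pick]
    near = idx_near[pick]
    years = np.array([p.year_cleared for p in active])
    lus = np.array([p.land_use for p in active])

    _, series = annual_min_distance(dmat[pick], years, year_range)
    dist_time = series.sum(axis=1)

    def structure_at(var):
        if var not in landscape.structure:
            raise ValueError(f"structure raster {var!r} missing; run simulate_structure first")
        return landscape.structure[var][sel_rows, sel_cols]

    table = pd.DataFrame(
        {
            "point_id": np.arange(n),
            "x": sx,
            "y": sy,
            "fs_tree": structure_at("tree_cover"),
            "fs_shrub": structure_at("shrub_cover"),
            "fs_agb": structure_at("agb"),
            "distance_m": dist[pick],
            "age_yr": (survey_year - years[near]).astype(float),
            "land_use": lus[near],
            "temp_c": landscape.covariates["temp"][sel_rows, sel_cols],
            "precip_mm": landscape.covariates["precip"][sel_rows, sel_cols],
            "dist_time_myr": dist_time,
            "dist_home_m": distance_to_points(sx, sy, landscape.homesteads),
            "dist_roads_m": distance_to_lines(sx, sy, landscape.roads),
        }
    )[POINT_COLUMNS]
    assert set(table["land_use"]) <= set(LAND_USES)
    return table
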