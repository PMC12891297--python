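"""Planar distance primitives shared by sampling, simulation and footprint code.

All distances are Euclidean on the projected plane, from a query point (a cell
center or a sample point) to the nearest point of a plot *polygon*.  A point
adjacent to a plot therefore has a small positive distance (half a cell for a
cell center next to a plot face), and the same convention is used everywhere:
point sampling, the deforestation-legacy series, and the footprint rasters.
"""

from __future__ import annotations

import numpy as np
import shapely


def plot_distance_matrix(xs, ys, plots) -> np.ndarray:
    """Distance from each point to each plot polygon.

    Parameters
    ----------
    xs, ys : array-like, shape (n,)
        Point coordinates in map units (m).
    plots : sequence of DeforestationPlot

    Returns
    -------
    ndarray, shape (n, n_plots)
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    pts = shapely.points(xs, ys)
    geoms = np.array([p.polygon for p in plots], dtype=object)
    return shapely.distance(pts[:, None], geoms[None, :])


def nearest_plot_arrays(xs, ys, plots):
    """Index of and distance to the nearest plot for each point.

    Ties are broken in favour of the plot appearing first in ``plots``; callers
    pass plots sorted by ``plot_id`` so ties resolve to the lowest id.

    Returns
    -------
    idx : ndarray of int, shape (n,)
    dist : ndarray of float, shape (n,)
    """
    d = plot_distance_matrix(xs, ys, plots)
    idx = np.argmin(d, axis=1)  # first occurrence -> lowest plot_id
    return idx, d[np.arange(d.shape[0]), idx]


def distance_to_points(xs, ys, targets) -> np.ndarray:
    """Distance from each query point to the nearest target point.

    ``targets`` is an (m, 2) array; returns +inf where there are no targets.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    targets = np.asarray(targets, dtype=float).reshape(-1, 2)
    if targets.shape[0] == 0:
        return np.full(xs.shape, np.inf)
    dx = xs[:, None] - targets[None, :, 0]
    dy = ys[:, None] - targets[None, :, 1]
    return np.sqrt(dx * dx + dy * dy).min(axis=1)


def distance_to_lines(xs, ys, lines) -> np.ndarray:
    """Distance from each query point to the nearest of a set of polylines."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if not lines:
        return np.full(xs.shape, np.inf)
    pts = shapely.points(xs, ys)
    union = shapely.union_all(np.array(list(lines), dtype=object))
    return shapely.distance(pts, union)


def annual_min_distance(dist_matrix, years, year_range):
    """Per-point annual series of distance to the nearest already-cleared plot.

    Parameters
    ----------
    dist_matrix : ndarray (n_points, n_plots)
        Static point-to-plot distances.
    years : array-like of int, shape (n_plots,)
        Clearing year of each plot.
    year_range : (int, int)
        Inclusive span of the deforestation record.

    Returns
    -------
    series_years : ndarray of int
        Years from the first clearing year to ``year_range[1]``.
    series : ndarray (n_points, len(series_years))
        Non-increasing running minimum distance per point.
    """
    years = np.asarray(years, dtype=int)
    lo, hi = int(year_range[0]), int(year_range[1])
    sel = (years >= lo) & (years <= hi)
    if not sel.any():
        raise ValueError(f"no plots cleared within year range {year_range}")
    dm = np.asarray(dist_matrix, dtype=float)[:, sel]
    yrs = years[sel]
    first = int(yrs.min())
    series_years = np.arange(first, hi + 1)
    series = np.empty((dm.shape[0], series_years.size))
    running = np.full(dm.shape[0], np.inf)
    for j, y in enumerate(series_years):
        new = yrs == y
        if new.any():
            running = np.minimum(running, dm[:, new].min(axis=1))
        series[:, j] = running
    return series_years, series
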