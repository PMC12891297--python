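"""Seeded synthetic dry-forest landscapes with deforestation plots.

The generator produces the raw material for the whole pipeline: a gridded
landscape (forest mask, climate covariate fields, roads, homesteads) and a set
of rectangular deforestation plots with clearing years and post-deforestation
land uses.  :func:`simulate_structure` then fills the forest-structure rasters
(tree cover, shrub cover, aboveground biomass) from a known generative
edge-effect model, so that every downstream stage — sampling, model fitting,
penetration depths, footprint accounting — can be tested against known truth.

Two generative modes exist.  ``model_matched`` draws the response from exactly
the linear predictor of the fitted multilevel model (Gaussian noise on the
standardized log scale), making parameter recovery well-posed.  ``mechanistic``
uses a saturating exponential edge profile with an age lag,
``FS(d) = FS_far * (1 - M_LC * (1 - exp(-lag*age)) * exp(-d/lambda_LC))``,
and serves as an off-model robustness check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon, box

from .constants import (
    COVARIATE_TERMS,
    LAND_USES,
    MAX_EDGE_DISTANCE,
    STRUCTURE_VARS,
    SURVEY_YEAR,
    YEAR_RANGE,
)
from .geometry import (
    annual_min_distance,
    distance_to_lines,
    distance_to_points,
    nearest_plot_arrays,
    plot_distance_matrix,
)
from .standardize import TransformParams


class PlacementError(RuntimeError):
    """Raised when the requested plots cannot be placed without overlap."""


@dataclass
class DeforestationPlot:
    plot_id: int
    polygon: Polygon
    year_cleared: int
    land_use: str

    def __post_init__(self):
        if self.land_use not in LAND_USES:
            raise ValueError(f"land_use must be one of {LAND_USES}, got {self.land_use!r}")
        if not (YEAR_RANGE[0] <= self.year_cleared <= YEAR_RANGE[1]):
            raise ValueError(
                f"year_cleared {self.year_cleared} outside data period {YEAR_RANGE}"
            )


@dataclass
class GridLandscape:
    """Co-registered rasters plus vector context on a regular planar grid.

    Row 0 is the southern (bottom) row; cell centers are at
    ``origin + (index + 0.5) * cell_size``.  Structure rasters are defined
    (finite) on forest cells only and NaN elsewhere.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float]
    forest_mask: np.ndarray
    covariates: dict[str, np.ndarray]
    structure: dict[str, np.ndarray] = field(default_factory=dict)
    roads: list[LineString] = field(default_factory=list)
    homesteads: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    boundary: Polygon | None = None
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 1e4

    def cell_centers(self):
        """(X, Y) coordinate rasters of cell centers, shape (n_rows, n_cols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_index(self, x, y):
        """(row, col) of the cell containing each coordinate; errors off-grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        if np.any((col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)):
            raise ValueError("coordinates outside the landscape grid")
        return row, col

    def validate(self):
        for name, r in {**self.covariates, **self.structure}.items():
            if r.shape != self.shape:
                raise ValueError(f"raster {name!r} shape {r.shape} != grid {self.shape}")
        for name, r in self.structure.items():
            on = r[self.forest_mask]
            if not np.all(np.isfinite(on)):
                raise ValueError(f"structure {name!r} has non-finite values on forest cells")
            if np.any(np.isfinite(r[~self.forest_mask])):
                raise ValueError(f"structure {name!r} defined outside forest")
            if name in ("tree_cover", "shrub_cover") and (on.min() < 0 or on.max() > 100):
                raise ValueError(f"{name!r} outside [0, 100]")
            if name == "agb" and on.min() < 0:
                raise ValueError("agb has negative values")
        return self


@dataclass
class LandscapeConfig:
    """Defaults emulate the study setting at reduced extent: a ~32 x 32 km
    window with 100-m cells, ~a third of the interior cleared since 1976,
    an east-west rainfall gradient and a south-north temperature gradient."""

    n_rows: int = 320
    n_cols: int = 320
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)
    n_plots: int = 35
    plot_side_range: tuple[float, float] = (500.0, 2000.0)
    land_use_probs: dict[str, float] = field(
        default_factory=lambda: {"cropland": 0.4, "pasture": 0.4, "silvopasture": 0.2}
    )
    year_range: tuple[int, int] = YEAR_RANGE
    placement_margin: float = 10_000.0
    n_homesteads: int = 25
    n_roads: int = 6
    temp_range: tuple[float, float] = (18.0, 24.0)
    precip_range: tuple[float, float] = (600.0, 1000.0)
    covariate_noise_sd: tuple[float, float] = (0.3, 20.0)
    n_nonforest_patches: int = 0
    nonforest_patch_side: float = 500.0
    max_placement_attempts: int = 200

    def validate(self):
        w = self.n_cols * self.cell_size
        h = self.n_rows * self.cell_size
        if self.n_plots > 0:
            max_side = self.plot_side_range[1]
            if w - 2 * self.placement_margin < max_side or h - 2 * self.placement_margin < max_side:
                raise ValueError(
                    "placement_margin leaves no room for plots of the requested size"
                )
        p = sum(self.land_use_probs.get(lu, 0.0) for lu in LAND_USES)
        if abs(p - 1.0) > 1e-9:
            raise ValueError("land_use_probs must sum to 1 over the three land uses")
        if not (YEAR_RANGE[0] <= self.year_range[0] <= self.year_range[1] <= YEAR_RANGE[1]):
            raise ValueError(f"year_range must lie within {YEAR_RANGE}")
        return self


@dataclass
class GenerativeParams:
    """Truth for structure simulation, on the standardized log scale.

    ``intercept``, ``b_dist``, ``b_age``, ``b_int`` map each land use to the
    varying coefficients of the generative linear predictor; ``cov_slopes``
    maps covariate terms to fixed slopes.  ``response_log_mean/sd`` place the
    standardized response on a natural scale via
    ``FS = exp(eta * sd + mean) - 1``.  Mechanistic-mode fields describe the
    saturating exponential profile instead.
    """

    mode: str = "model_matched"
    intercept: dict[str, float] = field(default_factory=lambda: dict.fromkeys(LAND_USES, 0.0))
    b_dist: dict[str, float] = field(default_factory=lambda: dict.fromkeys(LAND_USES, 0.3))
    b_age: dict[str, float] = field(default_factory=lambda: dict.fromkeys(LAND_USES, 0.0))
    b_int: dict[str, float] = field(default_factory=lambda: dict.fromkeys(LAND_USES, 0.0))
    cov_slopes: dict[str, float] = field(
        default_factory=lambda: dict.fromkeys(COVARIATE_TERMS, 0.0)
    )
    noise_sd: float = 0.5
    response_log_mean: float = 4.0
    response_log_sd: float = 0.35
    reference_distance: float = MAX_EDGE_DISTANCE
    # mechanistic mode
    fs_far: float = 80.0
    magnitude: dict[str, float] = field(default_factory=lambda: dict.fromkeys(LAND_USES, 0.3))
    efold: dict[str, float] = field(default_factory=lambda: dict.fromkeys(LAND_USES, 200.0))
    lag_rate: float = 0.1

    def validate(self):
        if self.mode not in ("model_matched", "mechanistic"):
            raise ValueError(f"unknown generative mode {self.mode!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if any(v <= 0 for v in self.efold.values()):
            raise ValueError("e-folding scales must be > 0")
        if any(abs(v) >= 1 for v in self.magnitude.values()):
            raise ValueError("relative magnitudes must have |M| < 1")
        return self


def default_generative_params() -> dict[str, GenerativeParams]:
    """Study-condition truth per structure variable.

    Distance slopes are positive (structure degraded near edges), strongest
    for cropland, weak for silvopasture; the distance-age interaction deepens
    the cropland/pasture effect with edge age, while silvopasture starts with
    a slightly *positive* edge effect at young ages that reverses as the
    interaction accumulates.  Noise sd 0.5 on the standardized log scale.
    """
    common = dict(
        cov_slopes={
            "temp": -0.10,
            "precip": 0.15,
            "dist_time": 0.10,
            "dist_home": 0.05,
            "dist_roads": 0.05,
        },
        noise_sd=0.5,
    )
    varying = dict(
        intercept={"cropland": 0.10, "pasture": 0.0, "silvopasture": -0.10},
        b_dist={"cropland": 0.35, "pasture": 0.20, "silvopasture": 0.02},
        b_age={"cropland": -0.12, "pasture": -0.08, "silvopasture": -0.06},
        b_int={"cropland": 0.06, "pasture": 0.04, "silvopasture": 0.05},
    )
    return {
        "tree_cover": GenerativeParams(
            response_log_mean=np.log(41.0), response_log_sd=0.30, **varying, **common
        ),
        "shrub_cover": GenerativeParams(
            response_log_mean=np.log(31.0), response_log_sd=0.30, **varying, **common
        ),
        "agb": GenerativeParams(
            response_log_mean=np.log(81.0), response_log_sd=0.30, **varying, **common
        ),
    }


def _place_rectangles(rng, config: LandscapeConfig, n: int, side_range, existing):
    """Rejection-sample disjoint axis-aligned rectangles inside the margin box."""
    x0, y0 = config.origin
    w = config.n_cols * config.cell_size
    h = config.n_rows * config.cell_size
    m = config.placement_margin
    placed = list(existing)
    out = []
    attempts_per = config.max_placement_attempts
    for i in range(n):
        for _ in range(attempts_per):
            pw = rng.uniform(*side_range)
            ph = rng.uniform(*side_range)
            cx = rng.uniform(x0 + m + pw / 2, x0 + w - m - pw / 2)
            cy = rng.uniform(y0 + m + ph / 2, y0 + h - m - ph / 2)
            rect = box(cx - pw / 2, cy - ph / 2, cx + pw / 2, cy + ph / 2)
            if all(not rect.intersects(g) for g in placed):
                placed.append(rect)
                out.append(rect)
                break
        else:
            raise PlacementError(
                f"could not place rectangle {i + 1} of {n} after "
                f"{attempts_per} attempts; reduce plot count/size or margins"
            )
    return out


def generate_landscape(
    config: LandscapeConfig, seed: int
) -> tuple[GridLandscape, list[DeforestationPlot]]:
    """Generate a landscape and its deforestation plots, deterministic in ``seed``.

    Plot footprints are pairwise disjoint and the forest mask is their exact
    complement (minus optional generic non-forest patches), so plot cells and
    forest cells partition the grid.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    x0, y0 = config.origin
    w = config.n_cols * config.cell_size
    h = config.n_rows * config.cell_size
    boundary = box(x0, y0, x0 + w, y0 + h)

    rects = _place_rectangles(rng, config, config.n_plots, config.plot_side_range, [])
    years = rng.integers(config.year_range[0], config.year_range[1] + 1, size=config.n_plots)
    probs = [config.land_use_probs[lu] for lu in LAND_USES]
    uses = list(rng.choice(LAND_USES, size=config.n_plots, p=probs))
    # guarantee every level is represented when enough plots exist
    if config.n_plots >= len(LAND_USES):
        for i, lu in enumerate(LAND_USES):
            uses[i] = lu
    plots = [
        DeforestationPlot(plot_id=i, polygon=r, year_cleared=int(years[i]), land_use=uses[i])
        for i, r in enumerate(rects)
    ]

    nonforest = []
    if config.n_nonforest_patches > 0:
        nonforest = _place_rectangles(
            rng,
            config,
            config.n_nonforest_patches,
            (config.nonforest_patch_side, config.nonforest_patch_side),
            rects,
        )

    X, Y = np.meshgrid(
        x0 + (np.arange(config.n_cols) + 0.5) * config.cell_size,
        y0 + (np.arange(config.n_rows) + 0.5) * config.cell_size,
    )
    forest = np.ones(X.shape, dtype=bool)
    for geom in rects + nonforest:
        forest &= ~shapely.contains_xy(geom, X, Y)

    t0, t1 = config.temp_range
    p0, p1 = config.precip_range
    temp = t0 + (t1 - t0) * (Y - y0) / h + rng.normal(0.0, config.covariate_noise_sd[0], X.shape)
    precip = p0 + (p1 - p0) * (X - x0) / w + rng.normal(
        0.0, config.covariate_noise_sd[1], X.shape
    )

    roads = []
    for _ in range(config.n_roads):
        # straight road crossing the full landscape, random orientation
        if rng.random() < 0.5:
            roads.append(
                LineString([(x0, y0 + rng.uniform(0, h)), (x0 + w, y0 + rng.uniform(0, h))])
            )
        else:
            roads.append(
                LineString([(x0 + rng.uniform(0, w), y0), (x0 + rng.uniform(0, w), y0 + h)])
            )
    homesteads = np.column_stack(
        [rng.uniform(x0, x0 + w, config.n_homesteads), rng.uniform(y0, y0 + h, config.n_homesteads)]
    ) if config.n_homesteads > 0 else np.zeros((0, 2))

    land = GridLandscape(
        n_rows=config.n_rows,
        n_cols=config.n_cols,
        cell_size=config.cell_size,
        origin=config.origin,
        forest_mask=forest,
        covariates={"temp": temp, "precip": precip},
        roads=roads,
        homesteads=homesteads,
        boundary=boundary,
        meta={"seed": int(seed), "config": config},
    )
    return land, plots


def cell_predictors(
    landscape: GridLandscape,
    plots: list[DeforestationPlot],
    survey_year: int = SURVEY_YEAR,
    year_range: tuple[int, int] = YEAR_RANGE,
):
    """Per-forest-cell raw predictors of the edge model.

    Returns a dict of flat arrays over forest cells (row-major order of
    ``forest_mask.nonzero()``): distance, age, lc_idx, temp, precip,
    dist_time, dist_home, dist_roads, plus the cell coordinates.
    Only plots already cleared at ``survey_year`` exist for distance and
    legacy purposes.
    """
    active = [p for p in plots if p.year_cleared <= survey_year]
    if not active:
        raise ValueError("survey_year precedes all clearing years: no edges exist yet")
    active = sorted(active, key=lambda p: p.plot_id)
    rows, cols = np.nonzero(landscape.forest_mask)
    X, Y = landscape.cell_centers()
    xs, ys = X[rows, cols], Y[rows, cols]

    dmat = plot_distance_matrix(xs, ys, active)
    idx = np.argmin(dmat, axis=1)
    dist = dmat[np.arange(dmat.shape[0]), idx]
    years = np.array([p.year_cleared for p in active])
    age = (survey_year - years[idx]).astype(float)
    lc_idx = np.array([LAND_USES.index(p.land_use) for p in active])[idx]

    _, series = annual_min_distance(dmat, years, year_range)
    finite = np.isfinite(series)
    dist_time = np.where(finite, series, 0.0).sum(axis=1)

    out = {
        "x": xs,
        "y": ys,
        "rows": rows,
        "cols": cols,
        "distance": dist,
        "age": age,
        "lc_idx": lc_idx,
        "nearest_plot_id": np.array([p.plot_id for p in active])[idx],
        "temp": landscape.covariates["temp"][rows, cols],
        "precip": landscape.covariates["precip"][rows, cols],
        "dist_time": dist_time,
        "dist_home": distance_to_points(xs, ys, landscape.homesteads),
        "dist_roads": distance_to_lines(xs, ys, landscape.roads),
    }
    return out


def _population_transform(
    variable: str, params: GenerativeParams, preds: dict
) -> TransformParams:
    """Standardization statistics over forest cells within the reference
    distance (the model's domain), population ddof=0."""
    ref = preds["distance"] <= params.reference_distance
    means, sds = {}, {}
    for name in ("distance", "age") + COVARIATE_TERMS:
        x = preds[name][ref].astype(float)
        if name in ("distance", "age"):
            x = np.log(x + 1.0)
        means[name] = float(x.mean())
        sd = float(x.std())
        sds[name] = sd if sd > 0 else 1.0
    return TransformParams(
        variable=variable,
        response_mean=params.response_log_mean,
        response_sd=params.response_log_sd,
        response_offset=1.0,
        predictor_means=means,
        predictor_sds=sds,
    )


def linear_predictor(params: GenerativeParams, tp: TransformParams, preds: dict) -> np.ndarray:
    """Noise-free standardized linear predictor at each forest cell."""
    zd = tp.standardize_predictor("distance", preds["distance"])
    za = tp.standardize_predictor("age", preds["age"])
    lc = preds["lc_idx"]
    a = np.array([params.intercept[lu] for lu in LAND_USES])[lc]
    bd = np.array([params.b_dist[lu] for lu in LAND_USES])[lc]
    ba = np.array([params.b_age[lu] for lu in LAND_USES])[lc]
    bi = np.array([params.b_int[lu] for lu in LAND_USES])[lc]
    eta = a + bd * zd + ba * za + bi * zd * za
    for term in COVARIATE_TERMS:
        eta = eta + params.cov_slopes[term] * tp.standardize_predictor(term, preds[term])
    return eta


def simulate_structure(
    landscape: GridLandscape,
    plots: list[DeforestationPlot],
    params: GenerativeParams | dict[str, GenerativeParams] | None = None,
    survey_year: int = SURVEY_YEAR,
    seed: int = 0,
    variables: tuple[str, ...] = STRUCTURE_VARS,
) -> GridLandscape:
    """Fill the structure rasters from the generative edge model.

    ``params`` may be one :class:`GenerativeParams` (shared truth, independent
    noise per variable) or a mapping variable -> params; defaults to
    :func:`default_generative_params`.  The standardization used for
    generation is stored in ``landscape.meta['generative_transform']`` so a
    recovery study can fit on exactly the generative scale.
    """
    if params is None:
        params = default_generative_params()
    if isinstance(params, GenerativeParams):
        params = {v: params for v in variables}
    for p in params.values():
        p.validate()

    rng = np.random.default_rng(seed)
    preds = cell_predictors(landscape, plots, survey_year=survey_year)
    rows, cols = preds["rows"], preds["cols"]
    n = rows.size
    transforms: dict[str, TransformParams] = {}

    for var in variables:
        p = params[var]
        if p.mode == "model_matched":
            tp = _population_transform(var, p, preds)
            eta = linear_predictor(p, tp, preds) + rng.normal(0.0, p.noise_sd, n)
            fs = np.exp(eta * tp.response_sd + tp.response_mean) - tp.response_offset
            transforms[var] = tp
        elif p.mode == "mechanistic":
            lc = preds["lc_idx"]
            m = np.array([p.magnitude[lu] for lu in LAND_USES])[lc]
            lam = np.array([p.efold[lu] for lu in LAND_USES])[lc]
            depress = m * (1.0 - np.exp(-p.lag_rate * preds["age"])) * np.exp(
                -preds["distance"] / lam
            )
            fs = p.fs_far * (1.0 - depress) * np.exp(rng.normal(0.0, p.noise_sd, n))
        else:  # pragma: no cover - validate() rejects earlier
            raise ValueError(f"unknown generative mode {p.mode!r}")

        fs = np.maximum(fs, 0.0)
        if var in ("tree_cover", "shrub_cover"):
            fs = np.minimum(fs, 100.0)
        raster = np.full(landscape.shape, np.nan)
        raster[rows, cols] = fs
        landscape.structure[var] = raster

    landscape.meta["generative_params"] = params
    if transforms:
        landscape.meta["generative_transform"] = transforms
    landscape.meta["survey_year"] = int(survey_year)
    landscape.validate()
    return landscape
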