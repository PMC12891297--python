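"""Config-driven end-to-end orchestration.

Five stages — simulate, sample, fit, metrics, footprint — each with stable
on-disk outputs under one output directory, a manifest with file hashes, and
per-stage seeds derived deterministically from the master seed so that any
stage can be re-run in isolation and reproduce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .constants import LAND_USES, STRUCTURE_VARS, SURVEY_YEAR
from .footprint import biomass_deficit, map_edge_zone, summarize_footprint
from .landscape import (
    GridLandscape,
    LandscapeConfig,
    default_generative_params,
    generate_landscape,
    simulate_structure,
)
from .metrics import EdgeCurve, age_surface, conditional_curve, curve_metrics, default_grid
from .model import EdgeEffectsRegressor, PosteriorDraws, posterior_predictive_check
from .sampling import sample_points
from .standardize import standardize


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class ConfigError(ValueError):
    pass


@dataclass
class SamplingConfig:
    n: int = 3000
    max_distance: float = 2000.0
    boundary_buffer: float = 10_000.0


@dataclass
class ModelConfig:
    include_age: bool = False
    chains: int = 2
    iterations: int = 2000
    warmup: int = 500
    target_accept: float = 0.8
    max_treedepth: int = 10


@dataclass
class MetricsConfig:
    fraction: float = 0.9
    grid_step: float = 1.0
    ages: list[float] = field(default_factory=list)
    eval_age: float | None = None  # age at which footprint depths are taken (age models)


@dataclass
class FootprintConfig:
    threshold: float = 0.10
    deficit_mode: str = "model"
    potential_mode: str = "global"


@dataclass
class PipelineConfig:
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    footprint: FootprintConfig = field(default_factory=FootprintConfig)
    variables: tuple[str, ...] = STRUCTURE_VARS
    survey_year: int = SURVEY_YEAR
    seed: int = 0
    outdir: str = "chacoedge_run"

    def validate(self):
        self.landscape.validate()
        if self.metrics.ages and not self.model.include_age:
            raise ConfigError("metrics.ages requested but model.include_age is false")
        if self.model.include_age and self.metrics.eval_age is None and not self.metrics.ages:
            raise ConfigError("age model configured but no metrics.ages / eval_age given")
        if not (0 < self.metrics.fraction <= 1):
            raise ConfigError("metrics.fraction must be in (0, 1]")
        if not set(self.variables) <= set(STRUCTURE_VARS):
            raise ConfigError(f"variables must be among {STRUCTURE_VARS}")
        if self.footprint.deficit_mode not in ("model", "observed"):
            raise ConfigError("footprint.deficit_mode must be 'model' or 'observed'")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variables"] = list(self.variables)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {
            "landscape": LandscapeConfig,
            "sampling": SamplingConfig,
            "model": ModelConfig,
            "metrics": MetricsConfig,
            "footprint": FootprintConfig,
        }
        kwargs = {}
        for key, klass in sub.items():
            if key in d:
                v = d.pop(key)
                if isinstance(v, dict):
                    # YAML gives lists for tuple fields; coerce
                    v = {
                        k: tuple(x) if isinstance(x, list) and k.endswith(("range", "origin", "noise_sd")) else x
                        for k, x in v.items()
                    }
                    kwargs[key] = klass(**v)
                else:
                    kwargs[key] = v
        if "variables" in d:
            d["variables"] = tuple(d["variables"])
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(cio.read_yaml(path) or {})


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % 2**31


# ---- landscape persistence ---------------------------------------------------


def save_landscape(landscape: GridLandscape, plots, outdir: Path):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_ascii_grid(outdir / "forest_mask.asc", landscape.forest_mask.astype(float), landscape)
    for name, r in landscape.covariates.items():
        cio.write_ascii_grid(outdir / f"{name}.asc", r, landscape)
    for name, r in landscape.structure.items():
        cio.write_ascii_grid(outdir / f"{name}.asc", r, landscape)
    cio.plots_to_geojson(plots, outdir / "plots.geojson")
    roads_fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [list(c) for c in l.coords]},
                "properties": {"road_id": i},
            }
            for i, l in enumerate(landscape.roads)
        ],
    }
    (outdir / "roads.geojson").write_text(json.dumps(roads_fc, sort_keys=True) + "\n")
    pd.DataFrame(landscape.homesteads, columns=["x", "y"]).to_csv(
        outdir / "homesteads.csv", index=False, float_format="%.6f"
    )


def load_landscape(outdir: Path) -> tuple[GridLandscape, list]:
    from shapely.geometry import LineString, box

    outdir = Path(outdir)
    mask, header = cio.read_ascii_grid(outdir / "forest_mask.asc")
    n_rows, n_cols = mask.shape
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"])
    covariates = {}
    structure = {}
    for name in ("temp", "precip"):
        covariates[name], _ = cio.read_ascii_grid(outdir / f"{name}.asc")
    for name in STRUCTURE_VARS:
        p = outdir / f"{name}.asc"
        if p.exists():
            structure[name], _ = cio.read_ascii_grid(p)
    roads_fc = json.loads((outdir / "roads.geojson").read_text())
    roads = [LineString(f["geometry"]["coordinates"]) for f in roads_fc["features"]]
    homesteads = pd.read_csv(outdir / "homesteads.csv").to_numpy(dtype=float)
    landscape = GridLandscape(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin=origin,
        forest_mask=mask == 1.0,
        covariates=covariates,
        structure=structure,
        roads=roads,
        homesteads=homesteads.reshape(-1, 2),
        boundary=box(origin[0], origin[1], origin[0] + n_cols * cell, origin[1] + n_rows * cell),
    )
    plots = cio.plots_from_geojson(outdir / "plots.geojson")
    return landscape, plots


# ---- draws persistence -------------------------------------------------------


def save_draws(draws: PosteriorDraws, csv_path, json_path):
    draws.to_long_dataframe().to_csv(csv_path, index=False, float_format="%.10g")
    cio.write_json(draws.diagnostics_dict(), json_path)


def load_draws(csv_path, json_path) -> PosteriorDraws:
    df = pd.read_csv(csv_path)
    diag = json.loads(Path(json_path).read_text())
    names = list(dict.fromkeys(df["parameter"]))
    chains = int(df["chain"].max()) + 1
    iters = int(df["iteration"].max()) + 1
    arr = np.empty((chains, iters, len(names)))
    for j, nm in enumerate(names):
        sub = df[df["parameter"] == nm]
        arr[sub["chain"].to_numpy(), sub["iteration"].to_numpy(), j] = sub["value"].to_numpy()
    return PosteriorDraws(
        names=names,
        array=arr,
        rhat=diag.get("rhat", {}),
        ess=diag.get("ess", {}),
        seed=diag.get("seed", 0),
        spec_hash=diag.get("spec_hash", ""),
        include_age=diag.get("include_age", False),
        n_divergent=diag.get("n_divergent", 0),
    )


# ---- stages ------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, outdir: Path):
    landscape, plots = generate_landscape(config.landscape, stage_seed(config.seed, "simulate"))
    simulate_structure(
        landscape,
        plots,
        default_generative_params(),
        survey_year=config.survey_year,
        seed=stage_seed(config.seed, "structure"),
    )
    save_landscape(landscape, plots, outdir)
    return landscape, plots


def stage_sample(config: PipelineConfig, outdir: Path, landscape=None, plots=None):
    if landscape is None:
        landscape, plots = load_landscape(outdir)
    points = sample_points(
        landscape,
        plots,
        n=config.sampling.n,
        max_distance=config.sampling.max_distance,
        boundary_buffer=config.sampling.boundary_buffer,
        seed=stage_seed(config.seed, "sample"),
        survey_year=config.survey_year,
    )
    cio.write_points_csv(points, outdir / "points.csv")
    transforms = {
        v: standardize(points, v).transform.to_dict() for v in config.variables
    }
    cio.write_yaml(transforms, outdir / "standardization.yaml")
    return points


def stage_fit(config: PipelineConfig, outdir: Path, points=None):
    if points is None:
        path = outdir / "points.csv"
        if not path.exists():
            raise FileNotFoundError(f"prerequisite missing: {path} (run the sample stage first)")
        points = pd.read_csv(path)
    fits = {}
    for variable in config.variables:
        design = standardize(points, variable)
        est = EdgeEffectsRegressor(
            include_age=config.model.include_age,
            chains=config.model.chains,
            iterations=config.model.iterations,
            warmup=config.model.warmup,
            target_accept=config.model.target_accept,
            max_treedepth=config.model.max_treedepth,
            seed=stage_seed(config.seed, f"fit:{variable}"),
        )
        est.fit(design)
        ppc = posterior_predictive_check(
            est.draws_, design, n_rep=100, seed=stage_seed(config.seed, f"ppc:{variable}")
        )
        save_draws(est.draws_, outdir / f"draws_{variable}.csv", outdir / f"diagnostics_{variable}.json")
        diag = json.loads((outdir / f"diagnostics_{variable}.json").read_text())
        diag["posterior_predictive"] = ppc.summary()
        cio.write_json(diag, outdir / f"diagnostics_{variable}.json")
        fits[variable] = (est.draws_, design)
    return fits


def stage_metrics(config: PipelineConfig, outdir: Path, fits=None):
    if fits is None:
        path = outdir / "points.csv"
        if not path.exists():
            raise FileNotFoundError(f"prerequisite missing: {path} (run the sample stage first)")
        points = pd.read_csv(path)
        fits = {}
        for variable in config.variables:
            dpath = outdir / f"draws_{variable}.csv"
            if not dpath.exists():
                raise FileNotFoundError(
                    f"prerequisite missing: {dpath} (run the fit stage first)"
                )
            draws = load_draws(dpath, outdir / f"diagnostics_{variable}.json")
            fits[variable] = (draws, standardize(points, variable))

    grid = default_grid(step=config.metrics.grid_step)
    curve_rows, metric_rows = [], []
    curves: dict[str, dict[str, EdgeCurve]] = {}
    for variable, (draws, design) in fits.items():
        curves[variable] = {}
        for lu in LAND_USES:
            if draws.include_age:
                ages = config.metrics.ages or [config.metrics.eval_age]
                for (curve, em) in age_surface(
                    draws, design, lu, ages=ages, grid=grid, fraction=config.metrics.fraction
                ):
                    _append_curve(curve_rows, metric_rows, curve, em)
                eval_age = (
                    config.metrics.eval_age
                    if config.metrics.eval_age is not None
                    else max(ages)
                )
                curves[variable][lu] = conditional_curve(
                    draws, design, lu, age=eval_age, grid=grid
                )
            else:
                curve = conditional_curve(draws, design, lu, age=None, grid=grid)
                em = curve_metrics(curve, config.metrics.fraction)
                _append_curve(curve_rows, metric_rows, curve, em)
                curves[variable][lu] = curve
    pd.DataFrame(curve_rows).to_csv(outdir / "curves.csv", index=False, float_format="%.6f")
    pd.DataFrame(metric_rows).to_csv(outdir / "metrics.csv", index=False, float_format="%.6f")
    return curves


def _append_curve(curve_rows, metric_rows, curve, em):
    age = "marginal" if curve.age is None else curve.age
    step = max(1, curve.grid.size // 200)  # thin the stored curve to ~200 rows
    for i in range(0, curve.grid.size, step):
        curve_rows.append(
            {
                "variable": curve.variable,
                "land_use": curve.land_use,
                "age": age,
                "distance_m": curve.grid[i],
                "mean": curve.mean[i],
                "lo95": curve.lo95[i],
                "hi95": curve.hi95[i],
            }
        )
    metric_rows.append(
        {
            "variable": em.variable,
            "land_use": em.land_use,
            "age": age,
            "penetration_m": em.penetration_depth_m,
            "magnitude_pct": em.magnitude_pct,
        }
    )


def stage_footprint(config: PipelineConfig, outdir: Path, landscape=None, plots=None, curves=None):
    if landscape is None:
        landscape, plots = load_landscape(outdir)
    if curves is None:
        raise FileNotFoundError(
            "prerequisite missing: conditional curves (run the metrics stage first)"
        )
    summaries = {}
    for variable in config.variables:
        cset = curves[variable]
        depths = {
            lu: curve_metrics(c, config.metrics.fraction).penetration_depth_m
            for lu, c in cset.items()
        }
        zone = map_edge_zone(landscape, plots, depths)
        deficit = biomass_deficit(
            zone,
            landscape,
            cset,
            variable=variable,
            deficit_mode=config.footprint.deficit_mode,
            potential_mode=config.footprint.potential_mode,
        )
        summary = summarize_footprint(zone, deficit, landscape, config.footprint.threshold)
        cio.write_ascii_grid(outdir / f"deficit_{variable}.asc", deficit.deficit, landscape)
        cio.write_ascii_grid(
            outdir / f"edge_zone_{variable}.asc", zone.affected.astype(float), landscape
        )
        summaries[variable] = summary.to_dict()
        summaries[variable]["penetration_depths_m"] = depths
    cio.write_json(summaries, outdir / "footprint_summary.json")
    return summaries


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all five stages; returns (and writes) the artifact manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "stages": {}, "status": "incomplete"}

    def record(stage):
        files = sorted(
            p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
        )
        manifest["stages"][stage] = {
            "outputs": {f: _sha256(outdir / f) for f in files}
        }

    state: dict = {}
    stages = [
        ("simulate", lambda: state.update(zip(("landscape", "plots"), stage_simulate(config, outdir)))),
        ("sample", lambda: state.update(points=stage_sample(config, outdir, state.get("landscape"), state.get("plots")))),
        ("fit", lambda: state.update(fits=stage_fit(config, outdir, state.get("points")))),
        ("metrics", lambda: state.update(curves=stage_metrics(config, outdir, state.get("fits")))),
        ("footprint", lambda: state.update(summaries=stage_footprint(config, outdir, state.get("landscape"), state.get("plots"), state.get("curves")))),
    ]
    try:
        for name, fn in stages:
            fn()
            record(name)
    except Exception as exc:
        manifest["status"] = f"failed at stage {name!r}: {exc}"
        cio.write_json(manifest, outdir / "manifest.json")
        raise PipelineError(name, exc) from exc
    manifest["status"] = "complete"
    cio.write_json(manifest, outdir / "manifest.json")
    return manifest
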