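"""On-disk formats: ESRI ASCII grid rasters, GeoJSON plot vectors, YAML, CSV.

Rasters use the plain-text ESRI ASCII grid format (readable by any GIS) with
nodata -9999 outside the forest; plots are GeoJSON FeatureCollections with
``plot_id``, ``year_cleared`` and ``land_use`` properties.  All writers are
deterministic (fixed float formatting) so byte-identical reruns hash equal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .landscape import DeforestationPlot, GridLandscape

NODATA = -9999.0


def write_ascii_grid(path, array: np.ndarray, landscape: GridLandscape, nodata: float = NODATA):
    """Write a raster co-registered with ``landscape`` as an ESRI ASCII grid."""
    arr = np.asarray(array, dtype=float)
    if arr.shape != landscape.shape:
        raise ValueError(f"array shape {arr.shape} != landscape grid {landscape.shape}")
    out = np.where(np.isfinite(arr), arr, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {landscape.n_cols}\n")
        fh.write(f"nrows {landscape.n_rows}\n")
        fh.write(f"xllcorner {landscape.origin[0]:.6f}\n")
        fh.write(f"yllcorner {landscape.origin[1]:.6f}\n")
        fh.write(f"cellsize {landscape.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:.1f}\n")
        for row in out[::-1]:  # ASCII grids store the northern row first
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (array, header dict).  Nodata -> NaN."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        k, v = line.split()
        header[k.lower()] = float(v)
    data = np.loadtxt(lines[6:])
    data = np.atleast_2d(data)[::-1]  # back to row 0 = south
    nodata = header.get("nodata_value", NODATA)
    data = np.where(data == nodata, np.nan, data)
    return data, header


def plots_to_geojson(plots: list[DeforestationPlot], path=None) -> dict:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(p.polygon),
                "properties": {
                    "plot_id": int(p.plot_id),
                    "year_cleared": int(p.year_cleared),
                    "land_use": p.land_use,
                },
            }
            for p in sorted(plots, key=lambda p: p.plot_id)
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(fc, sort_keys=True) + "\n")
    return fc


def plots_from_geojson(source) -> list[DeforestationPlot]:
    if isinstance(source, (str, Path)):
        fc = json.loads(Path(source).read_text())
    else:
        fc = source
    plots = []
    for feat in fc["features"]:
        props = feat["properties"]
        plots.append(
            DeforestationPlot(
                plot_id=int(props["plot_id"]),
                polygon=shape(feat["geometry"]),
                year_cleared=int(props["year_cleared"]),
                land_use=props["land_use"],
            )
        )
    return sorted(plots, key=lambda p: p.plot_id)


def write_points_csv(points: pd.DataFrame, path):
    points.to_csv(path, index=False, float_format="%.6f")


def write_yaml(obj: dict, path):
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_json(obj: dict, path):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
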