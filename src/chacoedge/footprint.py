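"""Degradation footprint: edge-affected area, per-cell deficit, regional totals.

Every forest cell is attributed to its single nearest deforestation plot (no
compounding of multiple edges).  A cell is *affected* when its distance to
that plot is below the penetration depth estimated for the plot's land use.
The per-cell relative deficit comes from the fitted conditional curve,
``r(d) = 1 - FS(d) / FS(2000)`` clipped to [0, 1]; the potential value of an
affected cell is the mean observed value over unaffected forest, so the
absolute loss per cell is ``potential * r(d) * cell_area``.  Cells with a
deficit of at least the threshold (default 10%) count as *degraded*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import LAND_USES
from .landscape import DeforestationPlot, GridLandscape
from .metrics import EdgeCurve
from .geometry import nearest_plot_arrays


@dataclass
class EdgeZoneRaster:
    """Per-forest-cell nearest-edge geometry and the affected flag."""

    distance: np.ndarray  # m to nearest plot; NaN off forest
    land_use_idx: np.ndarray  # index into LAND_USES; -1 off forest
    affected: np.ndarray  # bool; False off forest
    cell_size: float

    @property
    def n_affected(self) -> int:
        return int(self.affected.sum())


@dataclass
class DeficitRaster:
    """Relative deficit and absolute loss per cell for one variable."""

    variable: str
    deficit: np.ndarray  # relative reduction r(d) in [0, 1]; 0 where unaffected
    loss: np.ndarray  # potential * r * cell_area (variable units * ha)
    potential: float  # mean over unaffected forest cells (natural units)
    cell_area_ha: float


@dataclass
class FootprintSummary:
    variable: str
    affected_area_ha: float
    affected_fraction_pct: float
    degraded_area_ha: float
    degraded_fraction_pct: float
    total_loss: float  # variable units * ha (tons for agb)
    loss_fraction_pct: float  # of the regional observed total
    threshold: float

    def to_dict(self) -> dict:
        return {k: (float(v) if not isinstance(v, str) else v) for k, v in self.__dict__.items()}


def map_edge_zone(
    landscape: GridLandscape,
    plots: list[DeforestationPlot],
    depths_by_land_use: dict[str, float],
) -> EdgeZoneRaster:
    """Distance/land-use attribution of every forest cell plus the affected flag.

    ``depths_by_land_use`` must cover every land use present among the plots;
    a zero depth (e.g. silvopasture with no detectable edge effect) simply
    yields no affected zone for that use.
    """
    present = {p.land_use for p in plots}
    missing = sorted(present - set(depths_by_land_use))
    if missing:
        raise ValueError(f"no penetration depth supplied for land use(s): {missing}")
    plots = sorted(plots, key=lambda p: p.plot_id)
    rows, cols = np.nonzero(landscape.forest_mask)
    X, Y = landscape.cell_centers()
    idx, dist = nearest_plot_arrays(X[rows, cols], Y[rows, cols], plots)
    lc = np.array([LAND_USES.index(p.land_use) for p in plots])[idx]
    depth = np.array(
        [depths_by_land_use.get(lu, 0.0) for lu in LAND_USES], dtype=float
    )[lc]

    distance = np.full(landscape.shape, np.nan)
    land_use_idx = np.full(landscape.shape, -1, dtype=int)
    affected = np.zeros(landscape.shape, dtype=bool)
    distance[rows, cols] = dist
    land_use_idx[rows, cols] = lc
    affected[rows, cols] = dist < depth
    return EdgeZoneRaster(
        distance=distance,
        land_use_idx=land_use_idx,
        affected=affected,
        cell_size=landscape.cell_size,
    )


def biomass_deficit(
    zone: EdgeZoneRaster,
    landscape: GridLandscape,
    curves_by_land_use: dict[str, EdgeCurve],
    variable: str = "agb",
    deficit_mode: str = "model",
    potential_mode: str = "global",
) -> DeficitRaster:
    """Per-cell relative deficit and absolute loss for one structure variable.

    ``deficit_mode='model'`` (default) takes the relative reduction from the
    fitted curve at the cell's distance; ``'observed'`` uses the cell's
    observed shortfall against the potential value (sensitivity alternative).
    ``potential_mode='global'`` estimates potential as the mean observed value
    over unaffected forest cells.
    """
    if variable not in landscape.structure:
        raise ValueError(f"structure raster {variable!r} missing from landscape")
    if deficit_mode not in ("model", "observed"):
        raise ValueError(f"unknown deficit_mode {deficit_mode!r}")
    if potential_mode != "global":
        raise ValueError(f"unknown potential_mode {potential_mode!r}")
    obs = landscape.structure[variable]
    forest = landscape.forest_mask
    unaffected = forest & ~zone.affected
    if not unaffected.any():
        raise ValueError("no unaffected forest cells to estimate the potential value")
    potential = float(np.nanmean(obs[unaffected]))

    deficit = np.zeros(landscape.shape)
    rows, cols = np.nonzero(zone.affected)
    if rows.size:
        if deficit_mode == "model":
            lc = zone.land_use_idx[rows, cols]
            d = zone.distance[rows, cols]
            r = np.zeros(rows.size)
            for k, lu in enumerate(LAND_USES):
                sel = lc == k
                if not sel.any():
                    continue
                if lu not in curves_by_land_use:
                    raise ValueError(f"no conditional curve supplied for land use {lu!r}")
                curve = curves_by_land_use[lu]
                fs = np.interp(d[sel], curve.grid, curve.mean)
                r[sel] = 1.0 - fs / curve.reference_value
        else:
            r = 1.0 - obs[rows, cols] / potential
        deficit[rows, cols] = np.clip(r, 0.0, 1.0)

    cell_area_ha = landscape.cell_area_ha
    loss = potential * deficit * cell_area_ha
    return DeficitRaster(
        variable=variable,
        deficit=deficit,
        loss=loss,
        potential=potential,
        cell_area_ha=cell_area_ha,
    )


def summarize_footprint(
    zone: EdgeZoneRaster,
    deficit: DeficitRaster,
    landscape: GridLandscape,
    threshold: float = 0.10,
) -> FootprintSummary:
    """Regional totals: affected/degraded areas and the total structural loss.

    The loss fraction is the total loss divided by the total observed amount
    over the remaining forest (value * cell area), as a percentage.
    """
    forest = landscape.forest_mask
    cell_area_ha = landscape.cell_area_ha
    forest_area = float(forest.sum()) * cell_area_ha
    affected_area = float(zone.affected.sum()) * cell_area_ha
    degraded = zone.affected & (deficit.deficit >= threshold)
    degraded_area = float(degraded.sum()) * cell_area_ha
    total_loss = float(deficit.loss.sum())
    obs = landscape.structure[deficit.variable]
    total_observed = float(np.nansum(obs[forest])) * cell_area_ha
    return FootprintSummary(
        variable=deficit.variable,
        affected_area_ha=affected_area,
        affected_fraction_pct=100.0 * affected_area / forest_area if forest_area else 0.0,
        degraded_area_ha=degraded_area,
        degraded_fraction_pct=100.0 * degraded_area / forest_area if forest_area else 0.0,
        total_loss=total_loss,
        loss_fraction_pct=100.0 * total_loss / total_observed if total_observed else 0.0,
        threshold=threshold,
    )
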