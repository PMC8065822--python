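"""Point-density, kernel-density and species-richness surfaces.

Occurrence localities are turned into continuous surfaces three ways:

* ``point_density`` — for each grid cell, the number of localities within a
  fixed radius of the cell centre divided by the search-circle area
  (points/km^2), i.e. a moving-window count.
* ``kernel_density`` — a quartic (biweight) kernel density surface, the
  compact-support kernel standard in GIS density tools; mass-normalised so
  that the surface integrates to the total point weight (away from edges).
* ``richness_tessellation`` / ``richness_surface`` — species richness in a
  square tessellation (distinct species per cell), smoothed back to a
  continuous surface by richness-weighted kernel density of cell centres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geo import GridRaster, GridSpec, project
from .io import OccurrenceTable


@dataclass(frozen=True)
class RichnessCell:
    """Centre (km) and distinct-species count of one tessellation cell."""

    x_km: float
    y_km: float
    richness: int


def _as_xy(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of projected km")
    return pts


def point_density(points: np.ndarray, grid: GridSpec, radius_km: float) -> GridRaster:
    """Moving-circle point density in points/km^2.

    Each cell value is (number of points within ``radius_km`` of the cell
    centre) / (pi * radius_km^2).  An empty point set yields a zero raster.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be > 0")
    pts = _as_xy(points)
    X, Y = grid.cell_centres()
    counts = np.zeros(X.shape)
    area = np.pi * radius_km**2
    r2 = radius_km**2
    # chunk over points: memory O(cells) instead of O(cells * points)
    for i in range(0, len(pts), 256):
        chunk = pts[i : i + 256]
        d2 = (X[..., None] - chunk[:, 0]) ** 2 + (Y[..., None] - chunk[:, 1]) ** 2
        counts += (d2 <= r2).sum(axis=-1)
    return GridRaster(grid, counts / area)


def kernel_density(
    points: np.ndarray,
    grid: GridSpec,
    bandwidth_km: float = 50.0,
    weights: np.ndarray | None = None,
) -> GridRaster:
    """Quartic-kernel density surface.

    K(d) = 3/(pi h^2) (1 - d^2/h^2)^2 for d < h, zero beyond; the cell value
    is sum_i w_i K(d_i).  Each unit-weight point contributes unit mass
    (integral over the plane), so total surface mass approximates the total
    weight for points at least ``bandwidth_km`` from the grid edge.
    """
    if bandwidth_km <= 0:
        raise ValueError("bandwidth_km must be > 0")
    pts = _as_xy(points)
    if weights is None:
        w = np.ones(len(pts))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(pts),):
            raise ValueError("weights must match the number of points")
    X, Y = grid.cell_centres()
    dens = np.zeros(X.shape)
    h2 = bandwidth_km**2
    norm = 3.0 / (np.pi * h2)
    for i in range(0, len(pts), 256):
        chunk, cw = pts[i : i + 256], w[i : i + 256]
        d2 = (X[..., None] - chunk[:, 0]) ** 2 + (Y[..., None] - chunk[:, 1]) ** 2
        u = 1.0 - d2 / h2
        np.maximum(u, 0.0, out=u)
        dens += (u * u * cw).sum(axis=-1)
    return GridRaster(grid, norm * dens)


def richness_tessellation(
    table: OccurrenceTable, resolution_km: float, projection_tag: str = "cea"
) -> list[RichnessCell]:
    """Species richness in a square tessellation of the occupied plane.

    Cells are ``resolution_km`` squares anchored at the projected origin
    (half-open [k*res, (k+1)*res)); a cell's richness is the number of
    distinct species with at least one occurrence inside it.  Empty cells
    are omitted.
    """
    if resolution_km <= 0:
        raise ValueError("resolution_km must be > 0")
    cells: dict[tuple[int, int], set[str]] = {}
    if table.records:
        lon = np.array([r.location.lon for r in table.records])
        lat = np.array([r.location.lat for r in table.records])
        x, y = project(lon, lat, projection_tag)
        cols = np.floor(x / resolution_km).astype(int)
        rows = np.floor(y / resolution_km).astype(int)
        for rec, ci, ri in zip(table.records, cols, rows):
            cells.setdefault((int(ci), int(ri)), set()).add(rec.species)
    return [
        RichnessCell(
            x_km=(ci + 0.5) * resolution_km,
            y_km=(ri + 0.5) * resolution_km,
            richness=len(sp),
        )
        for (ci, ri), sp in sorted(cells.items())
    ]


def richness_surface(
    cells: list[RichnessCell], grid: GridSpec, bandwidth_km: float = 50.0
) -> GridRaster:
    """Continuous richness surface: kernel density of tessellation-cell
    centres weighted by their richness (surface mass ~ total richness)."""
    pts = np.array([[c.x_km, c.y_km] for c in cells]).reshape(-1, 2)
    w = np.array([c.richness for c in cells], dtype=float)
    return kernel_density(pts, grid, bandwidth_km, weights=w)


def richness_cells_to_csv(cells: list[RichnessCell], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "x_km": [c.x_km for c in cells],
            "y_km": [c.y_km for c in cells],
            "richness": [c.richness for c in cells],
        }
    ).to_csv(path, index=False)
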