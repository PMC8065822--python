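"""Coordinate, distance and grid primitives shared by every analysis stage.

All planar work happens on an equal-area projected grid in kilometres; all
"distance between localities" quantities are great-circle kilometres on a
sphere of radius 6371 km.  Keeping the two regimes explicit (``GeoPoint`` in
degrees vs. plain ``(x_km, y_km)`` tuples/arrays) avoids the classic GIS bug
of mixing them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0

#: projection tags accepted by :func:`project` / :func:`unproject`.
#: ``cea`` is the world (equator-centred) Lambert cylindrical equal-area
#: projection on the 6371-km sphere: x = R*lon_rad, y = R*sin(lat).
SUPPORTED_PROJECTIONS = ("cea",)


class ProjectionError(ValueError):
    """Raised for an unsupported projection tag."""


@dataclass(frozen=True)
class GeoPoint:
    """A longitude/latitude pair in decimal degrees (lon first)."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise ValueError("GeoPoint coordinates must be finite")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")


@dataclass(frozen=True)
class GridSpec:
    """A regular square grid in projected kilometres.

    Cells are half-open ``[edge, edge + cell_size)`` in both axes; row 0 sits
    at the minimum y.  Cell (row i, col j) has its centre at
    ``(x_min + (j + 0.5) * cell_size, y_min + (i + 0.5) * cell_size)``.
    """

    x_min: float
    y_min: float
    cell_size: float
    n_cols: int
    n_rows: int
    projection_tag: str = "cea"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size * self.cell_size

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of shape (n_rows, n_cols) of cell centres."""
        xs = self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_min + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map projected points to (row, col); third array flags in-grid points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_min) / self.cell_size).astype(int)
        row = np.floor((y - self.y_min) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return row, col, inside


@dataclass
class GridRaster:
    """A grid plus a value per cell; NaN marks nodata.

    Statistics over a raster must always go through :meth:`valid_values`
    (or an explicit mask) so nodata cells never leak into sums or means.
    """

    spec: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match spec "
                f"({self.spec.n_rows}, {self.spec.n_cols})"
            )

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def total_mass(self) -> float:
        """Sum of valid cell values times cell area (km^2)."""
        return float(np.nansum(self.values) * self.spec.cell_area_km2)


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in km between two points on the 6371-km sphere."""
    lon1, lat1, lon2, lat2 = map(math.radians, (a.lon, a.lat, b.lon, b.lat))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    s = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def haversine_km_arrays(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Vectorised haversine over degree arrays (broadcasting applies)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    s = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(s)))


def _check_tag(projection_tag: str) -> None:
    if projection_tag not in SUPPORTED_PROJECTIONS:
        raise ProjectionError(
            f"unsupported projection tag {projection_tag!r}; supported: {SUPPORTED_PROJECTIONS}"
        )


def project(
    lon: np.ndarray, lat: np.ndarray, projection_tag: str = "cea"
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat degrees to equal-area planar km.

    The cylindrical equal-area map is exactly area-preserving on the sphere,
    so densities per km^2 computed on the projected grid are true spherical
    densities.
    """
    _check_tag(projection_tag)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = EARTH_RADIUS_KM * np.radians(lon)
    y = EARTH_RADIUS_KM * np.sin(np.radians(lat))
    return x, y


def unproject(
    x: np.ndarray, y: np.ndarray, projection_tag: str = "cea"
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`project`; y values are clipped to the valid range."""
    _check_tag(projection_tag)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = np.degrees(x / EARTH_RADIUS_KM)
    lat = np.degrees(np.arcsin(np.clip(y / EARTH_RADIUS_KM, -1.0, 1.0)))
    return lon, lat


def project_points(points: list[GeoPoint], projection_tag: str = "cea") -> np.ndarray:
    """Project a list of GeoPoints to an (n, 2) array of km coordinates."""
    if not points:
        return np.empty((0, 2))
    lon = np.array([p.lon for p in points])
    lat = np.array([p.lat for p in points])
    x, y = project(lon, lat, projection_tag)
    return np.column_stack([x, y])


def make_grid(
    extent: tuple[float, float, float, float],
    cell_size: float,
    projection_tag: str = "cea",
) -> GridSpec:
    """Build the smallest grid of ``cell_size``-km cells covering ``extent``.

    ``extent`` is (x_min, y_min, x_max, y_max) in projected km.  The grid
    covers, never truncates: a 10.5-km span at cell size 1 gets 11 columns.
    """
    x_min, y_min, x_max, y_max = extent
    if not (x_max > x_min and y_max > y_min):
        raise ValueError("extent is degenerate")
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    if cell_size > (x_max - x_min) and cell_size > (y_max - y_min):
        raise ValueError("cell_size exceeds the extent in both axes")
    n_cols = int(math.ceil((x_max - x_min) / cell_size - 1e-12))
    n_rows = int(math.ceil((y_max - y_min) / cell_size - 1e-12))
    return GridSpec(x_min, y_min, cell_size, max(n_cols, 1), max(n_rows, 1), projection_tag)
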