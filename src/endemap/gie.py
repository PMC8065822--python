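"""Geographical Interpolation of Endemism (GIE).

GIE maps endemism without committing to a grid of fixed cells.  Each species
is reduced to the centroid of its occurrences plus an *area of influence* —
the great-circle distance from the centroid to its farthest occurrence.
Species are binned into endemism classes by that radius (narrow-range
classes first: up to 100 km, then up to 300 km).  Within a class, every
species contributes a compact kernel centred on its centroid and peaking at
exactly 1, so the summed surface reads directly as "number of endemic
species whose interpolated ranges overlap here".  Thresholding the surface
at >= 2 (synendemic) species and polygonizing the connected cells yields
areas of endemism; the per-class areas combine into a consensus map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely import unary_union
from shapely.geometry import MultiPolygon, Polygon, box

from .geo import (
    GeoPoint,
    GridRaster,
    GridSpec,
    haversine_km,
    haversine_km_arrays,
    project_points,
    unproject,
)
from .io import OccurrenceTable


@dataclass(frozen=True)
class SpeciesRange:
    species: str
    centroid: GeoPoint
    radius_km: float
    n_points: int

    def __post_init__(self) -> None:
        if self.radius_km < 0:
            raise ValueError("radius_km must be >= 0")


@dataclass(frozen=True)
class EndemismClassSpec:
    class_id: int
    max_radius_km: float
    bandwidth_km: float | None = None  # defaults to max_radius_km

    @property
    def h(self) -> float:
        return self.bandwidth_km if self.bandwidth_km is not None else self.max_radius_km


#: the two endemism classes used throughout: narrow-range (radius <= 100 km)
#: and medium-range (100 km < radius <= 300 km).
DEFAULT_CLASSES = (EndemismClassSpec(1, 100.0), EndemismClassSpec(2, 300.0))


@dataclass
class EndemismSurface:
    class_id: int
    raster: GridRaster
    ranges: list[SpeciesRange] = field(default_factory=list)
    bandwidth_km: float = 0.0


@dataclass
class AreaOfEndemism:
    class_id: int
    polygon: Polygon | MultiPolygon
    species: list[str]
    max_overlap: float


@dataclass
class AreasOfEndemism:
    class_id: int
    min_synendemic: int
    areas: list[AreaOfEndemism]


def species_range(points: list[GeoPoint], species: str) -> SpeciesRange:
    """Centroid (mean of equal-area projected coordinates, mapped back to
    lon/lat) and radius (max great-circle distance centroid -> occurrence)."""
    if not points:
        raise ValueError("species_range needs >= 1 point")
    xy = project_points(points)
    cx, cy = xy[:, 0].mean(), xy[:, 1].mean()
    lon, lat = unproject(cx, cy)
    centroid = GeoPoint(float(lon), float(lat))
    radius = max(haversine_km(centroid, p) for p in points)
    return SpeciesRange(species, centroid, radius, len(points))


def ranges_from_table(table: OccurrenceTable) -> list[SpeciesRange]:
    by_species: dict[str, list[GeoPoint]] = {}
    for rec in table.records:
        by_species.setdefault(rec.species, []).append(rec.location)
    return [species_range(pts, sp) for sp, pts in sorted(by_species.items())]


def classify_ranges(
    ranges: list[SpeciesRange],
    classes: tuple[EndemismClassSpec, ...] = DEFAULT_CLASSES,
    nested: bool = False,
) -> dict[int, list[SpeciesRange]]:
    """Assign each species to an endemism class by its radius.

    Default: disjoint intervals (0, b1], (b1, b2], ... — each species lands
    in the first class whose bound covers its radius; beyond the last bound
    the species is unassigned (key ``None`` omitted; non-endemic at these
    scales).  With ``nested`` a species joins every class whose bound covers
    its radius.
    """
    bounds = [c.max_radius_km for c in classes]
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("class bounds must be strictly increasing")
    out: dict[int, list[SpeciesRange]] = {c.class_id: [] for c in classes}
    for rng in ranges:
        for spec in classes:
            if rng.radius_km <= spec.max_radius_km:
                out[spec.class_id].append(rng)
                if not nested:
                    break
    return out


def gie_surface(
    ranges: list[SpeciesRange], grid: GridSpec, class_spec: EndemismClassSpec
) -> EndemismSurface:
    """Kernel-interpolated endemism surface for one class.

    Each species adds K(d) = (1 - d^2/h^2)^2 for d < h (peak-normalised
    quartic; d = great-circle km from cell centre to the species centroid,
    h = the class bandwidth).  The cell value is the number of overlapping
    species ranges, in species-equivalents.
    """
    h = class_spec.h
    X, Y = grid.cell_centres()
    lon, lat = unproject(X, Y, grid.projection_tag)
    total = np.zeros(X.shape)
    for rng in ranges:
        d = haversine_km_arrays(lon, lat, rng.centroid.lon, rng.centroid.lat)
        u = 1.0 - (d / h) ** 2
        np.maximum(u, 0.0, out=u)
        total += u * u
    return EndemismSurface(class_spec.class_id, GridRaster(grid, total), list(ranges), h)


def areas_of_endemism(surface: EndemismSurface, min_synendemic: int = 2) -> AreasOfEndemism:
    """Polygonized connected regions where >= ``min_synendemic`` species'
    kernels overlap.

    A cell qualifies when at least ``min_synendemic`` species' kernels are
    positive there — i.e. the cell lies inside that many areas of influence.
    (Thresholding the kernel *sum* instead would be knife-edged: with
    peak-normalised kernels the discretised sum of k coincident species
    approaches but never quite reaches k away from the exact centroid.)
    Qualifying cells are merged into 8-connected components, polygonized,
    and annotated with every species whose kernel is positive inside them.
    """
    grid = surface.raster.spec
    vals = surface.raster.values
    X, Ycent = grid.cell_centres()
    glon, glat = unproject(X, Ycent, grid.projection_tag)
    support_count = np.zeros(vals.shape, dtype=int)
    for rng in surface.ranges:
        d = haversine_km_arrays(glon, glat, rng.centroid.lon, rng.centroid.lat)
        support_count += d < surface.bandwidth_km
    mask = support_count >= min_synendemic
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    X, Y = grid.cell_centres()
    lon, lat = unproject(X, Y, grid.projection_tag)
    cs = grid.cell_size
    areas: list[AreaOfEndemism] = []
    for k in range(1, n_comp + 1):
        comp = labels == k
        rows, cols = np.nonzero(comp)
        cells = [
            box(grid.x_min + c * cs, grid.y_min + r * cs,
                grid.x_min + (c + 1) * cs, grid.y_min + (r + 1) * cs)
            for r, c in zip(rows, cols)
        ]
        poly = unary_union(cells)
        contributing = []
        clon, clat = lon[comp], lat[comp]
        for rng in surface.ranges:
            d = haversine_km_arrays(clon, clat, rng.centroid.lon, rng.centroid.lat)
            if (d < surface.bandwidth_km).any():
                contributing.append(rng.species)
        areas.append(
            AreaOfEndemism(surface.class_id, poly, sorted(contributing), float(vals[comp].max()))
        )
    return AreasOfEndemism(surface.class_id, min_synendemic, areas)


@dataclass
class ConsensusMap:
    """Union of per-class areas of endemism, labels intact."""

    layers: list[AreasOfEndemism]

    def all_areas(self) -> list[AreaOfEndemism]:
        return [a for layer in self.layers for a in layer.areas]

    def to_geojson(self, path) -> None:
        import json

        from shapely.geometry import mapping

        features = [
            {
                "type": "Feature",
                "properties": {
                    "class_id": a.class_id,
                    "species": a.species,
                    "max_overlap": a.max_overlap,
                },
                "geometry": mapping(a.polygon),
            }
            for a in self.all_areas()
        ]
        import pathlib

        pathlib.Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )


def consensus_map(layers: list[AreasOfEndemism]) -> ConsensusMap:
    """Combine class-level areas into one labelled layer set.  Overlapping
    or nested areas from different classes are both retained, each with its
    own class id and species list."""
    if not layers:
        raise ValueError("need >= 1 analysed class")
    return ConsensusMap(list(layers))
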