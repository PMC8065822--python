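"""Reading, validating and cleaning the pipeline's inputs and outputs.

Occurrence tables arrive as CSV (one row per locality), landscape patches as
GeoJSON polygons, rasters as ESRI ASCII grids (a plain-text format every GIS
reads).  Cleaning follows the usual museum/GBIF hygiene rules: drop rows with
missing mandatory fields, out-of-range coordinates, coordinate uncertainty
above a threshold, and exact (species, lon, lat) duplicates — and report
every drop, because downstream occupancy and endemism statistics are only as
good as the records that survive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, shape
from shapely.validation import make_valid

from .geo import GeoPoint, GridRaster, GridSpec

DEFAULT_COLUMN_MAP = {
    "taxon_group": "taxon_group",
    "species": "species",
    "lon": "lon",
    "lat": "lat",
    "precision_m": "precision_m",
    "source": "source",
}

#: default ceiling on coordinate uncertainty; records above it are dropped.
DEFAULT_MAX_UNCERTAINTY_M = 10_000.0


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


@dataclass(frozen=True)
class RawPoint:
    """An UNVALIDATED coordinate pair, for ingestion only.

    Parsed rows whose coordinates are numeric but out of range are carried
    as RawPoints so that :func:`clean_occurrences` can count them as
    invalid-coordinate drops instead of the loader discarding them silently.
    Retained records always end up with validated :class:`GeoPoint`s.
    """

    lon: float
    lat: float


@dataclass(frozen=True)
class OccurrenceRecord:
    taxon_group: str
    species: str
    location: GeoPoint | RawPoint
    precision_m: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.taxon_group or not self.species:
            raise ValueError("taxon_group and species must be non-empty")
        if self.precision_m is not None and self.precision_m <= 0:
            raise ValueError("precision_m must be positive when present")


@dataclass
class OccurrenceTable:
    records: list[OccurrenceRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def species_set(self) -> set[str]:
        return {r.species for r in self.records}

    def subset(self, taxon_group: str) -> "OccurrenceTable":
        return OccurrenceTable(
            [r for r in self.records if r.taxon_group == taxon_group],
            provenance=f"{self.provenance} [taxon_group={taxon_group}]",
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon_group": [r.taxon_group for r in self.records],
                "species": [r.species for r in self.records],
                "lon": [r.location.lon for r in self.records],
                "lat": [r.location.lat for r in self.records],
                "precision_m": [r.precision_m for r in self.records],
                "source": [r.source for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class PatchLayer:
    """Landscape polygons (an ecoregion-like mosaic) keyed by unique ids."""

    patches: list[tuple[str, str, Polygon | MultiPolygon]]

    def __post_init__(self) -> None:
        ids = [pid for pid, _, _ in self.patches]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise FormatError(f"duplicated patch ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def patch_ids(self) -> list[str]:
        return [pid for pid, _, _ in self.patches]


@dataclass
class CleaningReport:
    n_input: int = 0
    n_retained: int = 0
    n_dropped_duplicate: int = 0
    n_dropped_missing: int = 0
    n_dropped_invalid_coord: int = 0
    n_dropped_low_precision: int = 0

    def __post_init__(self) -> None:
        total = (
            self.n_retained
            + self.n_dropped_duplicate
            + self.n_dropped_missing
            + self.n_dropped_invalid_coord
            + self.n_dropped_low_precision
        )
        if total != self.n_input:
            raise ValueError("CleaningReport counts do not reconcile")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def _parse_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    return out if math.isfinite(out) else None


def load_occurrences(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    taxon_group: str | None = None,
) -> tuple[OccurrenceTable, list[dict]]:
    """Load an occurrence CSV.

    Returns the table plus a list of parse failures (row index and reason);
    unparseable rows are never silently dropped.  ``column_map`` maps the
    logical field names to the file's column headers.  ``taxon_group`` fills
    the group label when the file has no such column.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path)
    mandatory = ["species", "lon", "lat"]
    missing = [cmap[k] for k in mandatory if cmap[k] not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory columns: {missing}")

    records: list[OccurrenceRecord] = []
    failures: list[dict] = []
    has_group = cmap["taxon_group"] in df.columns
    has_prec = cmap["precision_m"] in df.columns
    has_src = cmap["source"] in df.columns
    for idx, row in df.iterrows():
        species = row[cmap["species"]]
        lon = _parse_float(row[cmap["lon"]])
        lat = _parse_float(row[cmap["lat"]])
        if not isinstance(species, str) or not species:
            failures.append({"row": int(idx), "reason": "missing species"})
            continue
        if lon is None or lat is None:
            failures.append({"row": int(idx), "reason": "unparseable coordinate"})
            continue
        group = row[cmap["taxon_group"]] if has_group else taxon_group
        if not isinstance(group, str) or not group:
            group = taxon_group or "unknown"
        try:
            loc: GeoPoint | RawPoint = GeoPoint(lon, lat)
        except ValueError:
            # numeric but out of range: carry raw for the cleaner to count
            loc = RawPoint(lon, lat)
        prec = _parse_float(row[cmap["precision_m"]]) if has_prec else None
        src = row[cmap["source"]] if has_src and isinstance(row[cmap["source"]], str) else None
        records.append(OccurrenceRecord(str(group), str(species), loc, prec, src))
    return OccurrenceTable(records, provenance=str(path)), failures


def clean_occurrences(
    table: OccurrenceTable,
    max_uncertainty_m: float = DEFAULT_MAX_UNCERTAINTY_M,
    round_decimals: int | None = None,
    exclude_species: set[str] | None = None,
) -> tuple[OccurrenceTable, CleaningReport]:
    """Apply the record-hygiene rules and return (cleaned table, report).

    Rules, in order per record: mandatory fields present; coordinates finite
    and in range (guaranteed by GeoPoint but re-checked for safety);
    precision_m <= max_uncertainty_m when precision is known (records with
    unknown precision are retained); exact (species, lon, lat) duplicates
    collapse to their first record.  ``round_decimals`` optionally rounds
    coordinates before the duplicate test (default off).  ``exclude_species``
    honours an external doubtful-record list.  Cleaning never raises; it
    reports.
    """
    exclude = exclude_species or set()
    retained: list[OccurrenceRecord] = []
    seen: set[tuple[str, float, float]] = set()
    n_dup = n_missing = n_invalid = n_lowprec = 0
    for rec in table.records:
        if not rec.taxon_group or not rec.species or rec.species in exclude:
            n_missing += 1
            continue
        lon, lat = rec.location.lon, rec.location.lat
        if not (math.isfinite(lon) and math.isfinite(lat) and -180 <= lon <= 180 and -90 <= lat <= 90):
            n_invalid += 1
            continue
        if isinstance(rec.location, RawPoint):  # in range after all: validate
            rec = OccurrenceRecord(rec.taxon_group, rec.species, GeoPoint(lon, lat),
                                   rec.precision_m, rec.source)
        if rec.precision_m is not None and rec.precision_m > max_uncertainty_m:
            n_lowprec += 1
            continue
        key_lon, key_lat = (
            (round(lon, round_decimals), round(lat, round_decimals))
            if round_decimals is not None
            else (lon, lat)
        )
        key = (rec.species, key_lon, key_lat)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        retained.append(rec)
    report = CleaningReport(
        n_input=len(table.records),
        n_retained=len(retained),
        n_dropped_duplicate=n_dup,
        n_dropped_missing=n_missing,
        n_dropped_invalid_coord=n_invalid,
        n_dropped_low_precision=n_lowprec,
    )
    return OccurrenceTable(retained, provenance=table.provenance + " [cleaned]"), report


def load_patches(path: str | Path) -> PatchLayer:
    """Load a GeoJSON FeatureCollection of (multi)polygons as a PatchLayer.

    Each feature needs an ``id`` (feature id or an ``id``/``patch_id``
    property) and optionally a ``name`` property.  Invalid geometries are
    repaired via make_valid; features that cannot be repaired to polygonal
    geometry are rejected with their id named.
    """
    try:
        gj = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read GeoJSON {path}: {exc}") from exc
    feats = gj.get("features")
    if feats is None:
        raise FormatError("not a GeoJSON FeatureCollection")
    patches = []
    for k, feat in enumerate(feats):
        props = feat.get("properties") or {}
        pid = feat.get("id", props.get("id", props.get("patch_id")))
        if pid is None:
            raise FormatError(f"feature {k} has no id property")
        name = str(props.get("name", pid))
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            geom = make_valid(geom)
        if geom.geom_type == "GeometryCollection":
            polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
            geom = MultiPolygon(
                [p for g in polys for p in (g.geoms if g.geom_type == "MultiPolygon" else [g])]
            )
        if geom.is_empty or geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise FormatError(f"feature {pid!r} is not polygonal after repair")
        patches.append((str(pid), name, geom))
    return PatchLayer(patches)


def write_patches(layer: PatchLayer, path: str | Path) -> None:
    """Write a PatchLayer as GeoJSON (RFC 7946 FeatureCollection)."""
    from shapely.geometry import mapping

    features = [
        {
            "type": "Feature",
            "id": pid,
            "properties": {"id": pid, "name": name},
            "geometry": mapping(geom),
        }
        for pid, name, geom in layer.patches
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


# ---------------------------------------------------------------------------
# rasters: ESRI ASCII grid

_NODATA = -9999.0


def write_ascii_grid(raster: GridRaster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid with full float64 precision.

    Values are printed with %.17g, which round-trips IEEE doubles exactly, so
    write-then-read is bit-exact despite the text encoding.
    """
    spec = raster.spec
    vals = np.where(raster.nodata_mask, _NODATA, raster.values)
    lines = [
        f"ncols {spec.n_cols}",
        f"nrows {spec.n_rows}",
        f"xllcorner {spec.x_min!r}",
        f"yllcorner {spec.y_min!r}",
        f"cellsize {spec.cell_size!r}",
        f"NODATA_value {_NODATA!r}",
    ]
    # ESRI convention: first data row is the TOP of the grid (max y).
    for i in range(spec.n_rows - 1, -1, -1):
        lines.append(" ".join(f"{v:.17g}" for v in vals[i]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ascii_grid(path: str | Path, projection_tag: str = "cea") -> GridRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    text = Path(path).read_text().strip().splitlines()
    header: dict[str, float] = {}
    data_start = 0
    for k, line in enumerate(text):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            data_start = k + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"ASCII grid missing header field {key}")
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", _NODATA)
    rows = [np.array(line.split(), dtype=float) for line in text[data_start:]]
    if len(rows) != n_rows or any(len(r) != n_cols for r in rows):
        raise FormatError("ASCII grid data block does not match header dimensions")
    values = np.flipud(np.vstack(rows))  # back to row 0 = min y
    values[values == nodata] = np.nan
    spec = GridSpec(
        header["xllcorner"], header["yllcorner"], header["cellsize"],
        n_cols, n_rows, projection_tag,
    )
    return GridRaster(spec, values)


def raster_roundtrip(raster: GridRaster, path: str | Path, format: str = "ascii") -> GridRaster:
    """Write then re-read a raster; returns the re-read raster."""
    if format != "ascii":
        raise FormatError(f"unknown raster format {format!r}; supported: 'ascii'")
    write_ascii_grid(raster, path)
    return read_ascii_grid(path, projection_tag=raster.spec.projection_tag)
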