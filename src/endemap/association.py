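"""Insect-plant association analyses.

Four complementary views of whether two taxa share geography and climate:

* :func:`raster_pearson` — Pearson correlation between two density rasters
  over their jointly valid cells (the band-statistics view of spatial
  co-occurrence).
* :func:`climate_profile` — per-taxon means of the 19 bioclim variables
  (BIO1..BIO19) sampled at the taxon's occurrence localities.
* :func:`euclidean_matrix` + :func:`wpgma` — hierarchical clustering of the
  bioclim profiles (Euclidean distance, WPGMA/McQuitty linkage): taxa whose
  climate envelopes resemble each other merge first.
* :func:`hyperoverlap_detect` — SVM-based niche-overlap detection: two
  occurrence clouds in bioclim space overlap iff neither a linear nor a
  polynomial decision boundary separates them perfectly; the misclassified
  fraction quantifies the depth of overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .geo import GridRaster
from .io import OccurrenceTable

BIOCLIM_NAMES = tuple(f"BIO{i}" for i in range(1, 20))

#: bioclim variables retained for niche-overlap detection (annual mean
#: temperature, temperature annual range, precipitation of the driest month,
#: precipitation of the warmest quarter).
OVERLAP_VARIABLES = ("BIO1", "BIO7", "BIO14", "BIO18")

_DATA_DIR = Path(__file__).parent / "data"


class RasterMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationReport:
    raster_a: str
    raster_b: str
    r: float
    n_cells: int


@dataclass
class ClimateProfile:
    taxon: str
    means: dict[str, float]
    n_excluded: dict[str, int] | None = None

    def __post_init__(self) -> None:
        missing = [v for v in BIOCLIM_NAMES if v not in self.means]
        if missing:
            raise ValueError(f"profile for {self.taxon} missing variables: {missing}")
        bad = [v for v in BIOCLIM_NAMES if not np.isfinite(self.means[v])]
        if bad:
            raise ValueError(f"profile for {self.taxon} has non-finite means: {bad}")

    def vector(self) -> np.ndarray:
        return np.array([self.means[v] for v in BIOCLIM_NAMES])


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` is an ordered list of (cluster_a, cluster_b, height) with
    clusters named by the sorted tuple of their leaves; heights are the raw
    inter-cluster distances at merge time, so the cophenetic distance of two
    leaves is the height of their lowest common merge.
    """

    leaves: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    def __post_init__(self) -> None:
        if len(self.merges) != max(len(self.leaves) - 1, 0):
            raise ValueError("a dendrogram on n leaves needs n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths (leaf depth =
        half the root height, the standard dendrogram rendering)."""
        node: dict[tuple[str, ...], tuple[str, float]] = {
            (leaf,): (leaf, 0.0) for leaf in self.leaves
        }
        for a, b, h in self.merges:
            (sa, ha), (sb, hb) = node[a], node[b]
            half = h / 2.0
            merged = tuple(sorted(a + b))
            node[merged] = (f"({sa}:{half - ha:g},{sb}:{half - hb:g})", half)
        root = tuple(sorted(self.leaves))
        return node[root][0] + ";" if self.merges else f"({self.leaves[0]}:0);"


@dataclass(frozen=True)
class OverlapReport:
    pair: tuple[str, str]
    overlap: bool
    boundary_shape: str  # "linear" | "polynomial"
    n_misclassified: int
    misclassified_percent: float
    n_support_vectors: int


def raster_pearson(a: GridRaster, b: GridRaster, name_a: str = "a", name_b: str = "b") -> CorrelationReport:
    """Pearson r between two rasters over cells valid in both."""
    if a.spec != b.spec:
        raise RasterMismatchError("rasters have different grid specs")
    valid = ~(a.nodata_mask | b.nodata_mask)
    va, vb = a.values[valid], b.values[valid]
    if va.size < 2:
        raise ValueError("need >= 2 jointly valid cells")
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("correlation undefined: a band has zero variance")
    r = float(np.corrcoef(va, vb)[0, 1])
    return CorrelationReport(name_a, name_b, r, int(va.size))


def climate_profile(
    table: OccurrenceTable, rasters: dict[str, GridRaster], taxon: str | None = None
) -> ClimateProfile:
    """Mean of each climate raster over the table's occurrence localities.

    Rasters must share one grid spec; localities are projected onto it.
    Localities falling on nodata are excluded per variable and counted in
    ``n_excluded``; localities off the grid entirely are excluded everywhere.
    """
    missing = [v for v in BIOCLIM_NAMES if v not in rasters]
    if missing:
        raise ValueError(f"missing rasters: {missing}")
    specs = {id(r.spec): r.spec for r in rasters.values()}
    first = next(iter(rasters.values())).spec
    if any(s != first for s in specs.values()):
        raise RasterMismatchError("climate rasters have differing grid specs")
    from .geo import project

    lon = np.array([r.location.lon for r in table.records])
    lat = np.array([r.location.lat for r in table.records])
    x, y = project(lon, lat, first.projection_tag)
    row, col, inside = first.cell_index(x, y)
    if not inside.any():
        raise ValueError("all occurrences fall outside the climate grid")
    means: dict[str, float] = {}
    excluded: dict[str, int] = {}
    for name in BIOCLIM_NAMES:
        vals = rasters[name].values[row[inside], col[inside]]
        ok = np.isfinite(vals)
        excluded[name] = int((~ok).sum() + (~inside).sum())
        if not ok.any():
            raise ValueError(f"no valid cells under occurrences for {name}")
        means[name] = float(vals[ok].mean())
    label = taxon or (table.records[0].taxon_group if table.records else "unknown")
    return ClimateProfile(label, means, excluded)


def kernel_overlap_points(
    table: OccurrenceTable,
    rasters: dict[str, GridRaster],
    variables: tuple[str, ...] = OVERLAP_VARIABLES,
) -> np.ndarray:
    """Attribute vectors for overlap detection: the selected climate
    variables sampled at each occurrence (rows with any nodata dropped)."""
    from .geo import project

    first = rasters[variables[0]].spec
    lon = np.array([r.location.lon for r in table.records])
    lat = np.array([r.location.lat for r in table.records])
    x, y = project(lon, lat, first.projection_tag)
    row, col, inside = first.cell_index(x, y)
    cols = []
    for v in variables:
        vals = np.full(len(table.records), np.nan)
        vals[inside] = rasters[v].values[row[inside], col[inside]]
        cols.append(vals)
    mat = np.column_stack(cols)
    return mat[np.isfinite(mat).all(axis=1)]


def reference_profiles(path: str | Path | None = None) -> list[ClimateProfile]:
    """Published per-taxon bioclim means for the Afrotropical flea-beetle
    genera (Afroblepharida, Blepharidina, Calotheca) and their candidate
    host-plant genera (Searsia, Commiphora), shipped with the package."""
    csv = Path(path) if path else _DATA_DIR / "bioclim_means_afrotropical.csv"
    df = pd.read_csv(csv, index_col=0)
    return [
        ClimateProfile(taxon, {v: float(df.loc[v, taxon]) for v in BIOCLIM_NAMES})
        for taxon in df.columns
    ]


def euclidean_matrix(
    profiles: list[ClimateProfile], standardize: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Pairwise Euclidean distances between bioclim profiles.

    With ``standardize`` each variable is z-scored across the profiles first
    (zero-variance variables contribute 0).  Default off: raw Table-style
    values, where large-scale variables (e.g. annual precipitation) dominate.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    labels = [p.taxon for p in profiles]
    mat = np.vstack([p.vector() for p in profiles])
    if standardize:
        sd = mat.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        mat = (mat - mat.mean(axis=0)) / sd
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(mat, metric="euclidean")), labels


def wpgma(dist: np.ndarray, labels: list[str]) -> Dendrogram:
    """WPGMA (McQuitty) agglomerative clustering.

    Repeatedly merge the closest pair of clusters at height equal to their
    current distance; the merged cluster's distance to any other cluster is
    the plain average (d1 + d2)/2 of its two members' distances, regardless
    of cluster sizes.  Ties broken lexicographically on cluster labels.
    """
    d = np.asarray(dist, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    clusters: dict[tuple[str, ...], dict[tuple[str, ...], float]] = {}
    keys = [(lab,) for lab in labels]
    for i, ki in enumerate(keys):
        clusters[ki] = {kj: float(d[i, j]) for j, kj in enumerate(keys) if j != i}
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b, dab in sorted(clusters[a].items()):
                if a < b and (best is None or dab < best[0] - 1e-15 or
                              (abs(dab - best[0]) <= 1e-15 and (a, b) < (best[1], best[2]))):
                    best = (dab, a, b)
        h, a, b = best
        merged = tuple(sorted(a + b))
        new_row: dict[tuple[str, ...], float] = {}
        for c in clusters:
            if c in (a, b):
                continue
            new_row[c] = (clusters[a][c] + clusters[b][c]) / 2.0
        del clusters[a], clusters[b]
        for c in clusters:
            clusters[c].pop(a, None)
            clusters[c].pop(b, None)
            clusters[c][merged] = new_row[c]
        clusters[merged] = new_row
        merges.append((a, b, h))
    return Dendrogram(list(labels), merges)


def _standardized(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pooled = np.vstack([xa, xb])
    mu, sd = pooled.mean(axis=0), pooled.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return np.vstack([(xa - mu) / sd, (xb - mu) / sd]), np.concatenate(
        [np.zeros(len(xa)), np.ones(len(xb))]
    )


def hyperoverlap_detect(
    points_a: np.ndarray,
    points_b: np.ndarray,
    pair: tuple[str, str] = ("A", "B"),
    degree: int = 3,
    C: float = 1e3,
    max_iter: int = 100_000,
) -> OverlapReport:
    """SVM niche-overlap detection between two attribute-point clouds.

    Stage 1 fits a near-hard-margin linear SVM; if it classifies every point
    correctly the niches are divergent with a linear boundary.  Stage 2
    retries with a polynomial kernel (default degree 3); perfect separation
    there still counts as divergence.  Any residual misclassification means
    the clouds interpenetrate: ``overlap=True`` with the polynomial stage's
    error count.  Features are pooled-z-scored before fitting.
    """
    xa = np.atleast_2d(np.asarray(points_a, dtype=float))
    xb = np.atleast_2d(np.asarray(points_b, dtype=float))
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need >= 2 points per group")
    if not (np.isfinite(xa).all() and np.isfinite(xb).all()):
        raise ValueError("attributes must be finite")
    X, y = _standardized(xa, xb)
    n = len(y)

    def _fit(kernel: str) -> tuple[int, int]:
        # the iteration cap keeps near-hard-margin fits on deeply
        # interpenetrating clouds from spinning; separable inputs converge
        # far below it, so divergence verdicts are unaffected.
        clf = SVC(kernel=kernel, C=C, degree=degree, coef0=1.0, gamma="scale",
                  max_iter=max_iter)
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X, y)
        mis = int((clf.predict(X) != y).sum())
        return mis, int(clf.n_support_.sum())

    mis_lin, sv_lin = _fit("linear")
    if mis_lin == 0:
        return OverlapReport(pair, False, "linear", 0, 0.0, sv_lin)
    mis_poly, sv_poly = _fit("poly")
    if mis_poly == 0:
        return OverlapReport(pair, False, "polynomial", 0, 0.0, sv_poly)
    return OverlapReport(pair, True, "polynomial", mis_poly, 100.0 * mis_poly / n, sv_poly)
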