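"""Species-by-patch occupancy and the corrected Habitat Specificity index.

Given cleaned occurrences and a mosaic of landscape patches (ecoregions),
the binary incidence matrix records which species occupy which patches.
The corrected Habitat Specificity of patch j is

    S_j = sum over the m_j species present in patch j of 1 / n_i

where n_i is the number of patches species i occupies in the whole
landscape.  The area term of the original index is deliberately absent
(the patches are ecological, not standardised, units), which buys the index
an exact conservation law: the patch scores sum to the retained species
count, since each species spreads a total weight of exactly 1 over its n_i
patches.  A patch scores high when many of its species occur almost nowhere
else — it is a per-patch measure of endemism pressure, not of raw richness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from shapely import STRtree
from shapely.geometry import Point

from .geo import GeoPoint
from .io import OccurrenceTable, PatchLayer


class OverlappingPatchesError(ValueError):
    """Patches must be disjoint (shared boundaries allowed)."""


@dataclass
class OccupancyMatrix:
    species_ids: list[str]
    patch_ids: list[str]
    incidence: np.ndarray  # binary, species x patch

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=int)
        if self.incidence.shape != (len(self.species_ids), len(self.patch_ids)):
            raise ValueError("incidence shape does not match labels")
        if np.any((self.incidence != 0) & (self.incidence != 1)):
            raise ValueError("incidence must be binary")
        if len(self.species_ids) and np.any(self.incidence.sum(axis=1) < 1):
            raise ValueError("every retained species must occupy >= 1 patch")

    @property
    def n_i(self) -> np.ndarray:
        """Per-species count of occupied patches (row sums)."""
        return self.incidence.sum(axis=1)

    @property
    def m_j(self) -> np.ndarray:
        """Per-patch count of present species (column sums)."""
        return self.incidence.sum(axis=0)


@dataclass
class SpecificityScores:
    patch_ids: list[str]
    s: dict[str, float] = field(default_factory=dict)
    occurrence_percent: dict[str, float] = field(default_factory=dict)
    m_j: dict[str, int] = field(default_factory=dict)

    def to_csv(self, path, layer: PatchLayer | None = None) -> None:
        import pandas as pd

        names = {pid: name for pid, name, _ in layer.patches} if layer else {}
        pd.DataFrame(
            {
                "patch_id": self.patch_ids,
                "patch_name": [names.get(p, p) for p in self.patch_ids],
                "S": [self.s[p] for p in self.patch_ids],
                "occurrence_percent": [self.occurrence_percent[p] for p in self.patch_ids],
                "m_j": [self.m_j[p] for p in self.patch_ids],
            }
        ).to_csv(path, index=False)


def _check_disjoint(patches: PatchLayer) -> None:
    geoms = [g for _, _, g in patches.patches]
    tree = STRtree(geoms)
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            if j <= i:
                continue
            inter = g.intersection(geoms[int(j)])
            if inter.area > 1e-9 * min(g.area, geoms[int(j)].area):
                a, b = patches.patches[i][0], patches.patches[int(j)][0]
                raise OverlappingPatchesError(f"patches {a!r} and {b!r} overlap")


def assign_patch(point: GeoPoint, patches: PatchLayer, tree: STRtree | None = None) -> str | None:
    """Patch id covering the point, or None.

    A point exactly on a shared boundary is assigned to the covering patch
    with the lexicographically smallest id (deterministic tie-break).
    """
    p = Point(point.lon, point.lat)
    geoms = [g for _, _, g in patches.patches]
    if tree is None:
        tree = STRtree(geoms)
    hits = [int(k) for k in tree.query(p, predicate="covered_by")]
    if not hits:
        return None
    return min(patches.patches[k][0] for k in hits)


def build_occupancy(
    table: OccurrenceTable, patches: PatchLayer
) -> tuple[OccupancyMatrix, int, dict[str, str | None]]:
    """Point-in-polygon incidence of species over patches.

    Returns (matrix, n_unassigned, per-record patch assignment keyed by
    ``"{species}|{lon}|{lat}"``).  Species with every occurrence outside all
    patches are dropped from the matrix (they have no n_i).  Overlapping
    patches raise :class:`OverlappingPatchesError`.
    """
    _check_disjoint(patches)
    geoms = [g for _, _, g in patches.patches]
    tree = STRtree(geoms)
    patch_ids = patches.patch_ids
    col = {pid: k for k, pid in enumerate(patch_ids)}
    occupied: dict[str, set[str]] = {}
    assignment: dict[str, str | None] = {}
    unassigned = 0
    for rec in table.records:
        pid = assign_patch(rec.location, patches, tree)
        assignment[f"{rec.species}|{rec.location.lon}|{rec.location.lat}"] = pid
        if pid is None:
            unassigned += 1
        else:
            occupied.setdefault(rec.species, set()).add(pid)
    species_ids = sorted(occupied)
    incidence = np.zeros((len(species_ids), len(patch_ids)), dtype=int)
    for i, sp in enumerate(species_ids):
        for pid in occupied[sp]:
            incidence[i, col[pid]] = 1
    return OccupancyMatrix(species_ids, patch_ids, incidence), unassigned, assignment


def specificity_from_incidence(occ: OccupancyMatrix) -> dict[str, float]:
    """S_j per patch from the incidence matrix alone (exact rational sum)."""
    n_i = occ.n_i
    scores: dict[str, float] = {}
    for j, pid in enumerate(occ.patch_ids):
        total = Fraction(0)
        for i in np.nonzero(occ.incidence[:, j])[0]:
            total += Fraction(1, int(n_i[i]))
        scores[pid] = float(total)
    return scores


def specificity_scores(
    occ: OccupancyMatrix,
    table: OccurrenceTable,
    patches: PatchLayer | None = None,
    assignment: dict[str, str | None] | None = None,
) -> SpecificityScores:
    """Per-patch Habitat Specificity plus occurrence-locality percentages.

    ``occurrence_percent_j`` = 100 * (localities falling in patch j) /
    (total localities in the table); localities outside every patch count in
    the denominator only, so the percentages sum to <= 100.
    """
    s = specificity_from_incidence(occ)
    counts = {pid: 0 for pid in occ.patch_ids}
    total = len(table.records)
    if total:
        if assignment is None:
            if patches is None:
                raise ValueError("need either `patches` or a precomputed `assignment`")
            geoms = [g for _, _, g in patches.patches]
            tree = STRtree(geoms)
            for rec in table.records:
                pid = assign_patch(rec.location, patches, tree)
                if pid in counts:
                    counts[pid] += 1
        else:
            for rec in table.records:
                pid = assignment.get(f"{rec.species}|{rec.location.lon}|{rec.location.lat}")
                if pid in counts:
                    counts[pid] += 1
    pct = {pid: (100.0 * c / total if total else 0.0) for pid, c in counts.items()}
    m = {pid: int(occ.m_j[j]) for j, pid in enumerate(occ.patch_ids)}
    return SpecificityScores(list(occ.patch_ids), s, pct, m)
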