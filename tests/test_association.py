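"""Raster correlation, climate profiles, WPGMA clustering, SVM overlap."""

import numpy as np
import pytest

from endemap.association import (
    BIOCLIM_NAMES,
    ClimateProfile,
    RasterMismatchError,
    climate_profile,
    euclidean_matrix,
    hyperoverlap_detect,
    raster_pearson,
    reference_profiles,
    wpgma,
)
from endemap.geo import GeoPoint, GridRaster, GridSpec, unproject
from endemap.io import OccurrenceRecord, OccurrenceTable


def raster(values, spec=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    spec = spec or GridSpec(0, 0, 1.0, values.shape[1], values.shape[0])
    return GridRaster(spec, values)


class TestRasterPearson:
    def test_self_correlation(self, rng):
        a = raster(rng.normal(size=(6, 7)))
        assert raster_pearson(a, a).r == pytest.approx(1.0)

    def test_anticorrelation(self, rng):
        a = raster(rng.normal(size=(6, 7)))
        b = raster(5.0 - a.values, a.spec)
        assert raster_pearson(a, b).r == pytest.approx(-1.0)

    def test_hand_computed_three_cells(self):
        a = raster([[1.0, 2.0, 3.0]])
        b = raster([[6.0, 5.0, 1.0]])
        assert raster_pearson(a, b).r == pytest.approx(-5 / np.sqrt(28), rel=1e-12)

    def test_symmetry_and_affine_invariance(self, rng):
        a = raster(rng.normal(size=(5, 5)))
        b = raster(rng.normal(size=(5, 5)), a.spec)
        r1 = raster_pearson(a, b).r
        assert raster_pearson(b, a).r == pytest.approx(r1)
        scaled = raster(3.0 * b.values + 7.0, a.spec)
        assert raster_pearson(a, scaled).r == pytest.approx(r1)

    def test_joint_nodata_handling(self, rng):
        vals_a = rng.normal(size=(4, 4))
        vals_b = rng.normal(size=(4, 4))
        va, vb = vals_a.copy(), vals_b.copy()
        va[0, 0] = np.nan
        vb[3, 3] = np.nan
        rep = raster_pearson(raster(va), raster(vb, GridSpec(0, 0, 1.0, 4, 4)))
        keep = np.ones((4, 4), bool)
        keep[0, 0] = keep[3, 3] = False
        expected = np.corrcoef(vals_a[keep], vals_b[keep])[0, 1]
        assert rep.r == pytest.approx(expected)
        assert rep.n_cells == 14

    def test_spec_mismatch_and_zero_variance(self, rng):
        a = raster(rng.normal(size=(3, 3)))
        with pytest.raises(RasterMismatchError):
            raster_pearson(a, raster(rng.normal(size=(4, 4))))
        with pytest.raises(ValueError):
            raster_pearson(a, raster(np.ones((3, 3)), a.spec))


def _occ_table(points_km):
    lon, lat = unproject(np.array([p[0] for p in points_km]),
                         np.array([p[1] for p in points_km]))
    return OccurrenceTable(
        [OccurrenceRecord("t", f"sp{k}", GeoPoint(float(lo), float(la)))
         for k, (lo, la) in enumerate(zip(lon, lat))]
    )


class TestClimateProfile:
    def _rasters(self, values_fn, spec):
        return {name: GridRaster(spec, values_fn(name)) for name in BIOCLIM_NAMES}

    def test_constant_raster(self):
        spec = GridSpec(0, 0, 10.0, 20, 20)
        rasters = self._rasters(lambda n: np.full((20, 20), 7.5), spec)
        prof = climate_profile(_occ_table([(5, 5), (55, 125), (199, 3)]), rasters, taxon="t")
        assert all(v == 7.5 for v in prof.means.values())

    def test_two_point_mean(self):
        spec = GridSpec(0, 0, 10.0, 4, 1)
        vals = np.array([[10.0, 20.0, 30.0, 40.0]])
        rasters = self._rasters(lambda n: vals, spec)
        prof = climate_profile(_occ_table([(5, 5), (15, 5)]), rasters)
        assert all(v == 15.0 for v in prof.means.values())

    def test_gradient_matches_per_point_lookup(self, rng):
        spec = GridSpec(0, 0, 5.0, 40, 40)
        X, Y = spec.cell_centres()
        grad = 0.3 * X - 0.1 * Y
        rasters = self._rasters(lambda n: grad, spec)
        pts = [(float(x), float(y)) for x, y in rng.uniform(1, 199, (100, 2))]
        prof = climate_profile(_occ_table(pts), rasters)
        row, col, inside = spec.cell_index(np.array([p[0] for p in pts]),
                                           np.array([p[1] for p in pts]))
        assert inside.all()
        assert prof.means["BIO1"] == pytest.approx(grad[row, col].mean())

    def test_all_points_off_grid(self):
        spec = GridSpec(0, 0, 1.0, 2, 2)
        rasters = self._rasters(lambda n: np.ones((2, 2)), spec)
        with pytest.raises(ValueError):
            climate_profile(_occ_table([(500, 500)]), rasters)


def profile(taxon, vec):
    return ClimateProfile(taxon, dict(zip(BIOCLIM_NAMES, vec)))


class TestEuclideanMatrix:
    def test_identical_profiles(self):
        p = profile("a", np.arange(19.0))
        d, _ = euclidean_matrix([p, profile("b", np.arange(19.0))])
        assert d[0, 1] == 0.0

    def test_published_means_worked_distance(self):
        """Unstandardized distance between the Calotheca and Searsia bioclim
        mean profiles, cross-checked by explicit summation of the 19
        squared differences."""
        profs = {p.taxon: p for p in reference_profiles()}
        d, labels = euclidean_matrix(list(profs.values()))
        i, j = labels.index("Calotheca"), labels.index("Searsia")
        ssq = sum(
            (profs["Calotheca"].means[v] - profs["Searsia"].means[v]) ** 2
            for v in BIOCLIM_NAMES
        )
        assert d[i, j] == pytest.approx(np.sqrt(ssq), rel=1e-12)
        assert d[i, j] == pytest.approx(77.8, abs=0.05)

    def test_insect_host_pair_attains_minimum(self):
        """Of all 10 taxon pairs, the Calotheca-Searsia pair is climatically
        closest — the beetle sits nearest its putative host plant."""
        d, labels = euclidean_matrix(reference_profiles())
        off = [(d[i, j], frozenset((labels[i], labels[j])))
               for i in range(5) for j in range(i + 1, 5)]
        assert min(off)[1] == frozenset(("Calotheca", "Searsia"))

    def test_standardization_flag(self):
        d_raw, labels = euclidean_matrix(reference_profiles(), standardize=False)
        d_std, _ = euclidean_matrix(reference_profiles(), standardize=True)
        assert not np.allclose(d_raw, d_std)
        assert np.allclose(d_std, d_std.T) and (np.diag(d_std) == 0).all()


def reference_wpgma(d, labels):
    """Independent O(n^3) WPGMA on a condensed matrix with explicit index
    bookkeeping — a different data structure and scan order from the
    implementation under test."""
    import itertools

    active = {k: (labels[k],) for k in range(len(labels))}
    dist = {frozenset((i, j)): float(d[i, j])
            for i, j in itertools.combinations(range(len(labels)), 2)}
    merges = []
    nxt = len(labels)
    while len(active) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((active[min(kv[0])], active[max(kv[0])])))),
        )
        (i, j), h = sorted(best[0]), best[1]
        a, b = sorted((active[i], active[j]))
        merges.append((a, b, h))
        new = tuple(sorted(active[i] + active[j]))
        for k in list(active):
            if k in (i, j):
                continue
            dist[frozenset((nxt, k))] = (
                dist.pop(frozenset((i, k))) + dist.pop(frozenset((j, k)))
            ) / 2.0
        dist.pop(frozenset((i, j)))
        del active[i], active[j]
        active[nxt] = new
        nxt += 1
    return merges


class TestWPGMA:
    def test_two_leaves(self):
        tree = wpgma(np.array([[0.0, 3.5], [3.5, 0.0]]), ["a", "b"])
        assert tree.merges == [(("a",), ("b",), 3.5)]

    def test_hand_traced_three_leaves(self):
        d = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 6.0], [4.0, 6.0, 0.0]])
        tree = wpgma(d, ["A", "B", "C"])
        assert tree.merges[0] == (("A",), ("B",), 2.0)
        assert tree.merges[1][2] == pytest.approx(5.0)  # (4 + 6) / 2

    def test_matches_independent_reference(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 9))
            m = rng.uniform(1, 100, (n, n))
            d = np.triu(m, 1) + np.triu(m, 1).T
            labels = [f"L{k}" for k in range(n)]
            got = wpgma(d, labels).merges
            want = reference_wpgma(d, labels)
            assert [(a, b, pytest.approx(h)) for a, b, h in want] == got

    def test_matches_scipy_weighted_linkage_heights(self, rng):
        """Cross-check merge heights against scipy's 'weighted' (McQuitty)
        linkage on the condensed matrix."""
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        for _ in range(20):
            n = int(rng.integers(4, 9))
            m = rng.uniform(1, 100, (n, n))
            d = np.triu(m, 1) + np.triu(m, 1).T
            ours = [h for _, _, h in wpgma(d, [f"L{k}" for k in range(n)]).merges]
            scipys = linkage(squareform(d), method="weighted")[:, 2]
            assert np.allclose(sorted(ours), sorted(scipys))

    def test_heights_non_decreasing(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 9))
            m = rng.uniform(0, 10, (n, n))
            d = np.triu(m, 1) + np.triu(m, 1).T
            h = [x for _, _, x in wpgma(d, [f"L{k}" for k in range(n)]).merges]
            assert all(b >= a - 1e-9 for a, b in zip(h, h[1:]))

    def test_newick_export(self):
        d = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 6.0], [4.0, 6.0, 0.0]])
        nwk = wpgma(d, ["A", "B", "C"]).to_newick()
        assert nwk.endswith(";") and "A" in nwk and "(" in nwk
        # ultrametric: leaf depths all equal root height / 2
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(nwk), "newick")
        depths = tree.depths()
        leaf_depths = [v for c, v in depths.items() if c.name]
        assert np.allclose(leaf_depths, 2.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wpgma(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])
        with pytest.raises(ValueError):
            wpgma(np.array([[0.0, -1.0], [-1.0, 0.0]]), ["a", "b"])


class TestHyperoverlapDetect:
    def test_separable_clouds(self):
        rep = hyperoverlap_detect(np.array([[0, 0], [0, 1]]), np.array([[5, 5], [5, 6]]))
        assert (rep.overlap, rep.boundary_shape, rep.n_misclassified) == (False, "linear", 0)

    def test_identical_point_sets(self, rng):
        pts = rng.normal(size=(20, 4))
        rep = hyperoverlap_detect(pts, pts.copy())
        assert rep.overlap is True
        assert rep.misclassified_percent >= 50.0

    def test_xor_needs_polynomial(self):
        a = np.array([[0.0, 0.0], [1.0, 1.0]])
        b = np.array([[0.0, 1.0], [1.0, 0.0]])
        rep = hyperoverlap_detect(a, b)
        assert (rep.overlap, rep.boundary_shape) == (False, "polynomial")

    def test_label_symmetry(self, rng):
        a = rng.normal(0, 1, (15, 4))
        b = rng.normal(0.5, 1, (15, 4))
        r1 = hyperoverlap_detect(a, b, pair=("A", "B"))
        r2 = hyperoverlap_detect(b, a, pair=("B", "A"))
        assert (r1.overlap, r1.boundary_shape, r1.n_misclassified) == (
            r2.overlap, r2.boundary_shape, r2.n_misclassified)

    def test_degenerate_duplicated_point_not_fatal(self):
        a = np.tile([[1.0, 1.0]], (3, 1))
        b = np.array([[4.0, 4.0], [4.0, 5.0]])
        rep = hyperoverlap_detect(a, b)
        assert rep.overlap is False

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            hyperoverlap_detect(np.array([[0.0, 0.0]]), np.array([[1.0, 1.0], [2.0, 2.0]]))
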