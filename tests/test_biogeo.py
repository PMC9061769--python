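"""Transforms, dissimilarities, PCoA, Mantel, BH correction, distance decay."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from amdvir.biogeo import (
    DistanceMatrix,
    bh_adjust,
    correlation_matrix_bh,
    ddr_fit,
    dissimilarity,
    geographic_distance,
    mantel_test,
    pcoa,
    transform,
)


class TestTransforms:
    def test_hellinger_row(self):
        df = pd.DataFrame([[1.0, 3.0]])
        out = transform(df, "hellinger")
        assert out.iloc[0].tolist() == pytest.approx([0.5, np.sqrt(0.75)], abs=1e-4)

    def test_hellinger_one_hot(self):
        df = pd.DataFrame([[0.0, 5.0, 0.0]])
        out = transform(df, "hellinger")
        assert out.iloc[0].tolist() == [0.0, 1.0, 0.0]

    def test_hellinger_zero_row(self):
        out = transform(pd.DataFrame([[0.0, 0.0], [1.0, 1.0]]), "hellinger")
        assert out.iloc[0].tolist() == [0.0, 0.0]

    def test_standardize_constant_column(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        out = transform(df, "standardize")
        assert out["a"].tolist() == [0.0, 0.0, 0.0]
        assert out["b"].mean() == pytest.approx(0.0)
        assert out["b"].std(ddof=1) == pytest.approx(1.0)


class TestDissimilarity:
    def test_identical_rows_zero(self):
        d = dissimilarity(pd.DataFrame([[1.0, 2.0], [1.0, 2.0]]))
        assert d.values[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = dissimilarity(pd.DataFrame([[2.0, 0.0], [0.0, 2.0]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_worked_value(self):
        d = dissimilarity(pd.DataFrame([[1.0, 2.0], [2.0, 1.0]]))
        assert d.values[0, 1] == pytest.approx(1 / 3)

    def test_range_and_diagonal(self, rng):
        X = pd.DataFrame(rng.lognormal(0, 1, (6, 10)))
        d = dissimilarity(X)
        assert (d.values >= 0).all() and (d.values <= 1 + 1e-12).all()
        assert np.allclose(np.diag(d.values), 0)

    def test_all_zero_pair_warns(self, caplog):
        X = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]])
        with caplog.at_level("WARNING"):
            d = dissimilarity(X)
        assert d.values[0, 1] == 0.0


class TestGeographicDistance:
    def test_one_degree_latitude(self):
        coords = pd.DataFrame({"lat": [0.0, 1.0], "lon": [0.0, 0.0]}, index=["a", "b"])
        d = geographic_distance(coords)
        assert d.values[0, 1] == pytest.approx(111.19, abs=0.01)

    def test_identical_points(self):
        coords = pd.DataFrame({"lat": [5.0, 5.0], "lon": [7.0, 7.0]}, index=["a", "b"])
        assert geographic_distance(coords).values[0, 1] == 0.0

    def test_invalid_coordinates(self):
        coords = pd.DataFrame({"lat": [95.0], "lon": [0.0]}, index=["a"])
        with pytest.raises(ValueError):
            geographic_distance(coords)


class TestPcoa:
    def test_collinear_points(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        D = np.abs(pts - pts.T)
        d = DistanceMatrix(["a", "b", "c"], D)
        coords, evals = pcoa(d)
        pc1 = coords["PC1"].to_numpy()
        rec = np.abs(pc1[:, None] - pc1[None, :])
        assert np.allclose(rec, D, atol=1e-8)
        assert evals[1] == pytest.approx(0.0, abs=1e-8)

    def test_euclidean_reconstruction(self, rng):
        X = rng.normal(0, 1, (8, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        d = DistanceMatrix([f"s{i}" for i in range(8)], D)
        coords, evals = pcoa(d)
        C = coords.to_numpy()
        rec = np.sqrt(((C[:, None] - C[None]) ** 2).sum(-1))
        assert np.allclose(rec, D, atol=1e-8)

    def test_all_zero_distances(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        coords, _ = pcoa(d)
        assert coords.shape[1] == 0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


def random_distance(rng, n):
    pts = rng.normal(0, 1, (n, 2))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix([f"s{i}" for i in range(n)], D)


class TestMantel:
    def test_identity_maximal(self, rng):
        d = random_distance(rng, 10)
        r, p = mantel_test(d, d, n_perm=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_affine_invariance(self, rng):
        d1 = random_distance(rng, 8)
        d2 = random_distance(rng, 8)
        d2b = DistanceMatrix(d2.labels, d2.values * 3.5)
        r1, _ = mantel_test(d1, d2, n_perm=99, seed=1)
        r2, _ = mantel_test(d1, d2b, n_perm=99, seed=1)
        assert r1 == pytest.approx(r2)

    def test_matches_reference_implementation(self, rng):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM, mantel

        d1 = random_distance(rng, 12)
        d2 = random_distance(rng, 12)
        r, _ = mantel_test(d1, d2, n_perm=99, seed=0)
        r_ref, _, _ = mantel(
            SkDM(d1.values, ids=d1.labels), SkDM(d2.values, ids=d2.labels),
            permutations=0,
        )
        assert r == pytest.approx(float(r_ref), abs=1e-10)

    def test_label_mismatch(self, rng):
        d1 = random_distance(rng, 5)
        d2 = random_distance(rng, 5)
        d2.labels = ["x"] * 5
        with pytest.raises(ValueError):
            mantel_test(d1, d2)


class TestCorrelationBh:
    def test_bh_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_test_unchanged(self):
        assert bh_adjust([0.031])[0] == pytest.approx(0.031)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(0, 1, 30)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_perfect_linear_relation(self, rng):
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": rng.normal(0, 1, 50)})
        r, p, q = correlation_matrix_bh(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert q.loc["x", "y"] <= p.loc["x", "y"] * 3 + 1e-12

    def test_zero_variance_flagged(self, rng):
        df = pd.DataFrame({"x": np.ones(10), "y": rng.normal(0, 1, 10)})
        r, p, q = correlation_matrix_bh(df)
        assert np.isnan(r.loc["x", "y"])


class TestDdr:
    def geo(self, dists_km, labels):
        n = len(labels)
        D = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        D[iu] = dists_km
        D = D + D.T
        return DistanceMatrix(labels, D)

    def test_exact_linear_input(self, rng):
        """Similarity constructed as 0.9 - 0.10 log10(km) is recovered."""
        n = 8
        labels = [f"s{i}" for i in range(n)]
        iu = np.triu_indices(n, 1)
        D = np.zeros((n, n))
        D[iu] = rng.uniform(1.0, 1000.0, len(iu[0]))
        D = D + D.T
        geo = DistanceMatrix(labels, D)
        logd = np.log10(np.where(D > 0, D, 1.0))
        sim = 0.9 - 0.10 * logd
        comm = DistanceMatrix(labels, np.where(np.eye(n) > 0, 0.0, 1 - sim))
        fit = ddr_fit(geo, comm)
        assert fit.overall_slope == pytest.approx(-0.10, abs=1e-9)

    def test_two_regime_breakpoint(self):
        """Pairs below and above 1 km recover their own planted slopes."""
        n = 10
        labels = [f"s{i}" for i in range(n)]
        rng = np.random.default_rng(0)
        iu = np.triu_indices(n, 1)
        d = np.concatenate(
            [rng.uniform(0.3, 1.0, 20), rng.uniform(2, 100, len(iu[0]) - 20)]
        )
        D = np.zeros((n, n))
        D[iu] = d
        D = D + D.T
        geo = DistanceMatrix(labels, D)
        logd = np.log10(np.where(D > 0, D, 1.0))
        sim = np.where(D <= 1.0, 0.7 - 0.20 * logd, 0.6 - 0.05 * logd)
        comm = DistanceMatrix(labels, np.where(np.eye(n) > 0, 0.0, 1 - sim))
        fit = ddr_fit(geo, comm)
        assert fit.local_slope == pytest.approx(-0.20, abs=1e-9)
        assert fit.regional_slope == pytest.approx(-0.05, abs=1e-9)

    def test_shuffled_similarity_flat(self, rng):
        n = 15
        pts = rng.uniform(0, 5, (n, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)) * 100
        labels = [f"s{i}" for i in range(n)]
        geo = DistanceMatrix(labels, D)
        vals = rng.uniform(0.2, 0.8, (n, n))
        sym = (vals + vals.T) / 2
        np.fill_diagonal(sym, 0.0)
        comm = DistanceMatrix(labels, sym)
        fit = ddr_fit(geo, comm)
        # slope statistically indistinguishable from zero
        assert fit.p_values["overall"] > 0.001
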