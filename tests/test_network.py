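"""Bipartite network metrics: Barber modularity (BRIM), NODF, nulls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from amdvir.network import (
    BipartiteNetwork,
    barber_modularity_brim,
    barber_q,
    build_network,
    extract_subnetwork,
    nodf,
    permutation_null,
    richness_structure_regression,
)
from amdvir.records import VirusHostLink


def link(v, h):
    return VirusHostLink(v, h, frozenset({"homology"}), 1)


def net_from(A):
    A = np.asarray(A)
    return BipartiteNetwork(
        [f"v{i}" for i in range(A.shape[0])],
        [f"h{j}" for j in range(A.shape[1])],
        A,
    )


def exhaustive_q(A):
    """Oracle: max Barber Q over all set partitions of the smaller side;
    the other side's optimal assignment is independent per node."""
    A = np.asarray(A, dtype=float)
    r, c = A.shape
    if r > c:
        return exhaustive_q(A.T)
    m = A.sum()
    B = A - A.sum(1, keepdims=True) @ A.sum(0, keepdims=True) / m

    def partitions(items):
        if len(items) == 1:
            yield [items]
            return
        first = items[0]
        for smaller in partitions(items[1:]):
            for n, subset in enumerate(smaller):
                yield smaller[:n] + [[first] + subset] + smaller[n + 1 :]
            yield [[first]] + smaller

    best = -np.inf
    for part in partitions(list(range(r))):
        R = np.zeros((r, len(part)))
        for mod, nodes in enumerate(part):
            for n_ in nodes:
                R[n_, mod] = 1
        q = (B.T @ R).max(axis=1).clip(min=0).sum() / m
        best = max(best, q)
    return best


class TestBuildExtract:
    def test_build_collapses_duplicates(self):
        links = [link("v1", "h1"), link("v1", "h2"), link("v2", "h1"), link("v2", "h1")]
        net = build_network(links)
        assert net.incidence.sum() == 3
        assert net.virus_nodes == ["v1", "v2"]

    def test_extract_identity(self):
        net = net_from([[1, 0], [1, 1]])
        sub = extract_subnetwork(net, net.virus_nodes, net.host_nodes)
        assert np.array_equal(sub.incidence, net.incidence)

    def test_extract_drops_column(self):
        net = net_from([[1, 1], [1, 0]])
        sub = extract_subnetwork(net, ["v0", "v1"], ["h0"])
        assert sub.incidence.shape == (2, 1)
        assert sub.incidence.sum() == 2

    def test_unknown_node_raises(self):
        net = net_from([[1]])
        with pytest.raises(ValueError, match="unknown"):
            extract_subnetwork(net, ["nope"], [])


class TestBarberModularity:
    def test_two_disconnected_edges(self):
        q = barber_modularity_brim(net_from([[1, 0], [0, 1]]), seed=0).q
        assert q == pytest.approx(0.5)

    def test_complete_bipartite_zero(self):
        q = barber_modularity_brim(net_from(np.ones((2, 2), dtype=int)), seed=0).q
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_single_edge_zero(self):
        q = barber_modularity_brim(net_from([[1]]), seed=0).q
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_zero_edge_refused(self):
        with pytest.raises(ValueError, match="zero-edge"):
            barber_modularity_brim(net_from([[0]]), seed=0)

    def test_q_matches_stored_partition(self, rng):
        for _ in range(20):
            A = (rng.random((4, 5)) < 0.4).astype(int)
            if A.sum() == 0:
                continue
            net = net_from(A)
            res = barber_modularity_brim(net, seed=3)
            Aact, vn, hn = net.active_matrix()
            g = np.array([res.virus_module[v] for v in vn])
            h = np.array([res.host_module[x] for x in hn])
            assert res.q == pytest.approx(barber_q(Aact.astype(float), g, h))

    def test_permutation_invariance(self, rng):
        A = (rng.random((5, 5)) < 0.4).astype(int)
        A[0, 0] = 1
        q1 = barber_modularity_brim(net_from(A), seed=5).q
        perm = rng.permutation(5)
        q2 = barber_modularity_brim(net_from(A[perm][:, perm]), seed=5).q
        assert q1 == pytest.approx(q2)

    def test_restart_monotonicity(self, rng):
        A = (rng.random((6, 6)) < 0.35).astype(int)
        A[0, 0] = 1
        net = net_from(A)
        qs = [barber_modularity_brim(net, n_restarts=n, seed=9).q for n in (2, 5, 20)]
        assert qs == sorted(qs)


class TestNodf:
    def test_staircase_fully_nested(self):
        assert nodf(np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])).nodf == pytest.approx(100.0)

    def test_identity_not_nested(self):
        assert nodf(np.eye(3, dtype=int)).nodf == pytest.approx(0.0)

    def test_two_by_two(self):
        assert nodf(np.array([[1, 1], [1, 0]])).nodf == pytest.approx(100.0)

    def test_transpose_invariance(self, rng):
        for _ in range(10):
            A = (rng.random((5, 7)) < 0.4).astype(int)
            if A.sum() == 0 or min(A.shape) < 2:
                continue
            assert nodf(A).nodf == pytest.approx(nodf(A.T).nodf)

    def test_permutation_invariance(self, rng):
        A = (rng.random((6, 6)) < 0.5).astype(int)
        A[0] = 1
        v1 = nodf(A).nodf
        p, q = rng.permutation(6), rng.permutation(6)
        assert nodf(A[p][:, q]).nodf == pytest.approx(v1)

    def test_degenerate_refused(self):
        with pytest.raises(ValueError):
            nodf(np.array([[1]]))


class TestBrimOracle:
    def test_brim_equals_exhaustive_on_small_graphs(self, rng):
        """BRIM's best Q equals the exhaustive-search optimum on random
        bipartite graphs with <= 10 nodes."""
        checked = 0
        trial = 0
        while checked < 120:
            trial += 1
            r = rng.integers(2, 6)
            c = rng.integers(2, 11 - r)
            A = (rng.random((r, c)) < rng.uniform(0.2, 0.7)).astype(int)
            A = A[A.sum(1) > 0][:, A.sum(0) > 0]
            if A.size == 0 or A.sum() == 0:
                continue
            checked += 1
            res = barber_modularity_brim(net_from(A), n_restarts=20, seed=trial)
            assert res.q == pytest.approx(exhaustive_q(A), abs=1e-9), A


class TestPermutationNull:
    def test_p_bounds(self, rng):
        A = (rng.random((4, 4)) < 0.5).astype(int)
        A[0, 0] = 1
        out = permutation_null(net_from(A), metric="nodf", n_perm=99, seed=1)
        assert 1 / 100 <= out["p"] <= 1.0

    def test_nested_staircase_significant(self):
        A = np.tril(np.ones((5, 5), dtype=int))
        out = permutation_null(net_from(A), metric="nodf", n_perm=1000, seed=2)
        assert out["p"] <= 0.01

    def test_invalid_n_perm(self):
        with pytest.raises(ValueError):
            permutation_null(net_from([[1]]), n_perm=0)

    def test_degree_preserving_keeps_margins(self, rng):
        from amdvir.network import _null_matrix

        A = (rng.random((6, 8)) < 0.4).astype(np.int8)
        A[0, 0] = 1
        B = _null_matrix(A, "degree-preserving", rng)
        assert np.array_equal(A.sum(0), B.sum(0))
        assert np.array_equal(A.sum(1), B.sum(1))


class TestRichnessRegression:
    def test_exact_linear_metric(self):
        rich = pd.DataFrame({"prok": [1.0, 2.0, 3.0, 4.0]})
        mets = pd.DataFrame({"modularity": [2.0, 4.0, 6.0, 8.0]})
        out = richness_structure_regression(mets, rich)
        row = out.iloc[0]
        assert row["slope"] == pytest.approx(2.0)
        assert row["adjusted_r2"] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        rich = pd.DataFrame({"prok": [1.0, 1.0, 1.0]})
        mets = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        out = richness_structure_regression(mets, rich)
        assert np.isnan(out.iloc[0]["slope"])
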