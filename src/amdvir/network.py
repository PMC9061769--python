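"""Bipartite virus-host network structure.

The meta-network has one node per viral population and per host population
and a binary incidence matrix from the population-level links. Per-sample
sub-networks preserve the populations present in a sample. Structure is
quantified by Barber's bipartite modularity Q (maximized with the BRIM
alternating heuristic plus module merging) and by NODF nestedness
(overlap and decreasing fill), each with permutation null models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from amdvir.records import VirusHostLink


@dataclass
class BipartiteNetwork:
    virus_nodes: list[str]
    host_nodes: list[str]
    incidence: np.ndarray  # viruses x hosts, binary

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence)
        if self.incidence.shape != (len(self.virus_nodes), len(self.host_nodes)):
            raise ValueError("incidence shape mismatch")
        if not np.isin(self.incidence, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")
        if len(set(self.virus_nodes)) != len(self.virus_nodes) or len(
            set(self.host_nodes)
        ) != len(self.host_nodes):
            raise ValueError("duplicate node ids")

    @property
    def n_edges(self) -> int:
        return int(self.incidence.sum())

    def active_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Incidence with isolated (all-zero) rows/columns dropped."""
        rows = self.incidence.sum(axis=1) > 0
        cols = self.incidence.sum(axis=0) > 0
        return (
            self.incidence[np.ix_(rows, cols)],
            [v for v, k in zip(self.virus_nodes, rows) if k],
            [h for h, k in zip(self.host_nodes, cols) if k],
        )


@dataclass
class ModularityResult:
    q: float
    virus_module: dict[str, int]
    host_module: dict[str, int]
    n_restarts: int
    seed: int


@dataclass
class NestednessResult:
    nodf: float
    row_component: float
    col_component: float
    null_p: float | None = None
    n_permutations: int = 0


def build_network(links: Sequence[VirusHostLink]) -> BipartiteNetwork:
    """Binary incidence from population-level links; duplicate links collapse."""
    viruses = sorted({l.virus_population for l in links})
    hosts = sorted({l.host_population for l in links})
    vi = {v: i for i, v in enumerate(viruses)}
    hi = {h: i for i, h in enumerate(hosts)}
    A = np.zeros((len(viruses), len(hosts)), dtype=np.int8)
    for l in links:
        A[vi[l.virus_population], hi[l.host_population]] = 1
    return BipartiteNetwork(viruses, hosts, A)


def extract_subnetwork(
    meta: BipartiteNetwork,
    present_viruses: Iterable[str],
    present_hosts: Iterable[str],
) -> BipartiteNetwork:
    """Induced sub-network on the populations present in a sample.

    Nodes isolated in the sub-network stay in the node lists; the metric
    computations drop them via :meth:`BipartiteNetwork.active_matrix`.
    """
    pv, ph = sorted(set(present_viruses)), sorted(set(present_hosts))
    unknown = (set(pv) - set(meta.virus_nodes)) | (set(ph) - set(meta.host_nodes))
    if unknown:
        raise ValueError(f"unknown node id(s): {sorted(unknown)[:5]}")
    ri = [meta.virus_nodes.index(v) for v in pv]
    ci = [meta.host_nodes.index(h) for h in ph]
    return BipartiteNetwork(pv, ph, meta.incidence[np.ix_(ri, ci)])


# ---------------------------------------------------------------------------
# Barber modularity / BRIM


def barber_q(A: np.ndarray, g: np.ndarray, h: np.ndarray) -> float:
    """Barber's bipartite modularity of a joint module assignment."""
    m = A.sum()
    if m == 0:
        raise ValueError("modularity undefined on a zero-edge network")
    k = A.sum(axis=1, keepdims=True)
    d = A.sum(axis=0, keepdims=True)
    B = A - k @ d / m
    K = int(max(g.max(), h.max())) + 1
    R = np.zeros((len(g), K))
    R[np.arange(len(g)), g] = 1
    T = np.zeros((len(h), K))
    T[np.arange(len(h)), h] = 1
    return float(np.trace(R.T @ B @ T) / m)


def _brim_once(B: np.ndarray, m: float, h: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Alternate row/column label optimization until Q stops improving."""
    r, c = B.shape
    T = np.zeros((c, K))
    T[np.arange(c), h] = 1
    q_prev = -np.inf
    g = np.zeros(r, dtype=int)
    while True:
        g = np.argmax(B @ T, axis=1)
        R = np.zeros((r, K))
        R[np.arange(r), g] = 1
        h = np.argmax(B.T @ R, axis=1)
        T = np.zeros((c, K))
        T[np.arange(c), h] = 1
        q = float(np.trace(R.T @ B @ T) / m)
        if q <= q_prev + 1e-12:  # alternation is monotone; stop at a fixed point
            return g, h, q
        q_prev = q


def _merge_modules(B: np.ndarray, m: float, g: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Greedy module merging: accept any pairwise merge that increases Q."""
    while True:
        labels = sorted(set(g) | set(h))
        K = len(labels)
        relabel = {old: new for new, old in enumerate(labels)}
        g = np.array([relabel[x] for x in g])
        h = np.array([relabel[x] for x in h])
        R = np.zeros((len(g), K))
        R[np.arange(len(g)), g] = 1
        T = np.zeros((len(h), K))
        T[np.arange(len(h)), h] = 1
        M = R.T @ B @ T / m  # module-pair contributions
        best_gain, best_pair = 0.0, None
        for a in range(K):
            for b in range(a + 1, K):
                gain = M[a, b] + M[b, a]
                if gain > best_gain + 1e-12:
                    best_gain, best_pair = gain, (a, b)
        if best_pair is None:
            q = float(np.trace(M))
            return g, h, q
        a, b = best_pair
        g = np.where(g == b, a, g)
        h = np.where(h == b, a, h)


def barber_modularity_brim(
    net: BipartiteNetwork,
    n_restarts: int = 20,
    seed: int = 0,
) -> ModularityResult:
    """Maximize Barber's bipartite modularity with restarted BRIM.

    Each restart starts from a random column labelling with up to
    min(rows, cols) modules, alternates row/column label optimization to
    convergence, then greedily merges modules while Q increases and
    re-runs the alternation. Two deterministic starts (all columns
    together; every column its own module) are always included. The best
    partition over all starts is returned; results are deterministic for a
    given seed.
    """
    A, vnames, hnames = net.active_matrix()
    m = A.sum()
    if m == 0:
        raise ValueError("modularity undefined on a zero-edge network")
    r, c = A.shape
    K = max(1, min(r, c))
    k = A.sum(axis=1, keepdims=True)
    d = A.sum(axis=0, keepdims=True)
    B = A - k @ d / m
    rng = np.random.default_rng(seed)
    K_big = max(r, c)
    starts: list[tuple[np.ndarray, int]] = [
        (np.zeros(c, dtype=int), K),
        (np.arange(c) % K, K),
        (np.arange(c), K_big),
    ]
    for i in range(n_restarts):
        Ki = K if i % 2 == 0 else K_big
        starts.append((rng.integers(0, Ki, size=c), Ki))
    best = (-np.inf, None, None)
    for h0, Ki in starts:
        g, h, q = _brim_once(B, m, h0.astype(int), Ki)
        while True:
            g, h, q_m = _merge_modules(B, m, g, h)
            K_eff = int(max(g.max(), h.max())) + 1
            g2, h2, q2 = _brim_once(B, m, h, K_eff)
            if q2 <= q_m + 1e-12:
                q = q_m
                break
            g, h, q = g2, h2, q2
        if q > best[0]:
            best = (q, g.copy(), h.copy())
    q, g, h = best
    return ModularityResult(
        q=q,
        virus_module={v: int(x) for v, x in zip(vnames, g)},
        host_module={hn: int(x) for hn, x in zip(hnames, h)},
        n_restarts=n_restarts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# NODF nestedness


def _nodf_axis(M: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap percentages over all row pairs, and pair count."""
    totals = M.sum(axis=1)
    n = M.shape[0]
    acc = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            ti, tj = totals[i], totals[j]
            if ti == tj:
                continue
            rich, poor = (i, j) if ti > tj else (j, i)
            pt = totals[poor]
            if pt == 0:
                continue
            overlap = np.sum(M[rich] * M[poor])
            acc += 100.0 * overlap / pt
    return acc, pairs


def nodf(net: BipartiteNetwork | np.ndarray) -> NestednessResult:
    """NODF nestedness (0-100): mean paired overlap over all row pairs and
    column pairs with strictly decreasing marginal totals (equal totals
    contribute 0)."""
    if isinstance(net, BipartiteNetwork):
        M, _, _ = net.active_matrix()
    else:
        M = np.asarray(net)
    if M.sum() == 0:
        raise ValueError("nestedness undefined on a zero-edge network")
    if M.shape[0] < 2 and M.shape[1] < 2:
        raise ValueError("nestedness undefined on a single-row-and-column network")
    row_acc, row_pairs = _nodf_axis(M)
    col_acc, col_pairs = _nodf_axis(M.T)
    total_pairs = row_pairs + col_pairs
    return NestednessResult(
        nodf=(row_acc + col_acc) / total_pairs if total_pairs else 0.0,
        row_component=row_acc / row_pairs if row_pairs else 0.0,
        col_component=col_acc / col_pairs if col_pairs else 0.0,
    )


# ---------------------------------------------------------------------------
# Permutation nulls


def _null_matrix(M: np.ndarray, model: str, rng: np.random.Generator) -> np.ndarray:
    if model == "equiprobable":
        fill = M.mean()
        return (rng.random(M.shape) < fill).astype(np.int8)
    if model == "degree-preserving":
        out = M.copy()
        r, c = M.shape
        n_swap = 10 * int(M.sum())
        rows = rng.integers(0, r, size=(n_swap, 2))
        cols = rng.integers(0, c, size=(n_swap, 2))
        for (i1, i2), (j1, j2) in zip(rows, cols):
            if out[i1, j1] == 1 and out[i2, j2] == 1 and out[i1, j2] == 0 and out[i2, j1] == 0:
                out[i1, j1] = out[i2, j2] = 0
                out[i1, j2] = out[i2, j1] = 1
        return out
    raise ValueError(f"unknown null model {model!r}")


def permutation_null(
    net: BipartiteNetwork,
    metric: str = "modularity",
    n_perm: int = 1000,
    null_model: str = "equiprobable",
    seed: int = 0,
) -> dict:
    """One-sided empirical p-value of a network metric under a null model.

    p = (1 + #{null >= observed}) / (1 + n_perm); null matrices that leave
    the metric undefined (e.g. no edges) score 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    def measure(M: np.ndarray) -> float:
        try:
            if metric == "modularity":
                A = M[np.ix_(M.sum(axis=1) > 0, M.sum(axis=0) > 0)]
                res = barber_modularity_brim(
                    BipartiteNetwork(
                        [f"r{i}" for i in range(A.shape[0])],
                        [f"c{j}" for j in range(A.shape[1])],
                        A,
                    ),
                    n_restarts=5,
                    seed=seed,
                )
                return res.q
            if metric == "nodf":
                return nodf(M).nodf
            raise ValueError(f"unknown metric {metric!r}")
        except ValueError as exc:
            if "undefined" in str(exc) or "shape" in str(exc):
                return 0.0
            raise

    M, _, _ = net.active_matrix()
    observed = measure(M)
    rng = np.random.default_rng(seed)
    null_values = np.array(
        [measure(_null_matrix(M, null_model, rng)) for _ in range(n_perm)]
    )
    p = (1 + int(np.sum(null_values >= observed))) / (1 + n_perm)
    return {
        "observed": observed,
        "p": p,
        "null_mean": float(null_values.mean()),
        "null_model": null_model,
        "n_permutations": n_perm,
        "seed": seed,
    }


def richness_structure_regression(
    metrics: pd.DataFrame,
    richness: pd.DataFrame,
) -> pd.DataFrame:
    """OLS of each structure metric on each richness measure across samples.

    ``metrics`` (samples x {modularity, nestedness, ...}) and ``richness``
    (samples x {prokaryotic, viral, ...}) share their index. Returns one
    row per (metric, predictor) with slope, two-tailed p and adjusted R^2;
    zero-variance predictors are flagged with NaN results.
    """
    if len(metrics) < 3:
        raise ValueError("need at least 3 samples")
    rows = []
    for mcol in metrics.columns:
        for rcol in richness.columns:
            df = pd.concat([metrics[mcol], richness[rcol]], axis=1).dropna()
            y, x = df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
            if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                rows.append((mcol, rcol, np.nan, np.nan, np.nan))
                continue
            res = stats.linregress(x, y)
            n = len(x)
            adj = 1 - (1 - res.rvalue**2) * (n - 1) / (n - 2)
            rows.append((mcol, rcol, float(res.slope), float(res.pvalue), float(adj)))
    return pd.DataFrame(
        rows, columns=["metric", "predictor", "slope", "p", "adjusted_r2"]
    )
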