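"""Recursive path analysis (observed-variable SEM).

Models are DAGs over observed, standardized variables with independent
error terms and optional free covariances among exogenous variables. Each
endogenous variable's standardized coefficients are estimated by OLS on its
stated parents (maximum likelihood for this model class); goodness of fit
compares the model-implied covariance with the sample covariance through
the Wishart likelihood-ratio statistic

    F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p,    chi2 = (n - 1) F,

with degrees of freedom = p(p+1)/2 - #free parameters, and
RMSEA = sqrt(max(0, (chi2 - df) / (df (n - 1)))).

Model specs use a plain-text edge list: one ``A -> B`` line per directed
path and ``A ~~ B`` for a free exogenous covariance; ``#`` starts a comment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PathSpec:
    edges: list[tuple[str, str]]  # (cause, effect)
    covariances: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_text(cls, text: str) -> "PathSpec":
        edges, covs = [], []
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            if "->" in line:
                a, b = (t.strip() for t in line.split("->"))
                edges.append((a, b))
            elif "~~" in line:
                a, b = (t.strip() for t in line.split("~~"))
                covs.append((a, b))
            else:
                raise ValueError(f"line {lineno}: expected 'A -> B' or 'A ~~ B'")
        return cls(edges, covs)

    @property
    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b in self.edges + self.covariances:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    def topological_order(self) -> list[str]:
        ts = TopologicalSorter({v: set() for v in self.variables})
        for cause, effect in self.edges:
            ts.add(effect, cause)
        try:
            return list(ts.static_order())
        except CycleError as exc:
            raise ValueError(f"path model contains a cycle: {exc.args}") from exc


@dataclass
class PathModel:
    variables: list[str]
    edges: list[tuple[str, str]]
    covariances: list[tuple[str, str]]
    coefficients: dict[tuple[str, str], float]
    r2: dict[str, float]
    chi2: float
    df: int
    p_value: float
    rmsea: float
    n: int
    saturated: bool = False

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "coefficients": {f"{a}->{b}": v for (a, b), v in self.coefficients.items()},
            "r2": self.r2,
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "rmsea": self.rmsea,
            "n": self.n,
            "saturated": self.saturated,
        }


def evaluate_fit(chi2: float, df: int, n: int) -> tuple[float, float]:
    """Chi-square p-value and RMSEA for a fitted model.

    A saturated model (df = 0) reports p = 1 and RMSEA = 0.
    """
    if chi2 < 0:
        raise ValueError(f"negative chi-square: {chi2}")
    if df < 0:
        raise ValueError(f"negative degrees of freedom: {df}")
    if n < 2:
        raise ValueError("need n >= 2")
    if df == 0:
        return 1.0, 0.0
    p = float(stats.chi2.sf(chi2, df))
    rmsea = float(np.sqrt(max(0.0, (chi2 - df) / (df * (n - 1)))))
    return p, rmsea


def fit_path_model(data: pd.DataFrame, spec: PathSpec | str) -> PathModel:
    """Fit a recursive path model to (automatically standardized) data."""
    if isinstance(spec, str):
        spec = PathSpec.from_text(spec)
    order = spec.topological_order()
    missing = [v for v in order if v not in data.columns]
    if missing:
        raise ValueError(f"variables absent from data: {missing}")
    X = data[order].astype(float)
    X = (X - X.mean()) / X.std(ddof=1)
    n, p = X.shape
    parents: dict[str, list[str]] = {v: [] for v in order}
    for cause, effect in spec.edges:
        parents[effect].append(cause)
    n_params = len(spec.edges) + len(spec.covariances) + p
    df = p * (p + 1) // 2 - n_params
    if n <= n_params:
        raise ValueError(f"n = {n} too small for {n_params} free parameters")
    S = np.cov(X.to_numpy(), rowvar=False, ddof=1)
    idx = {v: i for i, v in enumerate(order)}

    coeffs: dict[tuple[str, str], float] = {}
    r2: dict[str, float] = {}
    B = np.zeros((p, p))
    psi = np.zeros((p, p))
    exog = [v for v in order if not parents[v]]
    for v in order:
        pa = parents[v]
        i = idx[v]
        if not pa:
            psi[i, i] = S[i, i]
            continue
        pi = [idx[u] for u in pa]
        beta = np.linalg.solve(S[np.ix_(pi, pi)], S[pi, i])
        for u, b in zip(pa, beta):
            coeffs[(u, v)] = float(b)
            B[i, idx[u]] = b
        explained = float(beta @ S[pi, i])
        r2[v] = min(1.0, max(0.0, explained / S[i, i]))
        psi[i, i] = max(S[i, i] - explained, 1e-12)
    free_cov = {frozenset(cv) for cv in spec.covariances}
    for a in exog:
        for b in exog:
            if a != b and frozenset((a, b)) in free_cov:
                psi[idx[a], idx[b]] = S[idx[a], idx[b]]

    inv = np.linalg.inv(np.eye(p) - B)
    sigma = inv @ psi @ inv.T
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise ValueError("singular sample or implied covariance matrix")
    F = logdet_m + float(np.trace(S @ np.linalg.inv(sigma))) - logdet_s - p
    chi2 = max(0.0, (n - 1) * F)
    p_value, rmsea = evaluate_fit(chi2, df, n)
    return PathModel(
        variables=order,
        edges=list(spec.edges),
        covariances=list(spec.covariances),
        coefficients=coeffs,
        r2=r2,
        chi2=chi2,
        df=df,
        p_value=p_value,
        rmsea=rmsea,
        n=n,
        saturated=df == 0,
    )


def simulate_path_data(
    spec: PathSpec | str,
    coefficients: dict[tuple[str, str], float],
    n: int,
    rng: np.random.Generator,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Draw data from linear structural equations with Gaussian noise.

    Exogenous variables are standard normal; each endogenous variable is
    the coefficient-weighted sum of its parents plus noise. By default the
    noise variance is set so every variable has unit variance (making the
    supplied coefficients standardized); passing ``noise_sd`` overrides it.
    """
    if isinstance(spec, str):
        spec = PathSpec.from_text(spec)
    order = spec.topological_order()
    parents: dict[str, list[str]] = {v: [] for v in order}
    for cause, effect in spec.edges:
        parents[effect].append(cause)
    data: dict[str, np.ndarray] = {}
    for v in order:
        pa = parents[v]
        if not pa:
            data[v] = rng.standard_normal(n)
            continue
        mean = sum(coefficients[(u, v)] * data[u] for u in pa)
        if noise_sd is None:
            explained = float(np.var(mean))
            sd = np.sqrt(max(1.0 - explained, 1e-6))
        else:
            sd = noise_sd
        data[v] = mean + sd * rng.standard_normal(n)
    return pd.DataFrame(data)
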