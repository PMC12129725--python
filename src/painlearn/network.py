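"""Connectivity screen: time series -> correlation network -> binary graph
-> nodal centralities -> Bayes-factor correlations with clinical scores ->
Bayesian false-discovery-rate control.

Parcel-level time series are correlated (Pearson), adaptively thresholded
to a fixed link density (10% by default, keeping the strongest signed
correlations), and the binary graph is scored with five nodal centrality
measures.  Centralities of nodes of interest are correlated with clinical
scores via a default Bayes-factor Pearson correlation (symmetric
stretched-beta prior on the population correlation), and the resulting
posterior error probabilities are ranked into cumulative-average q-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import integrate, special

from .models import InvalidDataError, InvalidParameterError

__all__ = [
    "ParcelTimeSeries",
    "BinaryGraph",
    "BayesCorrRow",
    "CENTRALITY_MEASURES",
    "sum_task_runs",
    "correlation_matrix",
    "threshold_to_density",
    "centralities",
    "bayes_pearson",
    "bf_to_pep",
    "bayes_fdr",
    "centrality_screen",
]

CENTRALITY_MEASURES = ("degree", "eigenvector", "betweenness", "closeness", "load")


@dataclass
class ParcelTimeSeries:
    """Parcels x volumes matrix with labels (BOLD-like arbitrary units)."""

    subject_id: str
    labels: list[str]
    data: np.ndarray
    condition: str = "task"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise InvalidDataError("data must be parcels x volumes matching labels")
        if self.data.shape[1] < 2 * self.data.shape[0]:
            warnings.warn(
                f"subject {self.subject_id}: only {self.data.shape[1]} volumes for "
                f"{self.data.shape[0]} parcels; correlation matrix may be rank-deficient",
                stacklevel=2)

    @property
    def n_parcels(self) -> int:
        return int(self.data.shape[0])


def sum_task_runs(runs: list[ParcelTimeSeries]) -> ParcelTimeSeries:
    """Elementwise sum of run-wise series (makes task comparable to rest)."""
    if not runs:
        raise InvalidDataError("no runs given")
    first = runs[0]
    for r in runs[1:]:
        if r.data.shape != first.data.shape or r.labels != first.labels:
            raise InvalidDataError("runs must share shape and parcel order")
    total = np.sum([r.data for r in runs], axis=0)
    return ParcelTimeSeries(first.subject_id, list(first.labels), total, first.condition)


def correlation_matrix(ts: ParcelTimeSeries) -> np.ndarray:
    """Full Pearson correlation matrix between parcel time series."""
    if ts.data.shape[1] < 3:
        raise InvalidDataError("need >= 3 volumes")
    sd = ts.data.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [ts.labels[i] for i in bad[:5]]
        raise InvalidDataError(f"zero-variance parcel(s): {names}")
    c = np.corrcoef(ts.data)
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class BinaryGraph:
    """Symmetric 0/1 adjacency with zero diagonal at a target link density."""

    adjacency: np.ndarray
    link_density: float
    labels: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return int(self.adjacency.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        if self.labels:
            g = nx.relabel_nodes(g, dict(enumerate(self.labels)))
        return g

    def edge_list(self) -> pd.DataFrame:
        i, j = np.triu_indices(self.n_nodes, k=1)
        keep = self.adjacency[i, j] > 0
        lab = self.labels or [str(k) for k in range(self.n_nodes)]
        return pd.DataFrame({"source": [lab[a] for a in i[keep]],
                             "target": [lab[b] for b in j[keep]]})


def threshold_to_density(
    corr: np.ndarray,
    target_density: float = 0.10,
    labels: list[str] | None = None,
    absolute: bool = False,
) -> BinaryGraph:
    """Keep the strongest edges to reach the target link density.

    The strongest ``round(density * n(n-1)/2)`` off-diagonal correlations
    are kept — by signed value by default (binarized functional networks
    conventionally use positive weights), or by magnitude with
    ``absolute=True``.  Ties at the cutoff break by (i, j) lexicographic
    order, so the graph is deterministic.
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.shape != (n, n) or not np.allclose(corr, corr.T, atol=1e-12):
        raise InvalidDataError("correlation matrix must be square and symmetric")
    if not (0.0 < target_density <= 1.0):
        raise InvalidParameterError(f"density must be in (0, 1], got {target_density}")
    i, j = np.triu_indices(n, k=1)
    vals = np.abs(corr[i, j]) if absolute else corr[i, j]
    k = int(round(target_density * n * (n - 1) / 2))
    # stable sort on (-value, i, j): lexsort keys are applied last-key-major
    order = np.lexsort((j, i, -vals))
    keep = order[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[i[keep], j[keep]] = 1
    adj += adj.T
    realized = k / (n * (n - 1) / 2) if n > 1 else 0.0
    return BinaryGraph(adj, float(realized), list(labels) if labels else [])


def _eigenvector_power(adj: np.ndarray, tol: float = 1e-10, max_iter: int = 100000) -> np.ndarray:
    """Principal eigenvector by power iteration on A + I (the shift ensures
    convergence on bipartite components); scores >= 0, unit max."""
    n = adj.shape[0]
    if adj.sum() == 0:
        return np.zeros(n)
    m = adj.astype(float) + np.eye(n)
    x = np.ones(n) / np.sqrt(n)
    for _ in range(max_iter):
        y = m @ x
        y /= np.linalg.norm(y)
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    return x / x.max()


def centralities(g: BinaryGraph) -> pd.DataFrame:
    """Five nodal centrality measures of the binary graph.

    degree: raw edge count; eigenvector: principal-eigenvector scores
    normalized to unit max; betweenness and load: unnormalized
    shortest-path pair fractions; closeness: classic definition per
    connected component, scaled by the reachable fraction.
    """
    n = g.n_nodes
    lab = g.labels or [str(k) for k in range(n)]
    if g.adjacency.sum() == 0:
        warnings.warn("empty graph: all centralities zero", stacklevel=2)
        return pd.DataFrame(0.0, index=lab, columns=list(CENTRALITY_MEASURES))
    G = nx.from_numpy_array(g.adjacency)
    deg = np.array([d for _, d in sorted(G.degree())], dtype=float)
    eig = _eigenvector_power(np.asarray(g.adjacency, dtype=float))
    bet = nx.betweenness_centrality(G, normalized=False)
    clo = nx.closeness_centrality(G)      # Wasserman-Faust reachability scaling
    load = nx.load_centrality(G, normalized=False)
    out = pd.DataFrame({
        "degree": deg,
        "eigenvector": eig,
        "betweenness": [bet[k] for k in range(n)],
        "closeness": [clo[k] for k in range(n)],
        "load": [load[k] for k in range(n)],
    })
    out.index = lab
    return out


# ---------------------------------------------------------------------------
# Bayesian Pearson correlation
# ---------------------------------------------------------------------------

def _log_h(rho: np.ndarray, r: float, n: int) -> np.ndarray:
    """rho-dependent part of the sampling density of the observed r."""
    rho = np.asarray(rho, dtype=float)
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)
    return ((n - 1) / 2.0 * np.log1p(-rho**2)
            - (n - 1.5) * np.log1p(-rho * r)
            + np.log(hyp))


def bayes_pearson(
    x: np.ndarray, y: np.ndarray, prior_width: float = 1.0, log_base: float = np.e
) -> tuple[float, float]:
    """Sample Pearson r and the two-sided default Bayes factor log(BF10).

    H1 places a symmetric stretched-beta prior of width ``prior_width`` on
    the population correlation; BF10 is the ratio of the marginal
    likelihood of the observed r under H1 (numerical integration over rho)
    to its likelihood under rho = 0.  Natural log by default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidDataError("x and y must be equal-length vectors")
    n = x.size
    if n < 4:
        raise InvalidDataError(f"need n >= 4 complete pairs, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidDataError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise InvalidDataError("constant input; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) > 1.0 - 1e-10:
        # degenerate: the observed r is impossible under rho = 0
        return r, float("inf")

    a = 1.0 / prior_width
    log_norm = special.betaln(a, a) + (2.0 * a - 1.0) * np.log(2.0)
    log_h0 = _log_h(np.array(0.0), r, n)

    def integrand(rho):
        log_prior = (a - 1.0) * np.log1p(-rho**2) - log_norm
        return np.exp(_log_h(rho, r, n) - log_h0 + log_prior)

    val, _ = integrate.quad(integrand, -1.0, 1.0, limit=200)
    log_bf = float(np.log(val) / np.log(log_base))
    return r, log_bf


def bf_to_pep(bf: float) -> tuple[float, float]:
    """Posterior P(H1|data) under equal priors, and the PEP = 1 - P(H1)."""
    if not (bf > 0):
        raise InvalidParameterError(f"Bayes factor must be positive, got {bf}")
    if np.isinf(bf):
        return 1.0, 0.0
    posterior_h1 = bf / (1.0 + bf)
    return posterior_h1, 1.0 - posterior_h1


def bayes_fdr(peps: np.ndarray, threshold: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative-average q-values of ranked PEPs and the retained set.

    Tests are ranked by posterior probability of H1 descending (PEP
    ascending); q_i is the running mean of the first i PEPs; tests with
    q_i < threshold are retained.  Outputs are in the input order.
    """
    peps = np.asarray(peps, dtype=float)
    if peps.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((peps < 0) | (peps > 1)):
        raise InvalidParameterError("PEPs must lie in [0, 1]")
    order = np.argsort(peps, kind="stable")
    q_sorted = np.cumsum(peps[order]) / np.arange(1, peps.size + 1)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q, q < threshold


@dataclass(frozen=True)
class BayesCorrRow:
    """One node x score cell of the centrality screen."""

    node: str
    score: str
    n: int
    r: float
    log_bf: float
    posterior_h1: float
    pep: float
    q_value: float
    retained: bool
    testable: bool = True


def centrality_screen(
    centrality: pd.DataFrame,
    clinical: pd.DataFrame,
    nodes: list[str] | None = None,
    threshold: float = 0.01,
    prior_width: float = 1.0,
    log_base: float = np.e,
) -> pd.DataFrame:
    """Bayes-factor correlations of nodal centrality with clinical scores.

    ``centrality``: subjects x nodes (one measure); ``clinical``: subjects
    x named scores.  Missing values are dropped pairwise; cells with fewer
    than 4 complete pairs are marked untestable and excluded from the FDR
    ranking.  The Bayesian FDR is applied across the whole screen.
    """
    common = centrality.index.intersection(clinical.index)
    if len(common) < 4:
        raise InvalidDataError("fewer than 4 subjects shared between tables")
    cent = centrality.loc[common]
    clin = clinical.loc[common]
    nodes = list(nodes) if nodes is not None else list(cent.columns)

    rows = []
    for node in nodes:
        for score in clin.columns:
            x = cent[node].to_numpy(dtype=float)
            y = clin[score].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n_ok = int(ok.sum())
            if n_ok < 4 or x[ok].std() == 0 or y[ok].std() == 0:
                rows.append(dict(node=node, score=score, n=n_ok, r=np.nan,
                                 log_bf=np.nan, posterior_h1=np.nan, pep=np.nan,
                                 q_value=np.nan, retained=False, testable=False))
                continue
            r, log_bf = bayes_pearson(x[ok], y[ok], prior_width, log_base)
            bf = float(log_base ** log_bf) if log_base != np.e else float(np.exp(log_bf))
            post, pep = bf_to_pep(bf)
            rows.append(dict(node=node, score=score, n=n_ok, r=r, log_bf=log_bf,
                             posterior_h1=post, pep=pep, q_value=np.nan,
                             retained=False, testable=True))
    out = pd.DataFrame(rows)
    mask = out["testable"].to_numpy()
    if mask.any():
        q, keep = bayes_fdr(out.loc[mask, "pep"].to_numpy(), threshold)
        out.loc[mask, "q_value"] = q
        out.loc[mask, "retained"] = keep
    return out
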