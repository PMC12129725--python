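"""Tests for the connectivity pipeline: correlation networks, density
thresholding, centralities, Bayes-factor correlations and Bayesian FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from painlearn.models import InvalidDataError, InvalidParameterError
from painlearn.network import (
    ParcelTimeSeries,
    bayes_fdr,
    bayes_pearson,
    bf_to_pep,
    centralities,
    centrality_screen,
    correlation_matrix,
    sum_task_runs,
    threshold_to_density,
)
from painlearn.synth import generate_clinical_scores, generate_parcel_timeseries


def ts(data, sid="s"):
    return ParcelTimeSeries(sid, [f"p{i}" for i in range(data.shape[0])], data)


class TestSumRuns:
    def test_identity_and_scaling(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((5, 50))
        assert np.array_equal(sum_task_runs([ts(x)]).data, x)
        np.testing.assert_allclose(sum_task_runs([ts(x)] * 4).data, 4 * x)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        runs = [ts(rng.standard_normal((5, 50))) for _ in range(4)]
        a = sum_task_runs(runs).data
        b = sum_task_runs(runs[::-1]).data
        np.testing.assert_allclose(a, b)

    def test_shape_mismatch(self):
        rng = np.random.default_rng(2)
        with pytest.raises(InvalidDataError):
            sum_task_runs([ts(rng.standard_normal((5, 50))),
                           ts(rng.standard_normal((5, 40)))])


class TestCorrelationMatrix:
    def test_basic_properties(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 100))
        x[1] = -x[0]
        c = correlation_matrix(ts(x))
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert c[0, 1] == pytest.approx(-1.0)
        np.testing.assert_allclose(c, c.T)

    def test_matches_scalar_formula_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((5, 200))
        c = correlation_matrix(ts(x))
        for i, j in itertools.combinations(range(5), 2):
            a, b = x[i] - x[i].mean(), x[j] - x[j].mean()
            r = (a @ b) / np.sqrt((a @ a) * (b @ b))
            assert c[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_parcel_named(self):
        x = np.random.default_rng(5).standard_normal((3, 50))
        x[2] = 7.0
        with pytest.raises(InvalidDataError, match="p2"):
            correlation_matrix(ts(x))


class TestThreshold:
    def test_exact_edge_count_at_study_scale(self):
        rng = np.random.default_rng(6)
        c = correlation_matrix(ts(rng.standard_normal((180, 400))))
        g = threshold_to_density(c, 0.10)
        assert g.n_edges == 1611
        assert np.array_equal(g.adjacency, g.adjacency.T)
        assert np.all(np.diag(g.adjacency) == 0)

    def test_full_density_complete_graph(self):
        rng = np.random.default_rng(7)
        c = correlation_matrix(ts(rng.standard_normal((10, 100))))
        g = threshold_to_density(c, 1.0)
        assert g.n_edges == 45

    def test_tie_break_is_lexicographic(self):
        n = 6
        c = np.full((n, n), 0.5)
        np.fill_diagonal(c, 1.0)
        g = threshold_to_density(c, 0.2)   # keep round(0.2*15)=3 edges
        i, j = np.nonzero(np.triu(g.adjacency, 1))
        assert list(zip(i, j)) == [(0, 1), (0, 2), (0, 3)]

    def test_strongest_signed_edges_kept(self):
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 0.9
        c[2, 3] = c[3, 2] = -0.95
        c[0, 2] = c[2, 0] = 0.1
        g = threshold_to_density(c, 1 / 6)   # one edge
        assert g.adjacency[0, 1] == 1 and g.adjacency[2, 3] == 0
        g_abs = threshold_to_density(c, 1 / 6, absolute=True)
        assert g_abs.adjacency[2, 3] == 1

    def test_density_validation(self):
        with pytest.raises(InvalidParameterError):
            threshold_to_density(np.eye(3), 0.0)


# ---------------------------------------------------------------------------
# brute-force centrality oracles (n <= 8): exhaustive shortest-path work
# ---------------------------------------------------------------------------

def all_shortest_paths(adj, s, t):
    n = adj.shape[0]
    best, out = None, []
    frontier = [[s]]
    while frontier and best is None or (frontier and len(frontier[0]) <= best):
        nxt = []
        for path in frontier:
            u = path[-1]
            if u == t:
                if best is None or len(path) == best:
                    best = len(path)
                    out.append(path)
                continue
            for v in range(n):
                if adj[u, v] and v not in path:
                    nxt.append(path + [v])
        frontier = nxt
        if best is not None:
            out.extend(p for p in frontier if p[-1] == t and len(p) == best)
            break
    # deduplicate
    uniq = {tuple(p) for p in out}
    return [list(p) for p in uniq]


def oracle_centralities(adj):
    """Independent brute force for degree/eigenvector/betweenness/closeness/load."""
    n = adj.shape[0]
    deg = adj.sum(axis=1).astype(float)

    w, V = np.linalg.eigh(adj.astype(float))
    v = np.abs(V[:, np.argmax(w)])
    eig = v / v.max() if v.max() > 0 else v

    # BFS distances
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        queue = [s]
        while queue:
            u = queue.pop(0)
            for x in range(n):
                if adj[u, x] and dist[s, x] == np.inf:
                    dist[s, x] = dist[s, u] + 1
                    queue.append(x)

    bet = np.zeros(n)
    load = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(dist[s, t]):
            continue
        paths = all_shortest_paths(adj, s, t)
        sigma = len(paths)
        for v_ in range(n):
            if v_ in (s, t):
                continue
            bet[v_] += sum(v_ in p for p in paths) / sigma

    # Goh load: a unit packet from s to t splits equally at each node among
    # the neighbours that still lie on a shortest path to t
    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(dist[s, t]):
                continue
            weights = {s: 1.0}
            for d_ in range(int(dist[s, t])):
                new = {}
                for u, w_u in weights.items():
                    nxt = [v_ for v_ in range(n)
                           if adj[u, v_] and dist[v_, t] == dist[u, t] - 1]
                    for v_ in nxt:
                        new[v_] = new.get(v_, 0.0) + w_u / len(nxt)
                for u, w_u in new.items():
                    if u != t:
                        load[u] += w_u
                weights = new

    clo = np.zeros(n)
    for u in range(n):
        reach = np.isfinite(dist[u]) & (np.arange(n) != u)
        r = reach.sum()
        if r > 0:
            total = dist[u, reach].sum()
            clo[u] = (r / total) * (r / (n - 1))
    return dict(degree=deg, eigenvector=eig, betweenness=bet, closeness=clo, load=load)


class TestCentralities:
    def test_star_graph_closed_form(self):
        adj = np.zeros((5, 5), dtype=int)
        adj[0, 1:] = adj[1:, 0] = 1
        from painlearn.network import BinaryGraph
        tab = centralities(BinaryGraph(adj, 0.4))
        assert tab["degree"].tolist() == [4, 1, 1, 1, 1]
        assert tab["betweenness"].iloc[0] == pytest.approx(6.0)   # all leaf pairs
        assert tab["eigenvector"].iloc[0] == pytest.approx(1.0)
        assert tab["closeness"].iloc[0] == pytest.approx(1.0)

    def test_complete_graph(self):
        from painlearn.network import BinaryGraph
        adj = np.ones((6, 6), dtype=int) - np.eye(6, dtype=int)
        tab = centralities(BinaryGraph(adj, 1.0))
        np.testing.assert_allclose(tab["betweenness"], 0.0)
        np.testing.assert_allclose(tab["degree"], 5.0)

    def test_empty_graph_warns_zeros(self):
        from painlearn.network import BinaryGraph
        with pytest.warns(UserWarning):
            tab = centralities(BinaryGraph(np.zeros((4, 4), dtype=int), 0.0))
        assert (tab.to_numpy() == 0).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_against_exhaustive_oracle_small_graphs(self, seed):
        from painlearn.network import BinaryGraph
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        adj = (rng.random((n, n)) < 0.45).astype(int)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        tab = centralities(BinaryGraph(adj, float(adj.sum() / (n * (n - 1)))))
        oracle = oracle_centralities(adj)
        for measure in ("degree", "eigenvector", "betweenness", "closeness", "load"):
            np.testing.assert_allclose(
                tab[measure].to_numpy(), oracle[measure], atol=1e-6,
                err_msg=f"{measure} seed={seed} n={n}")


class TestBayesPearson:
    def test_perfect_correlation_r(self):
        x = np.arange(10.0)
        r, _ = bayes_pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_null_simulation_median_bf_below_one(self):
        rng = np.random.default_rng(8)
        bfs = []
        for _ in range(200):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20)
            _, lbf = bayes_pearson(x, y)
            bfs.append(np.exp(lbf))
        assert np.median(bfs) < 1.0

    def test_quadrature_matches_fine_grid_oracle(self):
        """Adaptive quadrature vs a dense trapezoid grid at n=29, r=0.5."""
        from painlearn.network import _log_h
        from scipy.special import betaln

        rng = np.random.default_rng(9)
        x = rng.standard_normal(29)
        noise = rng.standard_normal(29)
        zx = (x - x.mean()) / x.std()
        nz = noise - (noise @ zx) / (zx @ zx) * zx
        nz = (nz - nz.mean()) / nz.std()
        y = 0.5 * zx + np.sqrt(0.75) * nz
        r, lbf = bayes_pearson(x, y)
        assert r == pytest.approx(0.5, abs=1e-12)

        rho = np.linspace(-1 + 1e-9, 1 - 1e-9, 400_001)
        a = 1.0
        log_norm = betaln(a, a) + (2 * a - 1) * np.log(2.0)
        log_prior = (a - 1) * np.log1p(-rho**2) - log_norm
        vals = np.exp(_log_h(rho, r, 29) - _log_h(np.array(0.0), r, 29) + log_prior)
        bf_grid = np.trapezoid(vals, rho)
        assert lbf == pytest.approx(np.log(bf_grid), abs=1e-6)

    def test_matches_pingouin_default_bf(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        for n in (10, 25, 40):
            x = rng.standard_normal(n)
            y = 0.4 * x + rng.standard_normal(n)
            r, lbf = bayes_pearson(x, y)
            assert lbf == pytest.approx(np.log(float(pingouin.bayesfactor_pearson(r, n))),
                                        abs=1e-4)

    def test_configurable_log_base(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(30)
        y = 0.5 * x + rng.standard_normal(30)
        _, ln_bf = bayes_pearson(x, y, log_base=np.e)
        _, log10_bf = bayes_pearson(x, y, log_base=10.0)
        assert log10_bf == pytest.approx(ln_bf / np.log(10.0))

    def test_input_validation(self):
        with pytest.raises(InvalidDataError):
            bayes_pearson(np.ones(10), np.arange(10.0))
        with pytest.raises(InvalidDataError):
            bayes_pearson(np.arange(3.0), np.arange(3.0))


class TestBfToPep:
    @pytest.mark.parametrize("bf,post,pep", [(1.0, 0.5, 0.5), (3.0, 0.75, 0.25)])
    def test_equal_prior_posterior(self, bf, post, pep):
        p, q = bf_to_pep(bf)
        assert p == pytest.approx(post)
        assert q == pytest.approx(pep)

    def test_large_bf_limit(self):
        _, pep = bf_to_pep(1e12)
        assert pep == pytest.approx(0.0, abs=1e-10)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidParameterError):
            bf_to_pep(0.0)


class TestBayesFdr:
    def test_worked_example(self):
        q, keep = bayes_fdr(np.array([0.02, 0.04, 0.30]), threshold=0.05)
        np.testing.assert_allclose(q, [0.02, 0.03, 0.12])
        assert keep.tolist() == [True, True, False]

    def test_all_zero_peps_all_retained(self):
        q, keep = bayes_fdr(np.zeros(5), threshold=1e-6)
        assert keep.all()

    def test_empty_input(self):
        q, keep = bayes_fdr(np.array([]))
        assert q.size == 0 and keep.size == 0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_nondecreasing_in_rank(self, peps):
        peps = np.asarray(peps)
        q, _ = bayes_fdr(peps)
        order = np.argsort(peps, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_retained_set_shrinks_with_threshold(self):
        rng = np.random.default_rng(12)
        peps = rng.uniform(0, 1, 50)
        prev = None
        for thr in (0.5, 0.2, 0.1, 0.01):
            _, keep = bayes_fdr(peps, thr)
            if prev is not None:
                assert np.all(keep <= prev)   # subset
            prev = keep


class TestScreen:
    def _tables(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        cent = pd.DataFrame(rng.standard_normal((n, 3)),
                            index=[f"s{i}" for i in range(n)],
                            columns=["node0", "node1", "node2"])
        clin = pd.DataFrame({
            "self": cent["node1"],
            "noise": rng.standard_normal(n),
        }, index=cent.index)
        return cent, clin

    def test_identical_score_gives_r_one(self):
        cent, clin = self._tables()
        out = centrality_screen(cent, clin, threshold=0.05)
        row = out[(out.node == "node1") & (out.score == "self")].iloc[0]
        assert row.r == pytest.approx(1.0)

    def test_joint_subject_permutation_invariance(self):
        cent, clin = self._tables(seed=1)
        out1 = centrality_screen(cent, clin)
        perm = np.random.default_rng(2).permutation(len(cent))
        out2 = centrality_screen(cent.iloc[perm], clin.iloc[perm])
        merged = out1.merge(out2, on=["node", "score"], suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged.r_a, merged.r_b, atol=1e-12)

    def test_untestable_cells_excluded(self):
        cent, clin = self._tables(n=10, seed=3)
        clin.loc[clin.index[3:], "noise"] = np.nan   # 3 complete pairs only
        out = centrality_screen(cent, clin, threshold=0.05)
        bad = out[out.score == "noise"]
        assert (~bad.testable).all()
        assert not bad.retained.any()

    def test_planted_hub_attains_max_degree(self):
        """The pipeline finds the planted hub in >=90% of replicates."""
        hits = 0
        labels = [f"p{i}" for i in range(30)]
        for seed in range(10):
            x, _ = generate_parcel_timeseries(30, 300, hub_node=5, hub_strength=1.0,
                                              seed=seed, n_linked=12)
            g = threshold_to_density(
                correlation_matrix(ParcelTimeSeries("s", labels, x)), 0.10,
                labels=labels)
            deg = centralities(g)["degree"]
            hits += int(deg.idxmax() == "p5")
        assert hits >= 9

    def test_graph_pipeline_deterministic(self):
        x, _ = generate_parcel_timeseries(20, 200, 2, 0.8, seed=5, n_linked=8)
        t = ParcelTimeSeries("s", [f"p{i}" for i in range(20)], x)
        g1 = threshold_to_density(correlation_matrix(t), 0.1)
        g2 = threshold_to_density(correlation_matrix(t), 0.1)
        assert np.array_equal(g1.adjacency, g2.adjacency)
        assert centralities(g1).equals(centralities(g2))
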