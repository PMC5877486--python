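"""Graph metrics: hand-worked examples and exhaustive brute-force oracles.

The oracles enumerate triangles, simple paths and shortest-path memberships
directly (feasible for M <= 6 nodes) and are independent of both the package
implementation and the libraries it delegates to.
"""

from itertools import permutations

import numpy as np
import pytest

import somnograph as sg


def _sl(mat):
    return sg.SLMatrix(values=np.asarray(mat, float),
                       params=sg.SLParams(l=1, m=2, w1=1, w2=10, p_ref=0.1))


def _rwe(mat):
    return sg.RWEMatrix(values=np.asarray(mat, float),
                        params=sg.WaveletParams(fs=128.0))


def _graph(weights, directed=False):
    return sg.WeightedGraph(weights=np.asarray(weights, float),
                            directed=directed)


def _random_graph(rng, m, directed=False):
    w = rng.uniform(0.05, 1.0, size=(m, m))
    if not directed:
        w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return _graph(w, directed)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_clustering(g):
    """Geometric-mean triangle intensity, weights normalized by the max."""
    w = g.weights / g.weights.max()
    m = g.n_nodes
    vals = []
    for u in range(m):
        if g.directed:
            # Fagiolo: total degree counts in- and out-edges separately
            d_tot = (sum(1 for v in range(m) if w[u, v] > 0)
                     + sum(1 for v in range(m) if w[v, u] > 0))
            bidir = sum(1 for v in range(m) if w[u, v] > 0 and w[v, u] > 0)
            wh = np.cbrt(w)
            t = 0.0
            for j in range(m):
                for h in range(m):
                    if u in (j, h) or j == h:
                        continue
                    t += ((wh[u, j] + wh[j, u]) * (wh[u, h] + wh[h, u])
                          * (wh[j, h] + wh[h, j]))
            t /= 2.0
            denom = d_tot * (d_tot - 1) - 2 * bidir
            vals.append(t / denom if denom > 0 else 0.0)
        else:
            neigh = [v for v in range(m) if w[u, v] > 0]
            d = len(neigh)
            if d < 2:
                vals.append(0.0)
                continue
            s = sum((w[u, a] * w[u, b] * w[a, b]) ** (1.0 / 3.0)
                    for i, a in enumerate(neigh) for b in neigh[i + 1:]
                    if w[a, b] > 0)
            vals.append(2.0 * s / (d * (d - 1)))
    return float(np.mean(vals))


def _all_shortest(g):
    """Min path length and the set of minimal simple paths per ordered pair."""
    m = g.n_nodes
    with np.errstate(divide="ignore"):
        lengths = np.where(g.weights > 0, 1.0 / g.weights, np.inf)
    best = {}
    for s in range(m):
        for t in range(m):
            if s == t:
                continue
            best_len, best_paths = np.inf, []
            inner = [v for v in range(m) if v not in (s, t)]
            for r in range(len(inner) + 1):
                for mid in permutations(inner, r):
                    path = (s, *mid, t)
                    plen = sum(lengths[a, b] for a, b in zip(path, path[1:]))
                    if plen < best_len - 1e-12:
                        best_len, best_paths = plen, [path]
                    elif abs(plen - best_len) <= 1e-12:
                        best_paths.append(path)
            best[(s, t)] = (best_len, best_paths)
    return best


def brute_path_efficiency(g):
    best = _all_shortest(g)
    dists = np.array([b[0] for b in best.values()])
    finite = np.isfinite(dists)
    char = float(dists[finite].mean())
    eff = float(np.where(finite, 1.0 / np.where(finite, dists, 1.0), 0.0).mean())
    return char, eff


def brute_betweenness(g):
    m = g.n_nodes
    best = _all_shortest(g)
    bc = np.zeros(m)
    for (s, t), (plen, paths) in best.items():
        if not g.directed and s > t:
            continue
        if not np.isfinite(plen):
            continue
        for v in range(m):
            if v in (s, t):
                continue
            frac = sum(1 for p in paths if v in p[1:-1]) / len(paths)
            bc[v] += frac
    norm = (m - 1) * (m - 2) * (0.5 if not g.directed else 1.0)
    return float((bc / norm).mean())


# ---------------------------------------------------------------------------
# conversion and hand-worked examples
# ---------------------------------------------------------------------------

class TestToGraph:
    def test_sl_ones_is_complete_unit_graph(self):
        vals = np.ones((4, 4)) - np.eye(4)
        g = sg.to_graph(_sl(vals))
        assert not g.directed
        np.testing.assert_allclose(g.weights, vals)

    def test_rwe_zero_matrix_maps_to_unit_similarity(self):
        g = sg.to_graph(_rwe(np.zeros((3, 3))))
        assert g.directed
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(g.weights[off], 1.0)

    def test_rwe_value_one_maps_to_half(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = 1.0
        g = sg.to_graph(_rwe(vals))
        assert g.weights[0, 1] == pytest.approx(0.5)

    def test_negative_entries_rejected(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = -0.2
        with pytest.raises(ValueError, match="negative"):
            sg.to_graph(_sl(vals))


class TestBinaryDegreeDensity:
    def test_full_threshold_on_complete_graph(self):
        g = _graph(np.ones((5, 5)) - np.eye(5))
        deg, den = sg.binary_degree_density(g, threshold_frac=1.0)
        assert deg == pytest.approx(4.0)
        assert den == pytest.approx(1.0)

    def test_keep_top_three_of_six(self):
        w = np.zeros((4, 4))
        vals = iter([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        for i in range(4):
            for j in range(i + 1, 4):
                w[i, j] = w[j, i] = next(vals)
        _, den = sg.binary_degree_density(_graph(w), threshold_frac=0.5)
        assert den == pytest.approx(0.5)

    def test_ties_at_cut_all_kept(self):
        w = np.zeros((4, 4))
        vals = iter([0.9, 0.5, 0.5, 0.5, 0.2, 0.1])
        for i in range(4):
            for j in range(i + 1, 4):
                w[i, j] = w[j, i] = next(vals)
        _, den = sg.binary_degree_density(_graph(w), threshold_frac=0.5)
        assert den >= 0.5  # all three 0.5-edges kept -> 4/6

    def test_directed_rejected(self, rng):
        g = _random_graph(rng, 4, directed=True)
        with pytest.raises(ValueError, match="undirected"):
            sg.binary_degree_density(g)

    def test_density_monotone_in_threshold(self, rng):
        g = _random_graph(rng, 6)
        dens = [sg.binary_degree_density(g, f)[1]
                for f in (0.2, 0.4, 0.6, 0.8, 1.0)]
        assert all(b >= a for a, b in zip(dens, dens[1:]))


class TestClustering:
    def test_complete_unit_k4(self):
        g = _graph(np.ones((4, 4)) - np.eye(4))
        assert sg.weighted_clustering(g) == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        assert sg.weighted_clustering(_graph(w)) == pytest.approx(0.0)

    def test_k3_geometric_mean(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        w[1, 2] = w[2, 1] = 0.125
        # each node: (1 * 1 * 0.125)^(1/3) = 0.5
        assert sg.weighted_clustering(_graph(w)) == pytest.approx(0.5)


class TestPathsAndBetweenness:
    def test_complete_unit_graph(self):
        g = _graph(np.ones((5, 5)) - np.eye(5))
        length, eff = sg.path_length_efficiency(g)
        assert length == pytest.approx(1.0)
        assert eff == pytest.approx(1.0)
        assert sg.mean_betweenness(g) == pytest.approx(0.0)

    def test_three_chain(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        length, eff = sg.path_length_efficiency(_graph(w))
        assert length == pytest.approx(4.0 / 3.0)
        assert eff == pytest.approx((1.0 + 1.0 + 0.5) / 3.0)

    def test_doubling_similarity_halves_path_length(self, rng):
        g = _random_graph(rng, 5)
        l1, _ = sg.path_length_efficiency(g)
        l2, _ = sg.path_length_efficiency(_graph(2.0 * g.weights))
        assert l2 == pytest.approx(l1 / 2.0)

    def test_path_graph_betweenness(self):
        w = np.zeros((4, 4))
        for i in range(3):
            w[i, i + 1] = w[i + 1, i] = 1.0
        # nodes b and c each carry 2 of 3 normalized pairs -> mean = 1/3
        assert sg.mean_betweenness(_graph(w)) == pytest.approx(1.0 / 3.0)

    def test_star_centre_betweenness(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        # centre routes all 3 peripheral pairs -> 1.0; mean = 0.25
        assert sg.mean_betweenness(_graph(w)) == pytest.approx(0.25)


class TestBruteForceOracles:
    @pytest.mark.parametrize("directed", [False, True])
    @pytest.mark.parametrize("m", [3, 4, 5, 6])
    def test_metrics_match_exhaustive_enumeration(self, m, directed, rng):
        for _ in range(3):
            g = _random_graph(rng, m, directed)
            assert sg.weighted_clustering(g) == pytest.approx(
                brute_clustering(g), abs=1e-9)
            length, eff = sg.path_length_efficiency(g)
            blength, beff = brute_path_efficiency(g)
            assert length == pytest.approx(blength, abs=1e-9)
            assert eff == pytest.approx(beff, abs=1e-9)
            assert sg.mean_betweenness(g) == pytest.approx(
                brute_betweenness(g), abs=1e-9)

    def test_permutation_invariance(self, rng):
        g = _random_graph(rng, 6)
        perm = rng.permutation(6)
        gp = _graph(g.weights[np.ix_(perm, perm)])
        assert sg.weighted_clustering(gp) == pytest.approx(
            sg.weighted_clustering(g), abs=1e-12)
        assert sg.path_length_efficiency(gp) == pytest.approx(
            sg.path_length_efficiency(g), abs=1e-12)
        assert sg.mean_betweenness(gp) == pytest.approx(
            sg.mean_betweenness(g), abs=1e-12)


class TestSmallWorld:
    def test_deterministic_given_seed(self, rng):
        g = _random_graph(rng, 8)
        a = sg.small_world_index(g, n_rand=10, seed=3)
        b = sg.small_world_index(g, n_rand=10, seed=3)
        assert a == b

    def test_random_weights_give_sigma_near_one(self):
        # the graph is statistically identical to its own surrogates
        sigmas = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            g = _random_graph(r, 10)
            sigmas.append(sg.small_world_index(g, n_rand=10, seed=seed))
        assert np.mean(sigmas) == pytest.approx(1.0, abs=0.2)

    def test_ring_lattice_clustering_exceeds_shuffled(self):
        # ring lattice, strong nearest-neighbour and weaker next-nearest
        # weights: every triangle uses two strong edges and one weak one,
        # which beats the random strong/weak assignment of the null
        m = 12
        w = np.zeros((m, m))
        for i in range(m):
            w[i, (i + 1) % m] = w[(i + 1) % m, i] = 1.0
            w[i, (i + 2) % m] = w[(i + 2) % m, i] = 0.3
        g = _graph(w)
        c = sg.weighted_clustering(g)
        # independent support-preserving surrogate built here, not via the
        # package: permute weights over the lattice's own edges
        r = np.random.default_rng(0)
        iu = np.triu_indices(m, 1)
        edge_sel = w[iu] > 0
        c_rand = []
        for _ in range(20):
            vals = w[iu].copy()
            vals[edge_sel] = r.permutation(vals[edge_sel])
            ws = np.zeros((m, m))
            ws[iu] = vals
            ws += ws.T
            c_rand.append(sg.weighted_clustering(_graph(ws)))
        assert c / np.mean(c_rand) > 1.0
        assert np.isfinite(sg.small_world_index(g, n_rand=10, seed=0))


class TestFeatureBlock:
    def test_sl_block_has_seven_features(self, rng):
        g = _random_graph(rng, 6)
        mat = _sl(g.weights)
        block = sg.graph_feature_block(mat, seed=0)
        assert block.as_array().size == 7

    def test_rwe_block_has_five_features(self, rng):
        w = rng.uniform(0.1, 1.0, size=(6, 6))
        np.fill_diagonal(w, 0.0)
        block = sg.graph_feature_block(_rwe(w), seed=0)
        assert block.as_array().size == 5

    def test_all_ones_sl_matrix_block(self):
        m = 5
        vals = np.ones((m, m)) - np.eye(m)
        block = sg.graph_feature_block(_sl(vals), seed=1)
        got = block.as_array()
        np.testing.assert_allclose(got[:6], [m - 1, 1.0, 1.0, 1.0, 1.0, 0.0])
        assert got[6] == pytest.approx(1.0)  # surrogates identical to input
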