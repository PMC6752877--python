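"""Weighted topology metrics against brute-force oracles and recovery fixtures."""

import itertools

import networkx as nx
import numpy as np
import pytest

import midnet as mn
from conftest import net_from


def sym(entries, n):
    w = np.zeros((n, n))
    for (i, j), v in entries.items():
        w[i, j] = w[j, i] = v
    return w


def two_cliques(k=4, bridge=None):
    n = 2 * k
    w = np.zeros((n, n))
    for blk in (range(k), range(k, n)):
        for a, b in itertools.combinations(blk, 2):
            w[a, b] = w[b, a] = 1.0
    if bridge is not None:
        a, b = bridge
        w[a, b] = w[b, a] = 1.0
    return w


# ---- density --------------------------------------------------------------


def test_density_examples():
    complete = two_cliques(4, None)
    complete[:4, 4:] = complete[4:, :4] = 1.0
    np.fill_diagonal(complete, 0.0)
    assert mn.network_density(net_from(complete)) == 1.0
    assert mn.network_density(net_from(np.zeros((5, 5)))) == 0.0
    path = sym({(0, 1): 1, (1, 2): 1, (2, 3): 1}, 4)
    assert mn.network_density(net_from(path)) == 0.5


# ---- clustering -----------------------------------------------------------


def test_clustering_unit_triangle_is_one():
    c, mean = mn.clustering_coefficient(net_from(sym({(0, 1): 1, (0, 2): 1, (1, 2): 1}, 3)))
    np.testing.assert_allclose(c, 1.0)
    assert mean == 1.0


def test_clustering_star_is_zero():
    star = sym({(0, j): 1 for j in range(1, 6)}, 6)
    c, mean = mn.clustering_coefficient(net_from(star))
    np.testing.assert_allclose(c, 0.0)


def test_clustering_weighted_triangle_geometric_mean():
    # triangle with weights 1, 1, 0.5 (already max-scaled): every node sits in
    # the single triangle, so C_i = (1·1·0.5)^(1/3) for all three
    w = sym({(0, 1): 1.0, (0, 2): 1.0, (1, 2): 0.5}, 3)
    c, _ = mn.clustering_coefficient(net_from(w))
    np.testing.assert_allclose(c, 0.5 ** (1 / 3), atol=1e-12)


def brute_onnela(w):
    wmax = w.max()
    n = w.shape[0]
    c = np.zeros(n)
    for i in range(n):
        k = np.count_nonzero(w[i])
        if k < 2:
            continue
        tot = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    tot += ((w[i, j] / wmax) * (w[i, h] / wmax) * (w[j, h] / wmax)) ** (1 / 3)
        c[i] = tot / (k * (k - 1))
    return c


def test_clustering_matches_brute_force_and_networkx(rng):
    for _ in range(5):
        n = 7
        w = rng.uniform(0, 1, size=(n, n)) * (rng.random((n, n)) < 0.5)
        w = np.triu(w, 1)
        w = w + w.T
        if w.max() == 0:
            continue
        c, _ = mn.clustering_coefficient(net_from(w))
        np.testing.assert_allclose(c, brute_onnela(w), atol=1e-9)
        g = nx.from_numpy_array(w)
        nxc = np.array([nx.clustering(g, weight="weight")[i] for i in range(n)])
        np.testing.assert_allclose(c, nxc, atol=1e-9)


def test_clustering_binary_limit_equals_binary_clustering(rng):
    for _ in range(20):
        n = 10
        a = (rng.random((n, n)) < 0.4).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        c, _ = mn.clustering_coefficient(net_from(a))
        g = nx.from_numpy_array(a)
        nxc = np.array([nx.clustering(g)[i] for i in range(n)])
        np.testing.assert_allclose(c, nxc, atol=1e-12)


def test_clustering_rejects_negative_weights():
    with pytest.raises(ValueError, match="nonnegative"):
        mn.clustering_coefficient(net_from(sym({(0, 1): -0.5, (1, 2): 1}, 3)))


# ---- modularity -----------------------------------------------------------


def set_partitions(n):
    """All partitions of range(n) as label arrays (restricted growth strings)."""
    labels = np.zeros(n, dtype=int)

    def rec(i, maxlab):
        if i == n:
            yield labels.copy()
            return
        for lab in range(maxlab + 2):
            labels[i] = lab
            yield from rec(i + 1, max(maxlab, lab))

    yield from rec(1, 0)


def exhaustive_best_q(w, gamma=1.0):
    return max(mn.modularity_q(w, labels, gamma) for labels in set_partitions(w.shape[0]))


def test_two_disconnected_cliques_optimum_is_half():
    w = two_cliques(4)
    labels, q = mn.modularity(net_from(w), seed=0)
    assert q == pytest.approx(0.5, abs=1e-12)  # 1 − 1/k for k equal modules
    assert q == pytest.approx(exhaustive_best_q(w), abs=1e-9)
    # the partition is exactly the two cliques
    assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
    assert labels[0] != labels[4]


def test_louvain_attains_exhaustive_optimum_on_planted_blocks():
    w = mn.generate_planted_network(8, "modular", seed=1, n_blocks=2)
    labels, q = mn.modularity(net_from(w), seed=0)
    assert q == pytest.approx(exhaustive_best_q(w), abs=1e-9)


def test_complete_graph_single_community_by_formula():
    n = 5
    w = np.ones((n, n)) - np.eye(n)
    labels = np.zeros(n, dtype=int)
    # direct double-loop evaluation with δ ≡ 1
    s = w.sum(axis=1)
    two_m = w.sum()
    expected = sum(
        w[i, j] - s[i] * s[j] / two_m for i in range(n) for j in range(n)
    ) / two_m
    assert expected == pytest.approx(0.0, abs=1e-12)  # one community ⇒ Q = 0
    assert mn.modularity_q(w, labels) == pytest.approx(expected, abs=1e-12)


def test_singleton_partition_formula_and_nonpositive(rng):
    for _ in range(5):
        n = 7
        w = rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.6)
        w = np.triu(w, 1)
        w = w + w.T
        if w.sum() == 0:
            continue
        labels = np.arange(n)
        s = w.sum(axis=1)
        expected = -float(np.sum(s**2)) / w.sum() ** 2
        q = mn.modularity_q(w, labels)
        assert q == pytest.approx(expected, abs=1e-12)
        assert q <= 0


def test_modularity_edgeless_errors():
    with pytest.raises(ValueError, match="edgeless"):
        mn.modularity(net_from(np.zeros((4, 4))))


def test_modularity_deterministic_given_seed():
    w = mn.generate_planted_network(30, "modular", seed=2, n_blocks=3)
    l1, q1 = mn.modularity(net_from(w), seed=42)
    l2, q2 = mn.modularity(net_from(w), seed=42)
    assert q1 == q2
    np.testing.assert_array_equal(l1, l2)


# ---- assortativity --------------------------------------------------------


def brute_assortativity(w):
    s = w.sum(axis=1)
    xs, ys = [], []
    n = w.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] != 0:
                xs += [s[i], s[j]]
                ys += [s[j], s[i]]
    xs, ys = np.array(xs), np.array(ys)
    mx, my = xs.mean(), ys.mean()
    return float(((xs - mx) * (ys - my)).sum() / np.sqrt(((xs - mx) ** 2).sum() * ((ys - my) ** 2).sum()))


@pytest.mark.parametrize("n", [3, 6, 12])
def test_star_assortativity_is_minus_one(n):
    star = sym({(0, j): 1 for j in range(1, n)}, n)
    assert mn.assortativity(net_from(star)) == pytest.approx(-1.0, abs=1e-12)


def test_ring_assortativity_undefined():
    n = 6
    ring = sym({(i, (i + 1) % n): 1 for i in range(n)}, n)
    assert np.isnan(mn.assortativity(net_from(ring)))


def test_two_bridged_cliques_match_brute_oracle():
    # bridge endpoints (strength 4) mostly attach to strength-3 nodes, so the
    # edge-list Pearson correlation is slightly negative: -1/12 by enumeration
    w = two_cliques(4, bridge=(0, 4))
    r = mn.assortativity(net_from(w))
    assert r == pytest.approx(brute_assortativity(w), abs=1e-12)
    assert r == pytest.approx(-1 / 12, abs=1e-12)


def test_weighted_assortativity_matches_oracle(rng):
    for _ in range(5):
        n = 9
        w = rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.4)
        w = np.triu(w, 1)
        w = w + w.T
        if np.count_nonzero(np.triu(w)) < 2:
            continue
        r = mn.assortativity(net_from(w))
        if not np.isnan(r):
            assert r == pytest.approx(brute_assortativity(w), abs=1e-12)


def test_assortativity_needs_two_edges():
    with pytest.raises(ValueError, match="2 edges"):
        mn.assortativity(net_from(sym({(0, 1): 1}, 4)))


def test_degree_variant_differs_on_weighted_graph():
    w = sym({(0, 1): 0.9, (1, 2): 0.1, (2, 3): 0.5, (3, 0): 0.2, (0, 2): 0.7}, 4)
    rs = mn.assortativity(net_from(w), variant="strength")
    rd = mn.assortativity(net_from(w), variant="degree")
    assert not np.isnan(rs)
    assert rs != rd or np.isnan(rd)


# ---- permutation invariance & report -------------------------------------


def test_metrics_invariant_under_node_relabeling(rng):
    w = mn.generate_planted_network(18, "modular", seed=3, n_blocks=3)
    perm = rng.permutation(18)
    wp = w[np.ix_(perm, perm)]
    a, b = net_from(w), net_from(wp)
    assert mn.network_density(a) == mn.network_density(b)
    ca, _ = mn.clustering_coefficient(a)
    cb, _ = mn.clustering_coefficient(b)
    np.testing.assert_allclose(np.sort(ca), np.sort(cb), atol=1e-12)
    _, qa = mn.modularity(a, seed=0)
    _, qb = mn.modularity(b, seed=0)
    assert qa == pytest.approx(qb, abs=1e-9)
    assert mn.assortativity(a) == pytest.approx(mn.assortativity(b), abs=1e-12)


def test_report_on_empty_network_flags_degeneracies():
    rep = mn.topology_report(net_from(np.zeros((5, 5))))
    assert rep.density == 0.0
    np.testing.assert_array_equal(rep.clustering_per_node, 0.0)
    assert rep.modularity_q is None and rep.partition is None
    assert np.isnan(rep.assortativity_r)
    assert "modularity_undefined_edgeless" in rep.flags


def test_report_clips_negative_weights_with_flag():
    w = sym({(0, 1): 0.8, (1, 2): -0.3, (2, 3): 0.5, (0, 2): 0.4}, 4)
    rep = mn.topology_report(net_from(w))
    assert any(f.startswith("clipped_1") for f in rep.flags)
    # density counts the negative edge; weighted metrics exclude it
    assert rep.density == pytest.approx(4 / 6)


def test_report_recovers_planted_assortative_sign():
    w = mn.generate_planted_network(50, "assortative", seed=4)
    rep = mn.topology_report(net_from(w))
    assert rep.assortativity_r > 0


def test_report_recovers_planted_modules():
    from sklearn.metrics import adjusted_rand_score

    for seed in (0, 1, 2):
        w = mn.generate_planted_network(30, "modular", seed=seed, n_blocks=3)
        rep = mn.topology_report(net_from(w), seed=seed)
        truth = np.arange(30) % 3
        assert adjusted_rand_score(truth, rep.partition) > 0.9
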