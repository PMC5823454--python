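"""Network inference: phi edges vs oracles, statistics, hubs, heavy-tail
diagnostics, and the person-level bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from comorbnet import (
    GeneratorConfig,
    bootstrap_network_statistic,
    build_network,
    hub_degree_share,
    network_stats,
    phi_correlation,
    scale_free_diagnostics,
    simulate_cohort,
)
from comorbnet.errors import DomainError
from comorbnet.network import ComorbidityNetwork, EdgeRecord, NetworkStats

from conftest import make_independent_matrix


def vectors_from_table(a, b, c, d):
    x = np.array([1] * a + [1] * b + [0] * c + [0] * d, dtype=np.uint8)
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=np.uint8)
    return x, y


def test_phi_identity():
    x = np.array([0, 1, 1, 0, 1, 0], dtype=np.uint8)
    w, p = phi_correlation(x, x)
    assert w == pytest.approx(1.0)
    assert p < 0.05


def test_phi_worked_table():
    x, y = vectors_from_table(30, 10, 10, 50)
    w, p = phi_correlation(x, y)
    assert w == pytest.approx((30 * 50 - 10 * 10) / math.sqrt(40 * 60 * 40 * 60))
    assert w == pytest.approx(0.583333, abs=1e-6)
    assert p == pytest.approx(float(sps.chi2.sf(100 * w * w, 1)))


@settings(derandomize=True, max_examples=200)
@given(
    a=st.integers(0, 25), b=st.integers(0, 25), c=st.integers(0, 25), d=st.integers(0, 25)
)
def test_phi_matches_2x2_formula(a, b, c, d):
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n < 2 or r1 in (0, n) or c1 in (0, n):
        return
    x, y = vectors_from_table(a, b, c, d)
    w, _ = phi_correlation(x, y)
    expected = (a * d - b * c) / math.sqrt(r1 * (n - r1) * c1 * (n - c1))
    assert w == pytest.approx(expected, abs=1e-12)


def test_phi_null_distribution():
    """Independent binaries: phi concentrates near 0 and its p-value is
    approximately uniform."""
    rng = np.random.default_rng(17)
    phis, pvals = [], []
    for _ in range(200):
        x = (rng.random(2000) < 0.4).astype(np.uint8)
        y = (rng.random(2000) < 0.6).astype(np.uint8)
        w, p = phi_correlation(x, y)
        phis.append(w)
        pvals.append(p)
    assert np.mean(np.abs(phis) < 0.05) > 0.95
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_phi_zero_variance_rejected():
    with pytest.raises(DomainError):
        phi_correlation(np.ones(10, dtype=np.uint8), np.zeros(10, dtype=np.uint8))


def test_single_person_network(small_catalog):
    x = np.zeros((1, len(small_catalog)), dtype=np.uint8)
    x[0, :3] = 1
    net = build_network(x, small_catalog)
    assert len(net.nodes) == 3
    assert net.edges == []


def test_empty_cohort_rejected(small_catalog):
    with pytest.raises(DomainError):
        build_network([], small_catalog)


def brute_force_edges(x, catalog, alpha):
    """Independent oracle: all unordered pairs via the scalar 2x2 path."""
    ids = catalog.condition_ids
    edges = {}
    for i in range(x.shape[1]):
        for j in range(i + 1, x.shape[1]):
            try:
                w, p = phi_correlation(x[:, i], x[:, j])
            except DomainError:
                continue
            if p <= alpha:
                edges[(ids[i], ids[j])] = w
    return edges


def test_edges_match_brute_force(small_catalog):
    rng = np.random.default_rng(8)
    for trial in range(5):
        x = make_independent_matrix(rng, 80, len(small_catalog), 0.1, 0.9)
        # plant some real structure
        x[:, 3] = x[:, 1] ^ (rng.random(80) < 0.1)
        net = build_network(x, small_catalog, alpha=0.05)
        got = {(e.disease_a, e.disease_b): e.weight for e in net.edges}
        expected = brute_force_edges(x, small_catalog, 0.05)
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k] == pytest.approx(expected[k], abs=1e-12)


def test_alpha_monotonicity(small_catalog):
    rng = np.random.default_rng(12)
    x = make_independent_matrix(rng, 300, len(small_catalog))
    counts = [
        len(build_network(x, small_catalog, alpha).edges) for alpha in (0.2, 0.05, 0.01, 0.001)
    ]
    assert counts == sorted(counts, reverse=True)


def test_permutation_invariance(small_catalog, cohort_small):
    rng = np.random.default_rng(4)
    x = make_independent_matrix(rng, 400, len(small_catalog), 0.2, 0.6)
    net = build_network(x, small_catalog, 0.05)
    perm = rng.permutation(x.shape[0])
    net_p = build_network(x[perm], small_catalog, 0.05)
    key = lambda n: sorted((e.disease_a, e.disease_b, round(e.weight, 12)) for e in n.edges)
    assert key(net) == key(net_p)


def test_handshake_and_histogram(cohort_small, catalog):
    net = build_network([r for r in cohort_small if r.group == "copd"], catalog)
    st_ = network_stats(net)
    assert sum(k * v for k, v in st_.degree_histogram.items()) == 2 * st_.n_edges
    assert sum(st_.degree_histogram.values()) == st_.n_nodes
    assert st_.density == pytest.approx(
        2 * st_.n_edges / (st_.n_nodes * (st_.n_nodes - 1))
    )


def _toy_network(nodes, edges, prevalence=None):
    return ComorbidityNetwork(
        nodes=list(nodes),
        edges=[EdgeRecord(a, b, 0.5, 0.001) for a, b in edges],
        stratum_label="toy",
        n_persons=100,
        node_prevalence=prevalence or {n: 0.1 for n in nodes},
    )


def test_complete_graph_saturates():
    nodes = list("abcde")
    edges = [(x, y) for i, x in enumerate(nodes) for y in nodes[i + 1 :]]
    st_ = network_stats(_toy_network(nodes, edges))
    assert st_.density == 1.0
    assert st_.degree_median == 4
    assert len(st_.hubs) == 5  # all nodes at the (constant) upper quartile


def test_even_degree_median():
    # path a-b-c-d plus edge b-d: degrees 1,2,2,3 -> median 2.0; q3 nearest-rank
    net = _toy_network("abcd", [("a", "b"), ("b", "c"), ("c", "d"), ("b", "d")])
    st_ = network_stats(net)
    assert st_.degree_median == 2.0
    assert st_.hub_threshold == 2  # nearest rank: ceil(0.75*4)=3rd smallest
    assert {h[0] for h in st_.hubs} == {"b", "c", "d"}


def test_hub_tie_break_by_prevalence():
    net = _toy_network(
        "abcd", [("a", "b"), ("c", "d"), ("a", "c"), ("b", "d")],
        prevalence={"a": 0.1, "b": 0.4, "c": 0.2, "d": 0.3},
    )
    st_ = network_stats(net)  # all degrees 2: hubs are everyone, sorted by prevalence
    assert [h[0] for h in st_.hubs] == ["b", "d", "c", "a"]


def test_density_undefined_single_node():
    with pytest.raises(DomainError):
        network_stats(_toy_network("a", []))


def test_hub_degree_share_star_and_saturation():
    # published-style stats view: hub set {center} of a 9-spoke star
    star = NetworkStats(
        n_nodes=10, n_edges=9, density=0.2, degree_median=1, degree_q1=1, degree_q3=1,
        mean_degree=1.8, degree_histogram={1: 9, 9: 1}, hub_threshold=9,
        hubs=[("center", 9, 0.5)],
    )
    assert hub_degree_share(star) == pytest.approx(0.5)
    nodes = list("abcde")
    edges = [(x, y) for i, x in enumerate(nodes) for y in nodes[i + 1 :]]
    st_ = network_stats(_toy_network(nodes, edges))
    assert hub_degree_share(st_) == pytest.approx(1.0)


def _stats_with_degrees(degrees):
    hist = {}
    for k in degrees:
        hist[int(k)] = hist.get(int(k), 0) + 1
    return NetworkStats(
        n_nodes=len(degrees), n_edges=int(sum(degrees)) // 2, density=0.1,
        degree_median=float(np.median(degrees)), degree_q1=0, degree_q3=0,
        mean_degree=float(np.mean(degrees)), degree_histogram=hist,
        hub_threshold=0, hubs=[],
    )


def test_scale_free_diagnostics_discriminates():
    rng = np.random.default_rng(23)
    geom_wins, zipf_wins = 0, 0
    for _ in range(20):
        geom = rng.geometric(0.25, size=500)
        if scale_free_diagnostics(_stats_with_degrees(geom)).loglik_difference <= 0:
            geom_wins += 1
        zipf = rng.zipf(2.2, size=500)
        if scale_free_diagnostics(_stats_with_degrees(zipf)).loglik_difference > 0:
            zipf_wins += 1
    assert geom_wins >= 18  # power law not favored under the geometric null
    assert zipf_wins >= 18  # and favored under a genuine power law


def test_scale_free_degenerate():
    report = scale_free_diagnostics(_stats_with_degrees([3] * 50))
    assert report.degenerate
    assert report.loglik_difference is None


def test_synthetic_networks_are_right_skewed(cohort_small, catalog):
    net = build_network([r for r in cohort_small if r.group == "copd"], catalog)
    report = scale_free_diagnostics(network_stats(net))
    assert report.skewness > 0


def test_bootstrap_constant_statistic_zero_width(cohort_small, catalog):
    sub = [r for r in cohort_small if r.group == "control"][:500]
    ci = bootstrap_network_statistic(sub, catalog, lambda s: 3.14, B=50, seed=1)
    assert ci.lower95 == ci.upper95 == pytest.approx(3.14)


def test_bootstrap_deterministic_and_stable(catalog, cohort_small):
    sub = [r for r in cohort_small if r.group == "control"]
    a = bootstrap_network_statistic(sub, catalog, "density", B=100, seed=5)
    b = bootstrap_network_statistic(sub, catalog, "density", B=100, seed=5)
    assert (a.lower95, a.upper95) == (b.lower95, b.upper95)
    c = bootstrap_network_statistic(sub, catalog, "density", B=100, seed=6)
    # different seeds: overlapping intervals with comparable widths
    assert max(a.lower95, c.lower95) < min(a.upper95, c.upper95)
    wa, wc = a.upper95 - a.lower95, c.upper95 - c.lower95
    assert abs(wa - wc) / max(wa, wc) < 0.2


def test_bootstrap_rejects_tiny_B(cohort_small, catalog):
    with pytest.raises(DomainError):
        bootstrap_network_statistic(cohort_small[:50], catalog, "density", B=1, seed=0)


def test_positive_only_and_bh_flags(small_catalog):
    rng = np.random.default_rng(31)
    x = make_independent_matrix(rng, 500, len(small_catalog))
    x[:, 2] = 1 - x[:, 1]  # strong negative pair
    full = build_network(x, small_catalog, 0.05)
    pos = build_network(x, small_catalog, 0.05, positive_only=True)
    assert all(e.weight > 0 for e in pos.edges)
    assert any(e.weight < 0 for e in full.edges)
    bh = build_network(x, small_catalog, 0.05, bh_correction=True)
    assert len(bh.edges) <= len(full.edges)


def test_network_exports_roundtrip(tmp_path, small_catalog):
    records, _ = simulate_cohort(GeneratorConfig(n_per_group=300, seed=2), small_catalog)
    net = build_network(records, small_catalog, 0.05)
    g = net.to_networkx()
    assert set(g.nodes) == set(net.nodes)
    assert g.number_of_edges() == len(net.edges)
    net.write_gexf(tmp_path / "n.gexf")
    net.write_graphml(tmp_path / "n.graphml")
    import networkx as nx

    back = nx.read_graphml(tmp_path / "n.graphml")
    assert back.number_of_edges() == len(net.edges)
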