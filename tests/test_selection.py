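"""Eigenvector centrality, KPP-Pos, ensemble aggregation, sufficiency cutoff."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import eigh

import pcanet as pn
from conftest import random_connected_network, random_network, star_network


def unit_model(te=0.0, ts=0.0, tm=0.0):
    return pn.DyadModel(te, ts, tm, 1.0, 1.0, 1.0, n_obs_dyads=1)


# ---------------------------------------------------------------------------
# eigenvector centrality
# ---------------------------------------------------------------------------


def test_star_center_dominates():
    net = star_network(4)
    scores = pn.eigenvector_scores(net)
    leaves = [scores[f"sl{i}"] for i in range(4)]
    assert scores["sc"] > max(leaves)
    assert max(leaves) - min(leaves) < 1e-12


def test_complete_graph_uniform_scores():
    ids = [f"v{i}" for i in range(6)]
    net = pn.Network(
        [pn.NodeRecord(i, True) for i in ids],
        [(a, b) for a, b in itertools.combinations(ids, 2)],
    )
    scores = pn.eigenvector_scores(net)
    for s in scores.values():
        assert s == pytest.approx(1 / math.sqrt(6), abs=1e-10)


def test_matches_dense_eigendecomposition():
    rng = np.random.default_rng(11)
    for _ in range(10):
        n = int(rng.integers(4, 13))
        net = random_connected_network(rng, n, 0.5)
        scores = pn.eigenvector_scores(net)
        A = net.adjacency_matrix().toarray()
        w, v = eigh(A)
        lead = np.abs(v[:, np.argmax(w)])
        lead /= np.linalg.norm(lead)
        mine = np.array([scores[i] for i in net.node_ids])
        assert np.max(np.abs(mine - lead)) < 1e-8


def test_scores_invariant_to_relabeling():
    rng = np.random.default_rng(5)
    net = random_connected_network(rng, 9, 0.4)
    relabel = {old: f"z{8 - k:02d}" for k, old in enumerate(net.node_ids)}
    renamed = pn.Network(
        [pn.NodeRecord(relabel[r.node_id], r.is_respondent) for r in net.nodes],
        [(relabel[u], relabel[v]) for u, v in net.edge_list()],
    )
    a = pn.eigenvector_scores(net)
    b = pn.eigenvector_scores(renamed)
    for old, new in relabel.items():
        assert a[old] == pytest.approx(b[new], abs=1e-9)


def test_empty_graph_raises():
    with pytest.raises(pn.EmptyGraphError):
        pn.eigenvector_scores(pn.Network([], []))


# ---------------------------------------------------------------------------
# top_m
# ---------------------------------------------------------------------------


def test_top_m_returns_all_when_m_equals_n():
    scores = {"a": 1.0, "b": 0.5, "c": 0.7}
    assert pn.top_m(scores, 3) == {"a", "b", "c"}
    with pytest.raises(ValueError):
        pn.top_m(scores, 4)


def test_top_m_ties_break_lexicographically():
    scores = {"d": 1.0, "b": 1.0, "c": 1.0, "a": 1.0}
    assert pn.top_m(scores, 2) == {"a", "b"}


@given(
    st.dictionaries(
        st.text(alphabet="abcdefgh", min_size=1, max_size=3),
        st.floats(0, 1, allow_nan=False),
        min_size=1,
        max_size=8,
    ),
    st.data(),
)
def test_top_m_matches_sort_then_slice(scores, data):
    m = data.draw(st.integers(1, len(scores)))
    oracle = set(
        sorted(scores, key=lambda k: (-scores[k], k))[:m]
    )
    assert pn.top_m(scores, m) == oracle


# ---------------------------------------------------------------------------
# KPP-Pos fitness
# ---------------------------------------------------------------------------


def test_star_center_fitness_closed_form():
    net = star_network(4)
    assert pn.kpp_fitness(net, {"sc"}) == pytest.approx(0.8)
    # leaf: center at 1, other leaves at 2 -> (1 + 3/2)/5
    assert pn.kpp_fitness(net, {"sl0"}) == pytest.approx((1 + 3 / 2) / 5)


def test_full_set_has_zero_fitness():
    net = star_network(3)
    assert pn.kpp_fitness(net, set(net.node_ids)) == 0.0
    with pytest.raises(ValueError):
        pn.kpp_fitness(net, set())


def _bfs_fitness_oracle(net, S):
    """Independent route: networkx BFS distances."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(net.node_ids)
    g.add_edges_from(net.edge_list())
    total = 0.0
    for j in net.node_ids:
        if j in S:
            continue
        d = min(
            (nx.shortest_path_length(g, s, j) for s in S if nx.has_path(g, s, j)),
            default=math.inf,
        )
        if math.isfinite(d) and d > 0:
            total += 1.0 / d
    return total / net.n_nodes


def test_fitness_matches_bfs_oracle():
    rng = np.random.default_rng(23)
    for _ in range(10):
        n = int(rng.integers(5, 11))
        net = random_network(rng, n, 0.35)
        ids = net.node_ids
        S = set(rng.choice(ids, size=int(rng.integers(1, 4)), replace=False))
        assert pn.kpp_fitness(net, S) == pytest.approx(_bfs_fitness_oracle(net, S))


# ---------------------------------------------------------------------------
# KPP-Pos selection
# ---------------------------------------------------------------------------


def test_kpp_selects_star_center():
    assert pn.kpp_select(star_network(4), 1) == {"sc"}


def test_kpp_two_stars_takes_both_centers():
    a, b = star_network(4, "a"), star_network(3, "b")
    net = pn.Network(a.nodes + b.nodes, a.edge_list() + b.edge_list())
    assert pn.kpp_select(net, 2) == {"ac", "bc"}


def test_kpp_never_below_greedy_seed():
    from pcanet.selection import _distance_matrix, _greedy_seed

    rng = np.random.default_rng(31)
    for _ in range(10):
        net = random_network(rng, 10, 0.3)
        D = _distance_matrix(net)
        members, _, greedy_fit = _greedy_seed(D, 3)
        chosen = pn.kpp_select(net, 3, kp_restarts=2, kp_max_sweeps=4, seed=1)
        assert pn.kpp_fitness(net, chosen) >= greedy_fit - 1e-12


def test_kpp_attains_exhaustive_optimum_on_small_graphs():
    rng = np.random.default_rng(17)
    hits = 0
    for _ in range(15):
        n = int(rng.integers(6, 11))
        net = random_network(rng, n, 0.35)
        m = int(rng.integers(2, 4))
        best = max(
            pn.kpp_fitness(net, set(S))
            for S in itertools.combinations(net.node_ids, m)
        )
        chosen = pn.kpp_select(net, m, seed=2)
        hits += pn.kpp_fitness(net, chosen) >= best - 1e-12
    assert hits >= 14


def test_kpp_m_equals_n_returns_everything():
    net = star_network(3)
    assert pn.kpp_select(net, net.n_nodes) == set(net.node_ids)


def test_kpp_deterministic_given_seed():
    rng = np.random.default_rng(41)
    net = random_network(rng, 12, 0.3)
    a = pn.kpp_select(net, 4, kp_restarts=3, seed=7)
    b = pn.kpp_select(net, 4, kp_restarts=3, seed=7)
    assert a == b


# ---------------------------------------------------------------------------
# ensemble aggregation and the sufficiency cutoff
# ---------------------------------------------------------------------------


def _tiny_ensemble(tiny_partial, M=6, seed=0):
    return pn.impute_ensemble(tiny_partial, unit_model(-0.4, 0.1, 0.0), M=M, seed=seed)


def test_counts_sum_to_m_times_M(tiny_partial):
    ens = _tiny_ensemble(tiny_partial)
    cfg = pn.SelectionConfig(algorithm="eigenvector", m=3, seed=0)
    counts = pn.aggregate_selections(ens, cfg)
    assert sum(counts.values()) == 3 * len(ens)


def test_counts_match_per_network_recount(tiny_partial):
    ens = _tiny_ensemble(tiny_partial, M=4)
    cfg = pn.SelectionConfig(algorithm="eigenvector", m=3, seed=0)
    counts = pn.aggregate_selections(ens, cfg)
    recount = {}
    for member in ens:
        for v in pn.top_m(pn.eigenvector_scores(member), 3):
            recount[v] = recount.get(v, 0) + 1
    assert counts == recount


def test_single_member_counts_are_indicators(tiny_partial):
    ens = _tiny_ensemble(tiny_partial, M=1)
    counts = pn.aggregate_selections(
        ens, pn.SelectionConfig(algorithm="eigenvector", m=4, seed=0)
    )
    assert set(counts.values()) == {1} and len(counts) == 4


def test_sufficiency_cutoff_scan_oracle():
    counts = {"a": 10, "b": 10, "c": 7, "d": 3, "e": 1, "f": 1}
    M, target = 10, 3
    cutoff, spca = pn.sufficiency_cutoff(counts, target, M)
    # exhaustive scan oracle with the tie rule (larger t preferred)
    best = min(
        range(M, 0, -1),
        key=lambda t: (abs(sum(c >= t for c in counts.values()) - target), -t),
    )
    assert cutoff == best
    assert spca == {v for v, c in counts.items() if c >= cutoff}


@given(
    st.dictionaries(
        st.text(alphabet="abcdefghij", min_size=1, max_size=2),
        st.integers(1, 8),
        min_size=1,
        max_size=10,
    ),
    st.integers(1, 10),
)
def test_sufficiency_cutoff_property(counts, target):
    M = 8
    cutoff, spca = pn.sufficiency_cutoff(counts, target, M)
    sizes = {t: sum(c >= t for c in counts.values()) for t in range(1, M + 1)}
    assert abs(sizes[cutoff] - target) == min(abs(s - target) for s in sizes.values())
    # ties resolved toward the larger threshold (smaller set)
    for t in range(cutoff + 1, M + 1):
        assert abs(sizes[t] - target) > abs(sizes[cutoff] - target)
    assert spca == {v for v, c in counts.items() if c >= cutoff}


def test_all_selected_everywhere_cutoff_is_M():
    counts = {v: 5 for v in "abcd"}
    cutoff, spca = pn.sufficiency_cutoff(counts, 4, 5)
    assert cutoff == 5 and spca == set("abcd")


# ---------------------------------------------------------------------------
# select_pcas
# ---------------------------------------------------------------------------


def test_zero_unobserved_dyads_perfectly_stable():
    """With no unobserved dyads every ensemble member equals the observed
    network, so eigenvector selection counts are all-or-nothing and the sPCA
    set equals the observed PCA set."""
    records = [pn.NodeRecord(f"r{i}", True) for i in range(6)]
    edges = [("r0", "r1"), ("r0", "r2"), ("r0", "r3"), ("r1", "r2"), ("r4", "r0"),
             ("r4", "r5")]
    net = pn.PartialNetwork(records, edges)
    ens = pn.impute_ensemble(net, unit_model(), M=7, seed=0)
    cfg = pn.SelectionConfig(algorithm="eigenvector", m=3, seed=0)
    result = pn.select_pcas(net, ens, cfg)
    assert set(result.counts.values()) == {7}
    assert result.spca_set == result.observed_set
    assert result.cutoff == 7


def test_selection_result_round_trip(tmp_path, tiny_partial):
    ens = _tiny_ensemble(tiny_partial, M=3)
    cfg = pn.SelectionConfig(algorithm="keyplayer", m=3, seed=5)
    result = pn.select_pcas(tiny_partial, ens, cfg)
    result.save(tmp_path / "sel.json")
    back = pn.SelectionResult.load(tmp_path / "sel.json")
    assert back == result
    comp = result.spca_composition
    assert comp["n"] == comp["n_respondent"] + comp["n_nonrespondent"]
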