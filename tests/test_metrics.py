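"""Expected influence, bridge EI, predictability and Walktrap communities."""

from itertools import combinations

import igraph as ig
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symptomnet import (
    bridge_expected_influence,
    expected_influence,
    centrality_table,
    predictability,
    two_group_split,
    walktrap,
)
from symptomnet.ggm import NetworkModel


def model_from_weights(w, labels=None):
    w = np.asarray(w, float)
    p = w.shape[0]
    return NetworkModel(
        weights=w,
        precision=np.eye(p),
        labels=labels or [f"X{i+1}" for i in range(p)],
        lambda_selected=0.1,
        gamma=0.5,
        lambda_path=np.array([0.1]),
        ebic_path=np.array([0.0]),
        n=100,
    )


def chain_3(w12=0.45, w23=0.35):
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w12
    w[1, 2] = w[2, 1] = w23
    return model_from_weights(w)


def test_empty_network_has_zero_expected_influence():
    assert np.array_equal(expected_influence(model_from_weights(np.zeros((4, 4)))), np.zeros(4))


def test_three_node_chain_expected_influence():
    ei = expected_influence(chain_3())
    assert ei == pytest.approx([0.45, 0.80, 0.35])


def test_negative_edge_decreases_both_endpoints():
    m = chain_3()
    before = expected_influence(m)
    m.weights[0, 2] = m.weights[2, 0] = -0.2
    after = expected_influence(m)
    assert after[0] == pytest.approx(before[0] - 0.2)
    assert after[2] == pytest.approx(before[2] - 0.2)
    assert after[1] == pytest.approx(before[1])


def test_single_community_means_zero_bridge_influence():
    m = chain_3()
    bei = bridge_expected_influence(m, groups=["g", "g", "g"])
    assert np.array_equal(bei, np.zeros(3))


def test_single_cross_edge_gives_both_endpoints_its_weight():
    w = np.zeros((5, 5))
    w[1, 3] = w[3, 1] = 0.10
    bei = bridge_expected_influence(model_from_weights(w), groups=["a", "a", "a", "b", "b"])
    assert bei == pytest.approx([0, 0.10, 0, 0.10, 0])


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_bridge_plus_within_equals_total_influence(seed):
    rng = np.random.default_rng(seed)
    p = rng.integers(3, 10)
    w = rng.normal(scale=0.2, size=(p, p))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    groups = rng.choice(["a", "b", "c"], size=p)
    m = model_from_weights(w)
    ei = expected_influence(m)
    bei = bridge_expected_influence(m, groups=groups)
    within = np.array(
        [(w[i] * (groups == groups[i])).sum() for i in range(p)]
    )
    assert np.allclose(bei + within, ei, atol=1e-12)


def test_two_group_split_from_item_labels():
    labels = ["MBI-1", "MBI-2", "D1", "D2"]
    assert list(two_group_split(labels)) == ["burnout", "burnout", "depression", "depression"]
    with pytest.raises(ValueError):
        two_group_split(["foo"])


def test_node_without_neighbors_has_zero_predictability():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.standard_normal((200, 3)), columns=["X1", "X2", "X3"])
    m = chain_3()
    m.weights[:] = 0
    assert np.array_equal(predictability(df, m), np.zeros(3))


def test_copy_of_sole_neighbor_is_fully_predictable():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(300)
    df = pd.DataFrame({"X1": x, "X2": x, "X3": rng.standard_normal(300)})
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 0.9
    r2 = predictability(df, model_from_weights(w))
    assert r2[0] >= 0.99 and r2[1] >= 0.99
    assert r2[2] == 0


def test_predictability_matches_independent_regression(study_table):
    """Mean neighbor-regression R2 agrees with an oracle least-squares redo."""
    from symptomnet import estimate_network, npn_transform

    transformed = npn_transform(study_table)
    model = estimate_network(transformed, npn=False, n_lambda=40)
    r2 = predictability(transformed, model)
    X = transformed.values.to_numpy()
    oracle = []
    for i in range(model.p):
        idx = np.flatnonzero(model.weights[i] != 0)
        if idx.size == 0:
            oracle.append(0.0)
            continue
        import numpy.linalg as la

        Z = np.column_stack([np.ones(len(X)), X[:, idx]])
        beta = la.solve(Z.T @ Z, Z.T @ X[:, i])
        resid = X[:, i] - Z @ beta
        oracle.append(1 - resid @ resid / ((X[:, i] - X[:, i].mean()) ** 2).sum())
    assert abs(r2.mean() - np.mean(oracle)) < 0.1
    assert np.all((r2 >= 0) & (r2 <= 1))


def weighted_modularity(w, membership):
    """Newman's weighted modularity, computed from scratch."""
    w = np.abs(w)
    p = w.shape[0]
    m2 = w.sum()  # 2m
    if m2 == 0:
        return 0.0
    k = w.sum(axis=1)
    q = 0.0
    for i in range(p):
        for j in range(p):
            if membership[i] == membership[j]:
                q += w[i, j] - k[i] * k[j] / m2
    return q / m2


def brute_force_best_modularity(w):
    """Exhaustive search over all set partitions (feasible for p <= 8)."""
    p = w.shape[0]

    def partitions(nodes):
        if not nodes:
            yield []
            return
        first, rest = nodes[0], nodes[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]
            yield [[first]] + part

    best = -np.inf
    for part in partitions(list(range(p))):
        membership = np.empty(p, int)
        for label, block in enumerate(part):
            membership[block] = label
        best = max(best, weighted_modularity(w, membership))
    return best


def two_clique_weights(strong=0.5, weak=0.05):
    w = np.zeros((8, 8))
    for block in (range(0, 4), range(4, 8)):
        for i, j in combinations(block, 2):
            w[i, j] = w[j, i] = strong
    w[3, 4] = w[4, 3] = weak
    return w


def test_two_cliques_split_into_two_communities():
    m = model_from_weights(two_clique_weights())
    ca = walktrap(m)
    assert ca.n_communities == 2
    assert len(set(ca.membership[:4])) == 1
    assert len(set(ca.membership[4:])) == 1
    # agrees with the exhaustive modularity optimum
    assert ca.modularity == pytest.approx(
        brute_force_best_modularity(m.weights), abs=1e-9
    )


def test_communities_never_span_disconnected_components():
    w = np.zeros((6, 6))
    w[0, 1] = w[1, 0] = 0.4
    w[1, 2] = w[2, 1] = 0.4
    w[3, 4] = w[4, 3] = 0.4
    w[4, 5] = w[5, 4] = 0.4
    ca = walktrap(model_from_weights(w))
    assert set(ca.membership[:3]).isdisjoint(set(ca.membership[3:]))


def test_isolated_nodes_become_singletons_with_warning():
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 0.5
    with pytest.warns(UserWarning, match="isolated"):
        ca = walktrap(model_from_weights(w))
    assert ca.membership[2] != ca.membership[3]
    assert ca.n_communities == 3


def test_edgeless_network_rejected():
    with pytest.raises(ValueError, match="at least one edge"):
        walktrap(model_from_weights(np.zeros((3, 3))))


def test_centrality_table_schema_and_zscores():
    labels = ["MBI-1", "MBI-2", "D1", "D2"]
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 0.5
    w[1, 2] = w[2, 1] = 0.2
    w[2, 3] = w[3, 2] = 0.4
    m = model_from_weights(w, labels=labels)
    tab = centrality_table(m)
    assert list(tab["node"]) == labels
    assert tab["z_expected_influence"].mean() == pytest.approx(0, abs=1e-12)
    assert tab["z_expected_influence"].std(ddof=0) == pytest.approx(1)
    # BEI defaults to the instrument split: only the MBI-2 -- D1 edge crosses
    assert tab["bridge_expected_influence"].to_numpy() == pytest.approx([0, 0.2, 0.2, 0])
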