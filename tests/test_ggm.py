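"""Graphical lasso, EBIC selection and partial-correlation conversion."""

import numpy as np
import pandas as pd
import pytest

from symptomnet import (
    correlation,
    ebic_select,
    estimate_network,
    glasso,
    precision_to_partials,
)
from symptomnet.ggm import CorrelationMatrix, lambda_path_for
from symptomnet.simulate import GeneratorConfig, simulate_dataset


def random_spd_corr(p, rng, strength=0.5):
    A = rng.standard_normal((p, p + 5))
    S = A @ A.T / (p + 5)
    d = np.sqrt(np.diag(S))
    R = strength * (S / np.outer(d, d)) + (1 - strength) * np.eye(p)
    np.fill_diagonal(R, 1.0)
    return R


def test_correlation_diagonal_and_antikeyed_duplicate():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(400)
    df = pd.DataFrame({"x": x, "neg": -x, "y": rng.standard_normal(400)})
    S = correlation(df)
    assert np.allclose(np.diag(S.values), 1.0)
    assert S.values[0, 1] == pytest.approx(-1.0)


def test_independent_columns_nearly_uncorrelated():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.standard_normal((10_000, 2)), columns=["a", "b"])
    S = correlation(df)
    assert abs(S.values[0, 1]) < 0.03


@pytest.mark.parametrize("p", [4, 5, 6])
def test_unpenalized_glasso_equals_direct_inversion(p):
    rng = np.random.default_rng(p)
    S = random_spd_corr(p, rng)
    theta = glasso(S, lam=0.0)
    assert np.allclose(theta, np.linalg.inv(S), atol=1e-4)


def test_full_shrinkage_gives_empty_network():
    rng = np.random.default_rng(7)
    S = random_spd_corr(5, rng)
    lam = np.abs(S - np.eye(5)).max()
    theta = glasso(S, lam=lam * 1.0001)
    w = precision_to_partials(theta)
    assert np.count_nonzero(w) == 0


def test_glasso_solution_is_locally_optimal():
    """The fitted precision beats 1,000 random perturbations on the penalized
    log-likelihood objective."""
    rng = np.random.default_rng(11)
    S = random_spd_corr(6, rng)
    lam = 0.08

    def objective(theta):
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0:
            return -np.inf
        penalty = lam * (np.abs(theta).sum() - np.abs(np.diag(theta)).sum())
        return logdet - np.trace(S @ theta) - penalty

    theta = glasso(S, lam=lam)
    base = objective(theta)
    for _ in range(1000):
        noise = rng.standard_normal((6, 6)) * 1e-3
        noise = (noise + noise.T) / 2
        assert objective(theta + noise) <= base + 1e-9


def test_edge_count_monotone_in_penalty():
    rng = np.random.default_rng(3)
    cfg = GeneratorConfig(
        n_respondents=600,
        blocks=[("A", 4, 0.25), ("B", 4, 0.2)],
        bridge_edges=[(0, 5, 0.2)],
        item_levels=[5] * 8,
        seed=3,
    )
    table, _ = simulate_dataset(cfg)
    S = correlation(pd.DataFrame(table.keyed()))
    path = lambda_path_for(S.values, n_lambda=20)
    counts = []
    for lam in path:
        w = precision_to_partials(glasso(S, lam))
        counts.append(np.count_nonzero(np.triu(w, 1)))
    assert all(a <= b for a, b in zip(counts, counts[1:]))


def test_identity_correlation_selects_empty_network():
    S = CorrelationMatrix(values=np.eye(6), n=500, labels=[f"x{i}" for i in range(6)])
    with pytest.warns(UserWarning, match="empty network"):
        model = ebic_select(S, gamma=0.5)
    assert model.edge_count() == 0


def test_heavier_ebic_gamma_never_adds_edges(small_table):
    df = small_table.keyed()
    m0 = estimate_network(df, gamma=0.0)
    m5 = estimate_network(df, gamma=0.5)
    assert m0.edge_count() >= m5.edge_count()


def test_partial_conversion_round_trips_sign_pattern():
    rng = np.random.default_rng(13)
    theta = random_spd_corr(6, rng)
    theta = np.linalg.inv(theta)
    w = precision_to_partials(theta)
    off = ~np.eye(6, dtype=bool)
    assert np.array_equal(np.sign(w[off]), -np.sign(theta[off]))


def test_three_node_partials_match_brute_force_inversion():
    rng = np.random.default_rng(17)
    S = random_spd_corr(3, rng)
    w = precision_to_partials(glasso(S, lam=0.0))
    # brute force: partial corr of (i,j) given k from the correlation entries
    for i, j, k in [(0, 1, 2), (0, 2, 1), (1, 2, 0)]:
        expected = (S[i, j] - S[i, k] * S[j, k]) / np.sqrt(
            (1 - S[i, k] ** 2) * (1 - S[j, k] ** 2)
        )
        assert w[i, j] == pytest.approx(expected, abs=1e-4)


def test_weights_are_symmetric_zero_diagonal(small_table):
    model = estimate_network(small_table.keyed())
    assert np.allclose(model.weights, model.weights.T)
    assert np.all(np.diag(model.weights) == 0)
    assert np.abs(model.weights).max() < 1


def test_array_shortcut_matches_full_estimator(small_table):
    """The warm-started array route and the full NetworkModel route select
    identical weights on the same input."""
    from symptomnet.ggm import estimate_weights

    df = small_table.keyed()
    model = estimate_network(df, n_lambda=30)
    w = estimate_weights(df.to_numpy(), n_lambda=30)
    assert np.allclose(model.weights, w, atol=1e-6)


def test_network_json_round_trip(tmp_path, small_table):
    model = estimate_network(small_table.keyed(), n_lambda=20)
    path = tmp_path / "net.json"
    model.to_json(path)
    from symptomnet.ggm import NetworkModel

    back = NetworkModel.from_json(path)
    assert np.allclose(back.weights, model.weights)
    assert back.labels == model.labels
    assert back.lambda_selected == model.lambda_selected


def test_independence_data_yield_near_empty_network():
    cfg = GeneratorConfig(
        n_respondents=2000,
        blocks=[("A", 5, 0.0), ("B", 5, 0.0)],
        item_levels=[4] * 10,
        seed=21,
    )
    table, _ = simulate_dataset(cfg)
    model = estimate_network(table)
    assert model.density() <= 0.05
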