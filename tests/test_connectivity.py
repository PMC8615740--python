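"""Seed-PLSC, weight matrices, thresholding and graph metrics."""

import numpy as np
import pandas as pd
import pytest

from mseplsc import (
    DegenerateRowError,
    ValidationError,
    WeightedGraph,
    edges_from_saliences,
    graph_metrics,
    hemisphere_summary,
    salience_to_weight_matrix,
    seed_plsc,
    split_seed,
    threshold_weights,
)
from oracles import graph_metrics_bruteforce, pearson_rows


def test_split_seed_counts_and_order(small_features):
    x, y = split_seed(small_features.data, ("F3", "F4"))
    assert list(y.columns) == ["F3", "F4"]
    assert x.shape[1] == 12 and "F3" not in x.columns
    # montage order preserved minus seeds
    assert list(x.columns)[:3] == ["AF3", "F7", "FC5"]
    x1, y1 = split_seed(small_features.data, ("AF3",))
    assert x1.shape[1] == 13 and list(y1.columns) == ["AF3"]


def test_split_seed_unknown_channel(small_features):
    with pytest.raises(ValidationError, match="Fz"):
        split_seed(small_features.data, ("Fz",))


def test_seed_plsc_shapes_and_rank(small_features):
    res = seed_plsc(small_features)
    assert res.decomposition.R.shape == (6, 12)
    assert res.decomposition.rank <= 6
    assert res.R_frame.index[0] == ("ASD", "F3")
    assert list(res.R_frame.columns) == list(res.X_seed.columns)
    assert np.abs(res.decomposition.R).max() <= 1 + 1e-12


def test_seed_plsc_self_correlated_channel(small_features):
    feats = small_features
    data = feats.data.copy()
    data["T8"] = data["F3"]  # make a non-seed channel mirror seed F3
    feats2 = type(feats)(data, feats.groups, feats.condition, feats.params)
    res = seed_plsc(feats2)
    col = res.R_frame["T8"]
    for g in ("ASD", "ADHD", "CONTROL"):
        assert col[(g, "F3")] == pytest.approx(1.0)


def test_edges_thresholding():
    idx = pd.MultiIndex.from_product(
        [["ASD"], ["F3", "F4"]], names=["group", "seed"]
    )
    conn = pd.DataFrame(
        [[0.2, -0.5], [0.582, 0.25]], index=idx, columns=["T7", "F8"]
    )
    edges = edges_from_saliences(conn, 0.3)
    assert len(edges) == 2
    weights = dict(zip(zip(edges["seed"], edges["channel"]), edges["weight"]))
    assert weights[("F4", "T7")] == pytest.approx(0.582)
    assert weights[("F3", "F8")] == pytest.approx(-0.5)  # sign retained
    assert len(edges_from_saliences(conn, 0.0)) == 4
    assert len(edges_from_saliences(conn * 0 + 0.2, 0.3)) == 0


def test_weight_matrix_extremes_and_oracle(rng):
    base = rng.standard_normal(6)
    V = pd.DataFrame(
        [base, base, -base, rng.standard_normal(6)],
        index=["a", "b", "c", "d"],
    )
    g = salience_to_weight_matrix(V)
    assert g.weights[0, 1] == pytest.approx(1.0)
    assert g.weights[0, 2] == pytest.approx(-1.0)
    assert np.diag(g.weights).max() == 0.0
    V2 = pd.DataFrame(rng.standard_normal((12, 6)),
                      index=[f"ch{i}" for i in range(12)])
    W = salience_to_weight_matrix(V2).weights
    expected = pearson_rows(V2.to_numpy())
    np.testing.assert_allclose(W, expected, atol=1e-12)


def test_weight_matrix_degenerate_row(rng):
    V = pd.DataFrame([np.ones(5), rng.standard_normal(5)], index=["flat", "ok"])
    with pytest.raises(DegenerateRowError, match="flat"):
        salience_to_weight_matrix(V)


def _triangle(w01, w02, w12):
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = w01
    W[0, 2] = W[2, 0] = w02
    W[1, 2] = W[2, 1] = w12
    return WeightedGraph(["A", "B", "C"], W)


def test_threshold_modes():
    g = _triangle(0.9, 0.5, 0.1)
    assert threshold_weights(g, "absolute", 0.2).n_edges == 2
    assert threshold_weights(g, "proportional", 1 / 3).n_edges == 1
    np.testing.assert_array_equal(
        threshold_weights(g, "proportional", 1.0).weights, g.weights
    )
    with pytest.raises(ValidationError):
        threshold_weights(g, "absolute", 1.5)
    with pytest.raises(ValidationError):
        threshold_weights(g, "nonsense", 0.2)


def test_threshold_monotonicity(rng):
    W = rng.uniform(-1, 1, (8, 8))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0)
    g = WeightedGraph(list("abcdefgh"), W)
    prev = g.n_edges
    for t in (0.1, 0.3, 0.5, 0.7, 0.9):
        cur = threshold_weights(g, "absolute", t).n_edges
        assert cur <= prev
        prev = cur


def test_graph_metrics_complete_triangle():
    m = graph_metrics(_triangle(0.5, 0.5, 0.5))
    assert list(m.per_node["degree"]) == [2, 2, 2]
    np.testing.assert_allclose(m.per_node["strength"], 1.0)
    np.testing.assert_allclose(m.per_node["betweenness"], 0.0)
    assert m.density == pytest.approx(1.0)


def test_graph_metrics_path_hub():
    m = graph_metrics(_triangle(0.5, 0.0, 0.5))  # path A - B - C
    assert m.per_node.loc["B", "betweenness"] == pytest.approx(1.0)
    assert m.per_node.loc["A", "betweenness"] == 0.0
    assert m.density == pytest.approx(2 / 3)


def test_graph_metrics_match_bruteforce_oracle(rng):
    for _ in range(5):
        W = rng.uniform(-1, 1, (12, 12))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        g = threshold_weights(
            WeightedGraph([f"n{i}" for i in range(12)], W), "absolute", 0.35
        )
        m = graph_metrics(g)
        deg, stren, dens, bc = graph_metrics_bruteforce(g.weights)
        np.testing.assert_array_equal(m.per_node["degree"], deg)
        np.testing.assert_allclose(m.per_node["strength"], stren, atol=1e-12)
        assert m.density == pytest.approx(dens)
        np.testing.assert_allclose(m.per_node["betweenness"], bc, atol=1e-12)


def test_graph_metrics_empty_graph():
    g = _triangle(0.0, 0.0, 0.0)
    m = graph_metrics(g)
    assert m.density == 0.0
    assert (m.per_node == 0).all().all()


def test_weighted_graph_validation():
    with pytest.raises(ValidationError):
        WeightedGraph(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]))  # asymmetric
    with pytest.raises(ValidationError):
        WeightedGraph(["a", "b"], np.array([[1.0, 0.5], [0.5, 0.0]]))  # diag


def test_hemisphere_summary_partitions_edges(small_features):
    res = seed_plsc(small_features)
    edges = edges_from_saliences(res.R_frame, 0.0)
    summary = hemisphere_summary(edges)
    # every (group, seed, channel) edge lands in exactly one cell
    assert summary["n_edges"].sum() == len(edges)
    assert set(summary["pairing"]) == {"same", "different"}
    # F3 is left: F3-T7 same-hemisphere, F3-T8 different
    assert (summary.groupby("pairing")["n_edges"].sum() > 0).all()
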