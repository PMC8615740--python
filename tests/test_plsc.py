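"""Behavior PLSC: normalization, stacked correlations, SVD, scores, permutation."""

import numpy as np
import pandas as pd
import pytest

from mseplsc import (
    AlignmentError,
    DegenerateColumnError,
    FeatureMatrix,
    GroupedDesign,
    MSEParams,
    SubjectBehavior,
    ValidationError,
    behavior_matrix,
    behavior_plsc,
    behavior_scores,
    brain_scores,
    build_correlation_matrix,
    decompose,
    emotional_state_mean,
    normalize_within_group,
    permutation_test,
)


def _design(sizes=(4, 4, 4)):
    labels = sum(([g] * n for g, n in zip(("ASD", "ADHD", "CONTROL"), sizes)), [])
    return GroupedDesign(tuple(labels))


def _row(v, a, d):
    return SubjectBehavior("s", "ASD", "valid", 30.0, v, a, d, 50.0)


@pytest.mark.parametrize("sam, expected", [
    ((5, 5, 5), 5.0),
    ((1, 9, 5), 5.0),
    ((2, 4, 6), 4.0),
])
def test_emotional_state_mean(sam, expected):
    assert emotional_state_mean(_row(*sam)) == expected


def test_emotional_state_mean_subset():
    assert emotional_state_mean(_row(1, 9, 5), subset=("arousal",)) == 9.0
    with pytest.raises(ValidationError):
        emotional_state_mean(_row(1, 9, 5), subset=("strength",))


def test_design_validation():
    with pytest.raises(ValidationError):
        GroupedDesign(("ASD", "ADHD", "ASD", "ADHD"))  # not contiguous
    with pytest.raises(ValidationError):
        GroupedDesign(("ASD", "ASD", "ADHD"))  # singleton group
    d = _design((2, 3, 2))
    assert d.groups == ("ASD", "ADHD", "CONTROL")
    assert d.block("ADHD") == slice(2, 5)


def test_normalize_within_group_definition():
    d = GroupedDesign(("ASD",) * 3)
    z = normalize_within_group(np.array([[1.0], [2.0], [3.0]]), d)
    np.testing.assert_allclose(
        z[:, 0], [-1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)], atol=1e-15
    )
    # idempotence
    np.testing.assert_allclose(normalize_within_group(z, d), z, atol=1e-15)


def test_normalize_within_group_properties(rng):
    d = _design((5, 7, 4))
    Z = normalize_within_group(rng.standard_normal((16, 6)), d)
    for _, sl in d.blocks():
        np.testing.assert_allclose(Z[sl].mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose((Z[sl] ** 2).sum(axis=0), 1, atol=1e-12)


def test_normalize_constant_column_errors():
    d = _design((2, 2, 2))
    M = np.ones((6, 2))
    M[:, 1] = np.arange(6)
    M[0:2, 1] = 7.0  # constant within ASD only
    with pytest.raises(DegenerateColumnError, match="ASD"):
        normalize_within_group(M, d)


def test_correlation_matrix_blocks_and_extremes(rng):
    d = _design((6, 6, 6))
    X = rng.standard_normal((18, 5))
    Y = np.empty((18, 3))
    Y[:, 0] = X[:, 2]          # perfectly correlated with channel 2
    Y[:, 1] = -X[:, 0]         # perfectly anti-correlated with channel 0
    Y[:, 2] = rng.standard_normal(18)
    Zx = normalize_within_group(X, d)
    Zy = normalize_within_group(Y, d)
    R = build_correlation_matrix(Zx, Zy, d)
    assert R.shape == (9, 5)
    assert np.abs(R).max() <= 1 + 1e-12
    for g in range(3):
        assert R[3 * g + 0, 2] == pytest.approx(1.0)
        assert R[3 * g + 1, 0] == pytest.approx(-1.0)


def test_correlation_of_independent_columns_is_small(rng):
    d = GroupedDesign(("ASD",) * 2000)
    X = rng.standard_normal((2000, 3))
    Y = rng.standard_normal((2000, 3))
    R = build_correlation_matrix(
        normalize_within_group(X, d), normalize_within_group(Y, d), d
    )
    assert np.abs(R).max() < 0.05


def test_decompose_identity_and_invariants():
    dec = decompose(np.eye(2))
    np.testing.assert_allclose(dec.singular_values, [1.0, 1.0])
    np.testing.assert_allclose(dec.explained_variance, [50.0, 50.0])
    assert dec.inertia == pytest.approx(2.0)


def test_decompose_matches_eigensolver_and_reconstructs(rng):
    R = rng.standard_normal((9, 14))
    dec = decompose(R)
    eigs = np.sort(np.linalg.eigvalsh(R @ R.T))[::-1]
    np.testing.assert_allclose(dec.singular_values ** 2, eigs, atol=1e-10)
    np.testing.assert_allclose(
        dec.U @ np.diag(dec.singular_values) @ dec.V.T, R, atol=1e-10
    )
    np.testing.assert_allclose(dec.U.T @ dec.U, np.eye(dec.rank), atol=1e-12)
    np.testing.assert_allclose(dec.V.T @ dec.V, np.eye(dec.rank), atol=1e-12)
    assert (dec.singular_values ** 2).sum() == pytest.approx(
        (R ** 2).sum(), rel=1e-12
    )
    assert dec.explained_variance.sum() == pytest.approx(100.0)
    # canonical sign: the dominant entry of each V column is positive
    for l in range(dec.rank):
        assert dec.V[np.argmax(np.abs(dec.V[:, l])), l] > 0


def test_decompose_rejects_nonfinite():
    with pytest.raises(ValidationError):
        decompose(np.array([[1.0, np.nan]]))


def test_channel_permutation_equivariance(rng):
    """Relabeling channels permutes V's rows and leaves the spectrum alone."""
    R = rng.standard_normal((6, 8))
    perm = rng.permutation(8)
    d1, d2 = decompose(R), decompose(R[:, perm])
    np.testing.assert_allclose(d1.singular_values, d2.singular_values, atol=1e-12)
    np.testing.assert_allclose(d1.V[perm], d2.V, atol=1e-10)


def test_brain_scores_shapes_and_projection_bound(rng):
    Zx = rng.standard_normal((12, 5))
    assert np.allclose(brain_scores(Zx, np.eye(5)), Zx)
    dec = decompose(rng.standard_normal((3, 5)))
    L = brain_scores(Zx, dec.V)
    assert np.linalg.norm(L) <= np.linalg.norm(Zx) + 1e-12
    with pytest.raises(AlignmentError):
        brain_scores(Zx, np.eye(4))


def test_behavior_scores_blockwise(rng):
    d = _design((2, 2, 2))
    Zy = rng.standard_normal((6, 3))
    U = np.vstack([np.eye(3)] * 3)  # identity block per group
    L = behavior_scores(Zy, U, d)
    np.testing.assert_allclose(L, Zy)
    with pytest.raises(AlignmentError):
        behavior_scores(Zy, np.eye(3), d)


def test_single_group_latent_identity(rng):
    """With one group, L_X' L_Y equals the diagonal of singular values."""
    d = GroupedDesign(("ASD",) * 30)
    Zx = normalize_within_group(rng.standard_normal((30, 6)), d)
    Zy = normalize_within_group(rng.standard_normal((30, 3)), d)
    R = build_correlation_matrix(Zx, Zy, d)
    dec = decompose(R)
    Lx = brain_scores(Zx, dec.V)
    Ly = behavior_scores(Zy, dec.U, d)
    np.testing.assert_allclose(
        Lx.T @ Ly, np.diag(dec.singular_values), atol=1e-10
    )


def _toy_features(rng, sizes=(5, 5, 5)):
    labels = sum(([g] * n for g, n in zip(("ASD", "ADHD", "CONTROL"), sizes)), [])
    n = len(labels)
    data = pd.DataFrame(
        rng.standard_normal((n, 6)),
        index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
        columns=["AF3", "F3", "FC6", "F4", "O1", "AF4"],
    )
    return FeatureMatrix(data, pd.Series(labels, index=data.index), "valid",
                         MSEParams(tau_max=1))


def test_behavior_plsc_end_to_end_labels(rng):
    feats = _toy_features(rng)
    Y = pd.DataFrame(
        rng.standard_normal((15, 3)), index=feats.data.index,
        columns=["age", "emotional_state", "confidence"],
    )
    res = behavior_plsc(feats, Y)
    assert res.decomposition.R.shape == (9, 6)
    assert res.R_frame.index[0] == ("ASD", "age")
    assert res.R_frame.index[-1] == ("CONTROL", "confidence")
    assert res.L_X.shape == (15, res.decomposition.rank)
    assert res.L_Y.shape == (15, res.decomposition.rank)


def test_behavior_matrix_alignment_and_duplicates():
    rows = [
        SubjectBehavior("a", "ASD", "valid", 30.0, 5, 5, 5, 50.0),
        SubjectBehavior("b", "ASD", "valid", 31.0, 4, 6, 5, 60.0),
    ]
    Y = behavior_matrix(rows, "valid", ["b", "a"])
    assert list(Y.index) == ["b", "a"]
    assert Y.loc["a", "age"] == 30.0
    with pytest.raises(AlignmentError):
        behavior_matrix(rows, "valid", ["a", "c"])
    with pytest.raises(ValidationError):
        behavior_matrix(rows + rows[:1], "valid", ["a"])


def test_permutation_perfect_association_attains_min_p(rng):
    """When Y is copied from X, no permutation can match the observed inertia."""
    labels = ("ASD",) * 20 + ("ADHD",) * 20 + ("CONTROL",) * 20
    d = GroupedDesign(labels)
    X = rng.standard_normal((60, 6))
    Y = X[:, :3].copy()
    res = permutation_test(X, Y, d, n_perm=199, seed=1)
    assert res.p_value == pytest.approx(1 / 200)
    assert (res.null_inertias < res.observed_inertia).all()


def test_permutation_null_p_is_moderate(rng):
    d = _design((8, 8, 8))
    res = permutation_test(
        rng.standard_normal((24, 5)), rng.standard_normal((24, 3)),
        d, n_perm=99, seed=2,
    )
    assert 0.01 <= res.p_value <= 1.0
    assert res.null_inertias.shape == (99,)


def test_permutation_global_scope_runs(rng):
    d = _design((4, 4, 4))
    res = permutation_test(
        rng.standard_normal((12, 4)), rng.standard_normal((12, 3)),
        d, n_perm=19, seed=3, scope="global",
    )
    assert res.scope == "global"


def test_permutation_rejects_bad_n_perm(rng):
    d = _design((2, 2, 2))
    with pytest.raises(ValidationError):
        permutation_test(np.ones((6, 2)), np.ones((6, 2)), d, n_perm=0)
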