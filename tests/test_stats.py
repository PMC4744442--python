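"""Standardization, slice moments, and the four SAVE-type statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sdrgsa as sg
from sdrgsa.stats import pooled_covariance

from _oracles import brute_slice_moments, brute_T, brute_V, brute_V_scalar
from conftest import random_expression


def _moments(X, labels, H, mode="exact", ddof=0):
    Z = sg.standardize(X, mode=mode, ddof=ddof)
    return sg.slice_moments(Z, sg.SlicePartition(labels, H=H))


# ---------------------------------------------------------------------------
# standardize


def test_exact_standardization_gives_identity_pooled_covariance(rng):
    X = random_expression(rng, 4, 2)
    Z = sg.standardize(X, mode="exact")
    assert np.abs(Z.values.mean(axis=0)).max() < 1e-10
    np.testing.assert_allclose(pooled_covariance(Z.values), np.eye(2), atol=1e-8)


def test_exact_mode_rejects_p_ge_n(rng):
    X = random_expression(rng, 30, 100)
    with pytest.raises(sg.SingularMatrixError):
        sg.standardize(X, mode="exact")


def test_shrinkage_handles_p_gt_n(rng):
    X = random_expression(rng, 30, 100)
    Z = sg.standardize(X, mode="shrinkage")
    assert np.all(np.isfinite(Z.values))
    # the shrunk covariance implied by the transform is positive definite
    shrunk = np.linalg.inv(Z.transform @ Z.transform)
    assert np.linalg.eigvalsh(shrunk)[0] > 0
    assert np.abs(Z.values.mean(axis=0)).max() < 1e-10


def test_auto_mode_selects_exact_then_falls_back(rng):
    assert sg.standardize(random_expression(rng, 50, 5), mode="auto").mode == "exact"
    assert (
        sg.standardize(random_expression(rng, 10, 20), mode="auto").mode == "shrinkage"
    )


def test_identity_mode_is_centering_only(rng):
    X = random_expression(rng, 8, 3)
    Z = sg.standardize(X, mode="identity")
    np.testing.assert_allclose(Z.values, X.values - X.values.mean(axis=0))


def test_ddof_flag_consistent(rng):
    X = random_expression(rng, 10, 3)
    Z = sg.standardize(X, mode="exact", ddof=1)
    n = 10
    S = Z.values.T @ (Z.values - Z.values.mean(0)) / (n - 1)
    np.testing.assert_allclose(S, np.eye(3), atol=1e-8)


# ---------------------------------------------------------------------------
# slice moments


def test_single_slice_reproduces_pooled_moments(rng):
    X = random_expression(rng, 9, 3)
    m = _moments(X, np.ones(9, dtype=int), H=1)
    np.testing.assert_allclose(m.means, 0, atol=1e-10)
    np.testing.assert_allclose(m.covariances[0], np.eye(3), atol=1e-8)


def test_duplicated_block_gives_identical_slices(rng):
    block = rng.standard_normal((3, 2))
    Z = sg.StandardizedMatrix(
        np.vstack([block, block]), np.eye(2), np.zeros(2), "identity"
    )
    m = sg.slice_moments(Z, sg.SlicePartition([1, 1, 1, 2, 2, 2], H=2))
    np.testing.assert_allclose(m.means[0], m.means[1])
    np.testing.assert_allclose(m.covariances[0], m.covariances[1])


@pytest.mark.parametrize("ddof", [0, 1])
def test_slice_moments_match_brute_force_loop(rng, ddof):
    Zv = rng.standard_normal((10, 3))
    labels = np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2])
    Z = sg.StandardizedMatrix(Zv, np.eye(3), np.zeros(3), "identity", ddof=ddof)
    m = sg.slice_moments(Z, sg.SlicePartition(labels, H=2))
    means, covs = brute_slice_moments(Zv, labels, 2, ddof=ddof)
    np.testing.assert_allclose(m.means, means, atol=1e-12)
    np.testing.assert_allclose(m.covariances, covs, atol=1e-12)


def test_degenerate_slice_rejected():
    with pytest.raises(sg.InvalidInputError, match=">= 2"):
        sg.SlicePartition([1, 1, 2], H=2)


# ---------------------------------------------------------------------------
# statistics: closed forms


def test_T_and_V_vanish_on_single_slice(rng):
    X = random_expression(rng, 8, 3)
    m = _moments(X, np.ones(8, dtype=int), H=1)
    T, Ti = sg.statistic_T(m)
    assert T == pytest.approx(0.0, abs=1e-12)
    assert sg.statistic_V(m) == pytest.approx(0.0, abs=1e-12)
    mi = _moments(X, np.ones(8, dtype=int), H=1, mode="identity")
    assert sg.statistic_T_star(mi)[0] == pytest.approx(0.0, abs=1e-12)
    assert sg.statistic_V_star(mi) == pytest.approx(0.0, abs=1e-12)


def test_scalar_closed_form_T():
    # p=1, two equal slices with variances 1.2 and 0.8 around pooled 1
    m = sg.SliceMoments(
        means=np.zeros((2, 1)),
        covariances=np.array([[[1.2]], [[0.8]]]),
        pooled_cov=np.eye(1),
        proportions=np.array([0.5, 0.5]),
    )
    T, Ti = sg.statistic_T(m)
    assert T == pytest.approx(0.04, abs=1e-12)
    assert Ti[0] == pytest.approx(0.04, abs=1e-12)


def test_scalar_closed_form_V():
    # p=1: variances (4, 1), means (0.3, -0.3) -> 0.5*(1+0.09)+0.5*(0+0.09)
    m = sg.SliceMoments(
        means=np.array([[0.3], [-0.3]]),
        covariances=np.array([[[4.0]], [[1.0]]]),
        pooled_cov=np.eye(1),
        proportions=np.array([0.5, 0.5]),
    )
    assert sg.statistic_V(m) == pytest.approx(0.59, abs=1e-12)
    assert sg.statistic_V(m) == pytest.approx(
        brute_V_scalar([4.0, 1.0], [0.3, -0.3], [0.5, 0.5]), abs=1e-12
    )


def test_contract_violation_on_unstandardized_moments(rng):
    X = random_expression(rng, 12, 3)
    mi = _moments(X, np.array([1] * 6 + [2] * 6), H=2, mode="identity")
    with pytest.raises(sg.ContractViolationError):
        sg.statistic_T(mi)
    with pytest.raises(sg.ContractViolationError):
        sg.statistic_V(mi)
    mz = _moments(X, np.array([1] * 6 + [2] * 6), H=2, mode="exact")
    with pytest.raises(sg.ContractViolationError):
        sg.statistic_T_star(mz)


# ---------------------------------------------------------------------------
# statistics vs brute-force oracles on small instances


@pytest.mark.parametrize("seed", range(8))
def test_matrix_forms_match_elementwise_oracles(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 13))
    p = int(rng.integers(1, 5))
    H = int(rng.integers(1, 4))
    if n < 2 * H + (p + 1) * (H > 0):  # keep slices comfortably filled
        n = 4 * H + p
    X = random_expression(rng, n, p)
    labels = np.sort(rng.integers(1, H + 1, n))
    # force every slice to have >= 2 members
    labels[: 2 * H] = np.repeat(np.arange(1, H + 1), 2)
    labels = np.sort(labels)

    mode = "exact" if n > p + 1 else "identity"
    m = _moments(X, labels, H=H, mode=mode)
    T, Ti = (sg.statistic_T(m) if mode == "exact" else sg.statistic_T_star(m))
    bT, bTi = brute_T(m.covariances, m.pooled_cov, m.proportions)
    assert T == pytest.approx(bT, rel=1e-10, abs=1e-10)
    np.testing.assert_allclose(Ti, bTi, atol=1e-10)

    V = sg.statistic_V(m) if mode == "exact" else sg.statistic_V_star(m)
    bV = brute_V(m.covariances, m.means, m.pooled_cov, m.proportions)
    assert V == pytest.approx(bV, rel=1e-8, abs=1e-10)


def test_T_star_equals_T_on_prestandardized_data(rng):
    X = random_expression(rng, 10, 4)
    Z = sg.standardize(X, mode="exact")
    # re-wrap the standardized values as a fresh expression matrix
    X2 = sg.ExpressionMatrix(Z.values, X.gene_ids, X.sample_ids)
    labels = np.array([1] * 5 + [2] * 5)
    mz = _moments(X2, labels, H=2, mode="exact")
    mi = _moments(X2, labels, H=2, mode="identity")
    T, _ = sg.statistic_T(mz)
    Ts, _ = sg.statistic_T_star(mi)
    assert Ts == pytest.approx(T, abs=1e-10)
    assert sg.statistic_V_star(mi) == pytest.approx(sg.statistic_V(mz), abs=1e-10)


# ---------------------------------------------------------------------------
# invariants


@given(st.integers(0, 10_000))
def test_nonnegativity_and_decomposition(seed):
    rng = np.random.default_rng(seed)
    n, p, H = 12, 3, 2
    X = random_expression(rng, n, p)
    labels = np.array([1] * 6 + [2] * 6)
    for mode, t_fn, v_fn in [
        ("exact", sg.statistic_T, sg.statistic_V),
        ("identity", sg.statistic_T_star, sg.statistic_V_star),
    ]:
        m = _moments(X, labels, H=H, mode=mode)
        T, Ti = t_fn(m)
        assert T >= 0 and np.all(Ti >= -1e-15)
        assert T == pytest.approx(Ti.sum(), rel=1e-12, abs=1e-15)
        assert v_fn(m) >= 0


@pytest.mark.parametrize("seed", range(4))
def test_affine_invariance_of_T_and_V(seed):
    rng = np.random.default_rng(seed)
    n, p = 15, 3
    X = random_expression(rng, n, p)
    A = rng.standard_normal((p, p)) + 2 * np.eye(p)  # invertible w.h.p.
    assert abs(np.linalg.det(A)) > 1e-6
    b = rng.standard_normal(p)
    X2 = sg.ExpressionMatrix(X.values @ A.T + b, X.gene_ids, X.sample_ids)
    labels = np.array([1] * 7 + [2] * 8)
    m1 = _moments(X, labels, H=2, mode="exact")
    m2 = _moments(X2, labels, H=2, mode="exact")
    assert sg.statistic_T(m1)[0] == pytest.approx(sg.statistic_T(m2)[0], abs=1e-8)
    assert sg.statistic_V(m1) == pytest.approx(sg.statistic_V(m2), abs=1e-8)


def test_gene_permutation_invariance(rng):
    n, p = 14, 4
    X = random_expression(rng, n, p)
    perm = rng.permutation(p)
    X2 = sg.ExpressionMatrix(
        X.values[:, perm], [X.gene_ids[j] for j in perm], X.sample_ids
    )
    labels = np.array([1] * 7 + [2] * 7)
    for mode, t_fn, v_fn in [
        ("exact", sg.statistic_T, sg.statistic_V),
        ("identity", sg.statistic_T_star, sg.statistic_V_star),
    ]:
        m1 = _moments(X, labels, H=2, mode=mode)
        m2 = _moments(X2, labels, H=2, mode=mode)
        T1, Ti1 = t_fn(m1)
        T2, Ti2 = t_fn(m2)
        assert T2 == pytest.approx(T1, rel=1e-9)
        np.testing.assert_allclose(Ti2, Ti1[perm], rtol=1e-9, atol=1e-12)
        assert v_fn(m2) == pytest.approx(v_fn(m1), rel=1e-9)


def test_null_expectation_of_T_decreases_with_n():
    """With Z independent of slices, within-slice covariances converge to
    the pooled covariance, so E[T] shrinks as n grows at fixed H and p."""
    p, H = 3, 2
    means = {}
    for n in (24, 120):
        vals = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            X = random_expression(rng, n, p)
            labels = np.repeat([1, 2], n // 2)
            T, _ = sg.statistic_T(_moments(X, labels, H=H))
            vals.append(T)
        means[n] = np.mean(vals)
    assert means[120] < means[24] / 2
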