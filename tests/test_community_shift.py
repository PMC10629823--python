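import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from sedadrivers.community_shift import (
    bh_adjust,
    bray_curtis,
    kruskal_wallis,
    permanova_oneway,
    permanova_pairwise,
    shannon,
)


# ------------------------------------------------------------------- shannon


@pytest.mark.parametrize(
    "counts,expected",
    [([5, 5], 1.0), ([10], 0.0), ([1, 1, 2], 1.5)],
)
def test_shannon_examples(counts, expected):
    assert shannon(counts) == pytest.approx(expected)


def test_shannon_all_zero_errors():
    with pytest.raises(ValueError):
        shannon([0, 0])


def test_shannon_maximal_at_uniform():
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = rng.integers(2, 12)
        v = rng.uniform(0.1, 10, size=n)
        assert shannon(v) <= shannon(np.ones(n)) + 1e-12


# -------------------------------------------------------------- kruskal-wallis


def test_kruskal_identical_groups_h_zero():
    h, p = kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])
    assert h == 0.0 and p == 1.0


def test_kruskal_separated_groups():
    h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
    assert h == pytest.approx(3.857, abs=1e-3)


def test_kruskal_single_group_errors():
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2, 3]])


# ---------------------------------------------------------------- bray-curtis


def test_bray_curtis_identical_rows_zero():
    d = bray_curtis(np.array([[1.0, 2.0], [1.0, 2.0]]))
    assert d[0, 1] == 0.0


def test_bray_curtis_disjoint_supports_one():
    d = bray_curtis(np.array([[1.0, 0.0], [0.0, 3.0]]))
    assert d[0, 1] == 1.0


def test_bray_curtis_direct_formula():
    d = bray_curtis(np.array([[1.0, 2.0], [2.0, 1.0]]))
    assert d[0, 1] == pytest.approx(1 / 3)


def test_bray_curtis_all_zero_pair_warns_zero():
    with pytest.warns(UserWarning):
        d = bray_curtis(np.array([[0.0, 0.0], [0.0, 0.0]]))
    assert d[0, 1] == 0.0


# ------------------------------------------------------------------ PERMANOVA


def _gower_r2(points, labels):
    """Independent R2 oracle via explicit Gower centering."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    d2 = np.array([[np.sum((a - b) ** 2) for b in points] for a in points])
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ d2 @ J
    ss_total = np.trace(G)
    # hat matrix of the one-way design
    X = np.array([[1.0 if l == g else 0.0 for g in sorted(set(labels))] for l in labels])
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    ss_between = np.trace(H @ G @ H)
    return ss_between / ss_total


def test_permanova_exhaustive_two_distinct_pairs():
    # two groups of identical points, groups distinct: p = 2/6 over the
    # 6 distinct label assignments of 2v2
    pts = np.array([[0.0], [0.0], [1.0], [1.0]])
    dist = DistanceMatrix(
        [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], ids=list("abcd")
    )
    f, r2, p = permanova_oneway(dist, ["g1", "g1", "g2", "g2"], exhaustive=True)
    assert p == pytest.approx(2 / 6)
    assert r2 == pytest.approx(_gower_r2(pts, ["g1", "g1", "g2", "g2"]))
    assert r2 == pytest.approx(1.0)


def test_permanova_monte_carlo_matches_exhaustive():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(8, 3))
    pts[:4] += 1.2
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    dist = DistanceMatrix(d, ids=[str(i) for i in range(8)])
    labels = ["a"] * 4 + ["b"] * 4
    _f, _r2, p_ex = permanova_oneway(dist, labels, exhaustive=True)
    n_perm = 4000
    _f, _r2, p_mc = permanova_oneway(dist, labels, n_perm=n_perm, seed=1)
    sd = np.sqrt(p_ex * (1 - p_ex) / n_perm)
    assert abs(p_mc - p_ex) < 3 * sd + 2 / n_perm


def test_permanova_agrees_with_skbio_pseudo_f():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(10, 4))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    dist = DistanceMatrix(d, ids=[str(i) for i in range(10)])
    labels = ["a"] * 5 + ["b"] * 5
    f_ours, _r2, _p = permanova_oneway(dist, labels, n_perm=99, seed=0)
    res = skbio_permanova(dist, grouping=labels, permutations=99)
    assert f_ours == pytest.approx(res["test statistic"], rel=1e-10)


def test_permanova_null_rejection_rate_calibrated():
    rng = np.random.default_rng(9)
    n_draws, n_perm, alpha = 150, 99, 0.05
    rejections = 0
    for i in range(n_draws):
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dist = DistanceMatrix(d, ids=[str(j) for j in range(10)])
        _f, _r2, p = permanova_oneway(dist, ["a"] * 5 + ["b"] * 5, n_perm=n_perm, seed=i)
        rejections += p <= alpha
    rate = rejections / n_draws
    assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_draws)


def test_permanova_r2_invariant_to_sample_order():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(9, 2))
    pts[:4] += 1.0
    labels = np.array(["a"] * 4 + ["b"] * 5)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    ids = [str(i) for i in range(9)]
    _f, r2_a, _p = permanova_oneway(DistanceMatrix(d, ids=ids), labels, n_perm=49, seed=0)
    perm = rng.permutation(9)
    _f, r2_b, _p = permanova_oneway(
        DistanceMatrix(d[np.ix_(perm, perm)], ids=[ids[i] for i in perm]),
        labels[perm],
        n_perm=49,
        seed=0,
    )
    assert r2_a == pytest.approx(r2_b)


def test_permanova_pairwise_structure():
    rng = np.random.default_rng(4)
    pts = np.vstack([rng.normal(0, 1, (4, 2)), rng.normal(3, 1, (4, 2)), rng.normal(6, 1, (4, 2))])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    dist = DistanceMatrix(d, ids=[str(i) for i in range(12)])
    phases = ["SP"] * 4 + ["E"] * 4 + ["P"] * 4
    comps = permanova_pairwise(dist, phases, n_perm=199, seed=0)
    assert len(comps) == 3
    for c in comps:
        assert 0 <= c.r2 <= 1
        assert c.p_adj >= c.p_raw
        assert c.p_raw >= 1 / (c.n_permutations + 1)


def test_permanova_pairwise_skips_singleton_phase():
    dist = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float), ids=list("abc"))
    with pytest.warns(UserWarning, match="skipped"):
        comps = permanova_pairwise(dist, ["x", "x", "y"], n_perm=9, seed=0)
    assert comps == []


# ------------------------------------------------------------------------ BH


def _bh_oracle(p):
    """Direct step-up formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return np.minimum(adj, 1.0)


def test_bh_worked_example():
    assert bh_adjust([0.01, 0.02, 0.04]).tolist() == pytest.approx([0.03, 0.03, 0.04])


def test_bh_single_and_equal():
    assert bh_adjust([0.2]).tolist() == [0.2]
    assert bh_adjust([0.3, 0.3, 0.3]).tolist() == pytest.approx([0.3, 0.3, 0.3])


def test_bh_out_of_range_errors():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def test_bh_matches_direct_step_up_formula():
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 15))
        assert np.allclose(bh_adjust(p), _bh_oracle(p))
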