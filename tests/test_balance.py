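"""Samplers against brute-force oracles and hand-built configurations.

Every neighbor-based rule is cross-checked against an O(n^2) enumeration
on small 2-D toy sets, and the synthesis arithmetic is verified through
the provenance each sampler records.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p300balance.balance import (
    SamplerParams,
    adasyn,
    apply_sampler,
    borderline_smote,
    ncr,
    ros,
    rus,
    smote,
    svm_smote,
    tomek,
)
from p300balance.synth import generate_toy_2d

OVERSAMPLERS = ["ros", "smote", "b-smote", "svm-smote", "adasyn"]
UNDERSAMPLERS = ["rus", "ncr", "tomek"]


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_knn(X, i, k):
    """Indices of the k nearest neighbors of row i (self excluded),
    Euclidean, ties by index."""
    d = np.linalg.norm(X - X[i], axis=1)
    d[i] = np.inf
    return np.argsort(d, kind="stable")[:k]


def brute_knn_in_pool(X, x, pool_idx, k):
    d = np.linalg.norm(X[pool_idx] - x, axis=1)
    return pool_idx[np.argsort(d, kind="stable")[:k]]


def brute_danger(X, y, m):
    """Minority rows with more than half of their m-NN in the majority."""
    out = []
    for i in np.flatnonzero(y == 1):
        nb = brute_knn(X, i, m)
        if np.sum(y[nb] == 0) > m / 2:
            out.append(i)
    return np.asarray(out, dtype=int)


def brute_tomek_majority(X, y):
    """Majority members of mutual cross-class nearest-neighbor pairs."""
    nn = np.array([brute_knn(X, i, 1)[0] for i in range(len(y))])
    return np.asarray(
        sorted(
            i
            for i in np.flatnonzero(y == 0)
            if y[nn[i]] == 1 and nn[nn[i]] == i
        ),
        dtype=int,
    )


def brute_ncr_removed(X, y, k):
    """Two-stage neighborhood cleaning by direct enumeration, including the
    degenerate-case rule: if condensation would empty the majority, the
    majority survivor closest to the minority class is kept."""
    drop1 = [
        i
        for i in np.flatnonzero(y == 0)
        if np.sum(y[brute_knn(X, i, k)] == 1) > k / 2
    ]
    survivors = np.setdiff1d(np.arange(len(y)), drop1)
    Xs, ys = X[survivors], y[survivors]
    maj_pos = np.flatnonzero(ys == 0)
    drop2 = [
        survivors[j]
        for j in maj_pos
        if ys[brute_knn(Xs, j, 1)[0]] == 0
    ]
    if len(drop2) == len(maj_pos) and len(maj_pos) > 0:
        min_rows = Xs[ys == 1]
        dists = [np.linalg.norm(min_rows - Xs[j], axis=1).min() for j in maj_pos]
        drop2.remove(survivors[maj_pos[int(np.argmin(dists))]])
    return np.sort(np.concatenate([drop1, drop2]).astype(int))


# ---------------------------------------------------------------------------


@pytest.mark.parametrize("name", OVERSAMPLERS + UNDERSAMPLERS)
def test_fixed_seed_reproducible(name, toy_features):
    p = SamplerParams(seed=13)
    a = apply_sampler(name, toy_features.X, toy_features.y, p)
    b = apply_sampler(name, toy_features.X, toy_features.y, p)
    np.testing.assert_array_equal(a.X, b.X)
    np.testing.assert_array_equal(a.y, b.y)


@pytest.mark.parametrize("name", OVERSAMPLERS)
def test_oversamplers_preserve_originals_and_balance(name, toy_features):
    X, y = toy_features.X, toy_features.y
    res = apply_sampler(name, X, y, SamplerParams(seed=1))
    n = len(y)
    np.testing.assert_array_equal(res.X[:n], X)  # originals first, unchanged
    np.testing.assert_array_equal(res.y[:n], y)
    n_min = int(np.sum(res.y == 1))
    n_maj = int(np.sum(res.y == 0))
    if name == "adasyn":
        # ceiling excess allowed: minority >= majority, bounded by +1/point
        assert n_maj <= n_min <= n_maj + int(np.sum(y == 1))
    elif name in ("b-smote", "svm-smote"):
        assert n_min <= n_maj  # synthesis limited to qualifying parents
        assert n_min >= int(np.sum(y == 1))
    else:
        assert n_min == n_maj


@pytest.mark.parametrize("name", ["smote", "b-smote", "svm-smote", "adasyn"])
def test_synthetics_are_segment_points(name, toy_features):
    """Each synthetic row equals p + r (q - p) for its recorded parent p,
    neighbor q and multiplier r in [0, 1]; both endpoints are minority."""
    X, y = toy_features.X, toy_features.y
    res = apply_sampler(name, X, y, SamplerParams(seed=2))
    assert len(res.synthetic_parent) > 0
    for row, p_idx, q_idx, r in zip(
        res.synthetic_rows, res.synthetic_parent, res.synthetic_neighbor, res.synthetic_r
    ):
        assert 0.0 <= r <= 1.0
        assert y[p_idx] == 1 and y[q_idx] == 1
        expect = X[p_idx] + r * (X[q_idx] - X[p_idx])
        np.testing.assert_allclose(res.X[row], expect, atol=1e-12)


def test_smote_neighbors_match_bruteforce(toy_features):
    """The neighbor recorded for each synthetic point is one of the parent's
    K nearest minority neighbors per the O(n^2) oracle."""
    X, y = toy_features.X, toy_features.y
    res = smote(X, y, SamplerParams(k=5, seed=3))
    mino = np.flatnonzero(y == 1)
    for p_idx, q_idx in zip(res.synthetic_parent, res.synthetic_neighbor):
        allowed = brute_knn_in_pool(X, X[p_idx], mino[mino != p_idx], 5)
        assert q_idx in allowed


def test_ros_copies_original_rows(toy_features):
    X, y = toy_features.X, toy_features.y
    res = ros(X, y, SamplerParams(seed=5))
    for row, p_idx in zip(res.synthetic_rows, res.synthetic_parent):
        assert y[p_idx] == 1
        np.testing.assert_array_equal(res.X[row], X[p_idx])


def test_ros_balanced_input_unchanged():
    X = np.random.default_rng(0).normal(size=(20, 2))
    y = np.repeat([0, 1], 10)
    res = ros(X, y, SamplerParams(seed=0))
    assert len(res.y) == 20


def test_smote_requires_enough_minority():
    X = np.zeros((8, 2))
    y = np.array([1, 1, 1, 0, 0, 0, 0, 0])
    with pytest.raises(ValueError):
        smote(X, y, SamplerParams(k=5))


def test_danger_set_matches_bruteforce(overlap_toy):
    X, y = overlap_toy.points, overlap_toy.labels
    res = borderline_smote(X, y, SamplerParams(k=5, m=10, seed=1))
    np.testing.assert_array_equal(np.sort(res.info["danger"]), brute_danger(X, y, 10))
    # every synthesis parent is a DANGER member
    assert set(res.synthetic_parent) <= set(res.info["danger"])


def test_danger_rule_counts():
    """A minority point with 6 of 10 majority neighbors is DANGER; one with
    all-minority neighborhood is not."""
    rng = np.random.default_rng(0)
    # borderline minority point at the edge of a majority cluster
    maj = rng.normal(0, 0.5, size=(30, 2))
    safe_min = rng.normal(0, 0.3, size=(12, 2)) + [8.0, 0.0]
    border_min = np.array([[0.2, 0.0]])
    X = np.vstack([maj, safe_min, border_min])
    y = np.array([0] * 30 + [1] * 13)
    danger = brute_danger(X, y, 10)
    assert 42 in danger  # the planted borderline point
    assert not any(i in danger for i in range(30, 42))  # far cluster is safe
    res = borderline_smote(X, y, SamplerParams(k=5, m=10, seed=0))
    np.testing.assert_array_equal(np.sort(res.info["danger"]), danger)


def test_empty_danger_no_synthesis(separated_toy):
    X, y = separated_toy.points, separated_toy.labels
    with pytest.warns(UserWarning, match="DANGER"):
        res = borderline_smote(X, y, SamplerParams(seed=0))
    assert len(res.y) == len(y)
    assert len(res.synthetic_parent) == 0


def test_svm_smote_parents_are_support_vectors(overlap_toy):
    from sklearn.svm import SVC

    X, y = overlap_toy.points, overlap_toy.labels
    res = svm_smote(X, y, SamplerParams(seed=4))
    svc = SVC(kernel="linear", C=1.0).fit(X, 2 * y - 1)
    sv_min = set(svc.support_[y[svc.support_] == 1])
    assert set(res.info["support_vectors"]) == sv_min
    assert set(res.synthetic_parent) <= sv_min


def test_svm_smote_gate_blocks_surrounded_svs():
    """Minority support vectors with a majority-dominated neighborhood are
    rejected as synthesis seeds."""
    rng = np.random.default_rng(1)
    maj = rng.normal(0, 1.0, size=(120, 2))
    # isolated minority points scattered through the majority cloud: each
    # one's M-neighborhood is pure majority
    mino = np.array([[x, y_] for x in (-1.0, 0.0, 1.0) for y_ in (-1.0, 0.0, 1.0)])[:8]
    X = np.vstack([maj, mino])
    y = np.array([0] * 120 + [1] * 8)
    with pytest.warns(UserWarning):
        res = svm_smote(X, y, SamplerParams(k=5, m=10, seed=0))
    assert len(res.synthetic_parent) == 0


def test_adasyn_budget_and_normalization(toy_features):
    X, y = toy_features.X, toy_features.y
    res = adasyn(X, y, SamplerParams(k=5, beta=1.0, seed=6))
    n_min, n_maj = int(np.sum(y == 1)), int(np.sum(y == 0))
    assert res.info["G"] == n_maj - n_min
    assert np.isclose(res.info["gamma"].sum(), 1.0)
    g = res.info["g"]
    np.testing.assert_array_equal(g, np.ceil(res.info["gamma"] * res.info["G"]))
    assert len(res.synthetic_parent) == g.sum() >= res.info["G"]


def test_adasyn_borderline_gets_more_than_interior():
    """A minority point inside the majority cloud (delta = K) receives more
    synthetics than one deep inside its own cluster (delta = 0)."""
    rng = np.random.default_rng(2)
    maj = rng.normal(0, 0.4, size=(30, 2))
    mino = rng.normal(0, 0.3, size=(9, 2)) + [10.0, 0.0]
    border = np.array([[0.0, 0.0]])
    X = np.vstack([maj, mino, border])
    y = np.array([0] * 30 + [1] * 10)
    res = adasyn(X, y, SamplerParams(k=5, beta=1.0, seed=0))
    g = res.info["g"]
    assert res.info["delta"][-1] == 5  # planted borderline point
    assert g[-1] > g[0]
    assert res.info["delta"][0] == 0


def test_adasyn_uniform_fallback(separated_toy):
    X, y = separated_toy.points, separated_toy.labels
    res = adasyn(X, y, SamplerParams(k=5, seed=0))
    n_min = int(np.sum(y == 1))
    np.testing.assert_allclose(res.info["gamma"], np.full(n_min, 1.0 / n_min))


def test_rus_partition(toy_features):
    X, y = toy_features.X, toy_features.y
    res = rus(X, y, SamplerParams(seed=7))
    assert int(np.sum(res.y == 0)) == int(np.sum(res.y == 1)) == int(np.sum(y == 1))
    # removed and kept rows partition the original majority
    kept_maj = res.X[res.y == 0]
    orig_maj = X[y == 0]
    assert len(res.removed_index) + len(kept_maj) == len(orig_maj)
    orig_rows = {tuple(r) for r in orig_maj}
    assert all(tuple(r) in orig_rows for r in kept_maj)
    assert all(tuple(X[i]) in orig_rows for i in res.removed_index)


def test_rus_balanced_unchanged():
    X = np.random.default_rng(3).normal(size=(20, 2))
    y = np.repeat([0, 1], 10)
    res = rus(X, y, SamplerParams(seed=0))
    assert len(res.y) == 20 and len(res.removed_index) == 0


def test_ncr_matches_bruteforce(overlap_toy):
    X, y = overlap_toy.points, overlap_toy.labels
    res = ncr(X, y, SamplerParams(seed=0))
    np.testing.assert_array_equal(res.removed_index, brute_ncr_removed(X, y, 3))
    # minority rows all survive
    assert int(np.sum(res.y == 1)) == int(np.sum(y == 1))


def test_ncr_hand_built_configuration():
    """Six points placed so stage 1 removes exactly the majority point with
    2 of 3 minority neighbors, and stage 2 prunes majority-adjacent rows."""
    X = np.array([
        [0.0, 0.0],   # 0 maj: neighbors 1,4,5 -> 2 of 3 minority -> stage 1
        [0.1, 0.0],   # 1 min
        [5.0, 0.0],   # 2 maj: neighbors 3,5,... majority-heavy, survives
        [5.1, 0.0],   # 3 maj
        [0.2, 0.1],   # 4 min
        [4.9, 0.1],   # 5 maj
    ])
    y = np.array([0, 1, 0, 0, 1, 0])
    removed = brute_ncr_removed(X, y, 3)
    assert 0 in removed  # edited-NN victim
    res = ncr(X, y, SamplerParams(seed=0))
    np.testing.assert_array_equal(res.removed_index, removed)
    np.testing.assert_array_equal(res.info["stage1_removed"], [0])
    # stage 2: majority points whose nearest survivor is majority
    assert set(res.info["stage2_removed"]) == set(removed) - {0}


def test_tomek_matches_bruteforce(overlap_toy):
    X, y = overlap_toy.points, overlap_toy.labels
    res = tomek(X, y, SamplerParams())
    np.testing.assert_array_equal(res.removed_index, brute_tomek_majority(X, y))
    assert int(np.sum(res.y == 1)) == int(np.sum(y == 1))


def test_tomek_four_point_construction():
    """One mutual cross-class nearest pair: exactly that majority point is
    removed, the rest stay."""
    X = np.array([[0.0, 0.0], [0.4, 0.0], [3.0, 0.0], [9.0, 0.0]])
    y = np.array([0, 1, 0, 0])
    res = tomek(X, y, SamplerParams())
    np.testing.assert_array_equal(res.removed_index, [0])
    assert len(res.y) == 3


def test_tomek_separated_no_links(separated_toy):
    X, y = separated_toy.points, separated_toy.labels
    res = tomek(X, y, SamplerParams())
    assert len(res.removed_index) == 0
    assert len(res.y) == len(y)


def test_knn_helper_matches_bruteforce():
    """The package's neighbor queries agree with direct enumeration on a
    200-point cloud for several k."""
    from p300balance.balance import _neighbors_excluding_self

    toy = generate_toy_2d(60, 140, separation=1.5, seed=9)
    X = toy.points
    idx = np.arange(len(X))
    for k in (1, 3, 10):
        got = _neighbors_excluding_self(X, idx, k)
        for i in idx:
            np.testing.assert_array_equal(np.sort(got[i]), np.sort(brute_knn(X, i, k)))


@pytest.mark.parametrize(
    "kwargs",
    [dict(k=0), dict(k=5, m=3), dict(beta=1.5), dict(sampling_ratio=0.0), dict(sampling_ratio=1.2)],
)
def test_params_validation(kwargs):
    with pytest.raises(ValueError):
        SamplerParams(**kwargs)


def test_unknown_sampler_rejected(toy_features):
    with pytest.raises(ValueError, match="unknown sampler"):
        apply_sampler("smite", toy_features.X, toy_features.y, SamplerParams())


@settings(max_examples=25, deadline=None)
@given(
    n_min=st.integers(8, 20),
    n_maj=st.integers(21, 60),
    sep=st.floats(0.2, 3.0),
    seed=st.integers(0, 10_000),
)
def test_smote_convexity_property(n_min, n_maj, sep, seed):
    """Synthetic SMOTE points always lie within the minority bounding box
    (convex combinations cannot escape it)."""
    toy = generate_toy_2d(n_min, n_maj, separation=sep, seed=seed)
    res = smote(toy.points, toy.labels, SamplerParams(k=5, seed=seed))
    mino = toy.points[toy.labels == 1]
    lo, hi = mino.min(axis=0), mino.max(axis=0)
    syn = res.X[res.synthetic_rows]
    assert np.all(syn >= lo - 1e-9) and np.all(syn <= hi + 1e-9)
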