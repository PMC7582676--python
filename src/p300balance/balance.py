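"""Class-imbalance samplers for target/nontarget ERP feature sets.

Five oversamplers grow the minority (target) class:

* ``ros`` — random duplication of minority rows;
* ``smote`` — synthesis on segments toward K nearest minority neighbors,
  ``s = p + r * (neighbor - p)`` with ``r ~ U(0, 1)``;
* ``borderline_smote`` — SMOTE restricted to the DANGER set: minority
  points with more than half of their M nearest neighbors (over the full
  dataset) in the majority class;
* ``svm_smote`` — synthesis seeded at minority-class support vectors of an
  SVM trained on the data, gated on the neighborhood NOT being
  majority-dominated;
* ``adasyn`` — per-point synthesis budget proportional to the majority
  fraction of the K-neighborhood, ``g(i) = ceil(gamma(i) * G)`` with
  ``G = beta * (|S_maj| - |S_min|)``.

Three undersamplers shrink the majority class: ``rus`` (random removal),
``ncr`` (edited-NN stage followed by a nearest-neighbor condensing stage),
and ``tomek`` (remove majority members of mutual cross-class nearest-
neighbor pairs).  The weighted-undersampling bagging ensemble lives in
:mod:`p300balance.classify` since it is a classifier, not a dataset
transform.

All samplers take ``(X, y)`` with ``y == 1`` marking the minority class,
never mutate their input, and are deterministic under a fixed seed.
Distances are Euclidean; a point is never its own neighbor; neighbor ties
are broken by row index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

__all__ = [
    "SamplerParams",
    "SamplerResult",
    "ros",
    "smote",
    "borderline_smote",
    "svm_smote",
    "adasyn",
    "rus",
    "ncr",
    "tomek",
    "SAMPLERS",
    "apply_sampler",
]


@dataclass(frozen=True)
class SamplerParams:
    """Shared knobs of the sampler family.

    ``k`` is the synthesis-neighbor count, ``m`` the danger-test neighbor
    count, ``beta`` the ADASYN balance level, ``sampling_ratio`` the desired
    minority/majority size ratio after balancing (1 = full balance), and
    ``ncr_k`` the edited-NN neighbor count.
    """

    k: int = 5
    m: int = 10
    beta: float = 1.0
    sampling_ratio: float = 1.0
    ncr_k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.m < self.k:
            raise ValueError("m must be >= k")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if not 0.0 < self.sampling_ratio <= 1.0:
            raise ValueError("sampling_ratio must lie in (0, 1]")


@dataclass
class SamplerResult:
    """Resampled dataset plus full provenance.

    For oversamplers ``synthetic_parent`` / ``synthetic_neighbor`` /
    ``synthetic_r`` record, per appended row, the original-row index of the
    parent p, of the neighbor defining the difference vector d, and the
    uniform multiplier r of ``s = p + r * d``.  For undersamplers
    ``removed_index`` lists the dropped original rows.  ``info`` carries
    method-specific extras (ADASYN's G, Z, delta, gamma, g; the DANGER set;
    the seeding support vectors).
    """

    X: np.ndarray
    y: np.ndarray
    synthetic_parent: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    synthetic_neighbor: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    synthetic_r: np.ndarray = field(default_factory=lambda: np.empty(0))
    removed_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    info: dict = field(default_factory=dict)

    @property
    def n_original(self) -> int:
        return len(self.y) - len(self.synthetic_parent)

    @property
    def synthetic_rows(self) -> np.ndarray:
        """Row indices (into output X) of synthesized instances."""
        return np.arange(self.n_original, len(self.y))


def _split(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    return np.flatnonzero(y == 1), np.flatnonzero(y == 0)


def _n_to_synthesize(n_min: int, n_maj: int, ratio: float) -> int:
    """Minority rows to add so that |S_min| / |S_maj| reaches ``ratio``."""
    return max(int(np.ceil(ratio * n_maj)) - n_min, 0)


def _knn_indices(query: np.ndarray, pool: np.ndarray, k: int) -> np.ndarray:
    """Indices into ``pool`` of the k nearest neighbors of each query row.

    ``pool`` rows identical in memory to a query row are NOT excluded here;
    callers handle self-exclusion by querying k+1 and dropping the self
    column, which keeps tie handling index-stable.
    """
    nn = NearestNeighbors(n_neighbors=min(k, len(pool)), algorithm="brute")
    nn.fit(pool)
    return nn.kneighbors(query, return_distance=False)


def _neighbors_excluding_self(X: np.ndarray, idx: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbors within X of the rows ``idx``, self excluded."""
    got = _knn_indices(X[idx], X, min(k + 1, len(X)))
    out = np.empty((len(idx), min(k, len(X) - 1)), dtype=int)
    for row, i in enumerate(idx):
        cols = got[row][got[row] != i][: out.shape[1]]
        out[row] = cols
    return out


def _interpolate(
    X: np.ndarray,
    parents: np.ndarray,
    neighbor_lists: np.ndarray,
    n_new: int,
    rng: np.random.Generator,
    parent_ids: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n_new`` synthetic points ``p + r (q - p)``.

    Parents are drawn uniformly with replacement from ``parents`` (row
    positions into ``neighbor_lists``); the neighbor q uniformly from that
    parent's list.  Returns (points, parent ids, neighbor ids, r draws).
    """
    pick = rng.integers(len(parents), size=n_new)
    ncols = neighbor_lists.shape[1]
    nb_pick = rng.integers(ncols, size=n_new)
    r = rng.uniform(0.0, 1.0, size=n_new)
    p_idx = parent_ids[pick]
    q_idx = neighbor_lists[pick, nb_pick]
    pts = X[p_idx] + r[:, None] * (X[q_idx] - X[p_idx])
    return pts, p_idx, q_idx, r


def ros(X: np.ndarray, y: np.ndarray, params: SamplerParams) -> SamplerResult:
    """Random oversampling: duplicate minority rows to the target ratio."""
    X, y = np.asarray(X, float), np.asarray(y, int)
    mino, maj = _split(y)
    if len(mino) == 0:
        raise ValueError("minority class is empty")
    n_new = _n_to_synthesize(len(mino), len(maj), params.sampling_ratio)
    rng = np.random.default_rng(params.seed)
    picks = mino[rng.integers(len(mino), size=n_new)]
    return SamplerResult(
        X=np.vstack([X, X[picks]]),
        y=np.concatenate([y, np.ones(n_new, dtype=int)]),
        synthetic_parent=picks,
        synthetic_neighbor=picks.copy(),
        synthetic_r=np.zeros(n_new),
    )


def smote(X: np.ndarray, y: np.ndarray, params: SamplerParams) -> SamplerResult:
    """SMOTE: interpolated synthesis toward K nearest minority neighbors."""
    X, y = np.asarray(X, float), np.asarray(y, int)
    mino, maj = _split(y)
    if len(mino) <= params.k:
        raise ValueError(f"SMOTE needs more than k={params.k} minority instances")
    n_new = _n_to_synthesize(len(mino), len(maj), params.sampling_ratio)
    rng = np.random.default_rng(params.seed)
    nb_local = _neighbors_excluding_self(X[mino], np.arange(len(mino)), params.k)
    neighbor_lists = mino[nb_local]  # map back to global row ids
    pts, p_idx, q_idx, r = _interpolate(
        X, np.arange(len(mino)), neighbor_lists, n_new, rng, parent_ids=mino
    )
    return SamplerResult(
        X=np.vstack([X, pts]),
        y=np.concatenate([y, np.ones(n_new, dtype=int)]),
        synthetic_parent=p_idx,
        synthetic_neighbor=q_idx,
        synthetic_r=r,
    )


def _danger_mask(X: np.ndarray, y: np.ndarray, mino: np.ndarray, m: int) -> np.ndarray:
    """True for minority points whose M-neighborhood (full dataset, self
    excluded) contains more than M/2 majority instances."""
    nb = _neighbors_excluding_self(X, mino, m)
    maj_counts = (y[nb] == 0).sum(axis=1)
    return maj_counts > nb.shape[1] / 2


def borderline_smote(
    X: np.ndarray,
    y: np.ndarray,
    params: SamplerParams,
    exclude_all_majority: bool = False,
) -> SamplerResult:
    """Borderline SMOTE: synthesize only from the DANGER set.

    A minority point is in DANGER when more than half of its M nearest
    neighbors over the whole dataset are majority.  With
    ``exclude_all_majority`` points whose entire M-neighborhood is majority
    are treated as noise and skipped (the behavior of the method's original
    formulation); the default keeps them, reading "more than half"
    literally.  Synthesis runs toward each DANGER member's K nearest
    *minority* neighbors.  An empty DANGER set returns the data unchanged
    with a warning.
    """
    X, y = np.asarray(X, float), np.asarray(y, int)
    mino, maj = _split(y)
    if len(mino) <= params.k:
        raise ValueError(f"borderline SMOTE needs more than k={params.k} minority instances")
    nb_full = _neighbors_excluding_self(X, mino, params.m)
    maj_counts = (y[nb_full] == 0).sum(axis=1)
    m_eff = nb_full.shape[1]
    danger = maj_counts > m_eff / 2
    if exclude_all_majority:
        danger &= maj_counts < m_eff
    danger_ids = mino[danger]
    if len(danger_ids) == 0:
        warnings.warn("DANGER set is empty; no synthesis performed")
        return SamplerResult(X=X.copy(), y=y.copy(), info={"danger": danger_ids})
    n_new = _n_to_synthesize(len(mino), len(maj), params.sampling_ratio)
    rng = np.random.default_rng(params.seed)
    nb_local = _neighbors_excluding_self(
        X[mino], np.searchsorted(mino, danger_ids), params.k
    )
    neighbor_lists = mino[nb_local]
    pts, p_idx, q_idx, r = _interpolate(
        X, np.arange(len(danger_ids)), neighbor_lists, n_new, rng, parent_ids=danger_ids
    )
    return SamplerResult(
        X=np.vstack([X, pts]),
        y=np.concatenate([y, np.ones(n_new, dtype=int)]),
        synthetic_parent=p_idx,
        synthetic_neighbor=q_idx,
        synthetic_r=r,
        info={"danger": danger_ids},
    )


def svm_smote(
    X: np.ndarray,
    y: np.ndarray,
    params: SamplerParams,
    C: float = 1.0,
) -> SamplerResult:
    """SVM-SMOTE: seed synthesis at minority-class support vectors.

    A linear soft-margin SVM (same contract as the downstream classifier,
    C=1 by default) is trained on the dataset; its minority-class support
    vectors are candidate parents.  A candidate qualifies when *fewer* than
    half of its M nearest neighbors (full dataset) are majority — i.e. it
    sits on the minority side of the boundary rather than deep in majority
    territory.  Synthesis then runs toward K nearest minority neighbors.
    """
    X, y = np.asarray(X, float), np.asarray(y, int)
    mino, maj = _split(y)
    if len(mino) <= params.k:
        raise ValueError(f"SVM-SMOTE needs more than k={params.k} minority instances")
    svc = SVC(kernel="linear", C=C)
    svc.fit(X, 2 * y - 1)
    sv_ids = svc.support_[np.asarray(y)[svc.support_] == 1]
    if len(sv_ids) == 0:
        warnings.warn("no minority support vectors; no synthesis performed")
        return SamplerResult(X=X.copy(), y=y.copy(), info={"support_vectors": sv_ids})
    nb_full = _neighbors_excluding_self(X, sv_ids, params.m)
    qualifies = (y[nb_full] == 0).sum(axis=1) < nb_full.shape[1] / 2
    parents = sv_ids[qualifies]
    if len(parents) == 0:
        warnings.warn("all minority support vectors are majority-surrounded; no synthesis")
        return SamplerResult(X=X.copy(), y=y.copy(), info={"support_vectors": sv_ids})
    n_new = _n_to_synthesize(len(mino), len(maj), params.sampling_ratio)
    rng = np.random.default_rng(params.seed)
    nb_local = _neighbors_excluding_self(
        X[mino], np.searchsorted(mino, parents), params.k
    )
    neighbor_lists = mino[nb_local]
    pts, p_idx, q_idx, r = _interpolate(
        X, np.arange(len(parents)), neighbor_lists, n_new, rng, parent_ids=parents
    )
    return SamplerResult(
        X=np.vstack([X, pts]),
        y=np.concatenate([y, np.ones(n_new, dtype=int)]),
        synthetic_parent=p_idx,
        synthetic_neighbor=q_idx,
        synthetic_r=r,
        info={"support_vectors": sv_ids, "parents": parents},
    )


def adasyn(X: np.ndarray, y: np.ndarray, params: SamplerParams) -> SamplerResult:
    """ADASYN: density-adaptive synthesis budget per minority point.

    ``G = beta * (|S_maj| - |S_min|)`` total; each minority point i gets
    ``g(i) = ceil(gamma(i) * G)`` synthetics, where ``gamma(i)`` is its
    normalized majority fraction ``delta(i)/K`` among K nearest neighbors
    over the full dataset.  Ceiling can overshoot G slightly; the excess is
    kept.  If every ``delta(i)`` is zero (minority nowhere near majority),
    gamma falls back to uniform.
    """
    X, y = np.asarray(X, float), np.asarray(y, int)
    mino, maj = _split(y)
    if len(mino) <= params.k:
        raise ValueError(f"ADASYN needs more than k={params.k} minority instances")
    G = params.beta * (len(maj) - len(mino))
    nb_full = _neighbors_excluding_self(X, mino, params.k)
    delta = (y[nb_full] == 0).sum(axis=1).astype(float)
    Z = float(np.sum(delta / params.k))
    if Z == 0.0:
        gamma = np.full(len(mino), 1.0 / len(mino))
    else:
        gamma = (delta / params.k) / Z
    g = np.ceil(gamma * G).astype(int) if G > 0 else np.zeros(len(mino), dtype=int)
    rng = np.random.default_rng(params.seed)
    nb_local = _neighbors_excluding_self(X[mino], np.arange(len(mino)), params.k)
    neighbor_lists = mino[nb_local]
    pts_list, p_list, q_list, r_list = [], [], [], []
    for row, count in enumerate(g):
        if count == 0:
            continue
        nb_pick = rng.integers(neighbor_lists.shape[1], size=count)
        r = rng.uniform(0.0, 1.0, size=count)
        p_idx = np.full(count, mino[row])
        q_idx = neighbor_lists[row, nb_pick]
        pts_list.append(X[p_idx] + r[:, None] * (X[q_idx] - X[p_idx]))
        p_list.append(p_idx)
        q_list.append(q_idx)
        r_list.append(r)
    if pts_list:
        pts = np.vstack(pts_list)
        p_idx = np.concatenate(p_list)
        q_idx = np.concatenate(q_list)
        r = np.concatenate(r_list)
    else:
        pts = np.empty((0, X.shape[1]))
        p_idx = q_idx = np.empty(0, dtype=int)
        r = np.empty(0)
    return SamplerResult(
        X=np.vstack([X, pts]),
        y=np.concatenate([y, np.ones(len(pts), dtype=int)]),
        synthetic_parent=p_idx,
        synthetic_neighbor=q_idx,
        synthetic_r=r,
        info={"G": G, "Z": Z, "delta": delta, "gamma": gamma, "g": g},
    )


def rus(X: np.ndarray, y: np.ndarray, params: SamplerParams) -> SamplerResult:
    """Random undersampling: thin the majority down to the target ratio."""
    X, y = np.asarray(X, float), np.asarray(y, int)
    mino, maj = _split(y)
    if len(maj) < len(mino):
        raise ValueError("majority class is smaller than minority class")
    n_keep = min(int(np.ceil(len(mino) / params.sampling_ratio)), len(maj))
    rng = np.random.default_rng(params.seed)
    kept_maj = np.sort(rng.choice(maj, size=n_keep, replace=False))
    removed = np.setdiff1d(maj, kept_maj)
    keep = np.sort(np.concatenate([mino, kept_maj]))
    return SamplerResult(X=X[keep].copy(), y=y[keep].copy(), removed_index=removed)


def ncr(X: np.ndarray, y: np.ndarray, params: SamplerParams) -> SamplerResult:
    """Neighborhood cleaning rule, two stages, minority never touched.

    Stage 1 (edited nearest neighbors, K = ``ncr_k``): drop a majority
    instance when more than half of its K nearest neighbors are not
    majority.  Stage 2, applied to the stage-1 survivors: drop a surviving
    majority instance when its single nearest neighbor (among survivors) is
    majority, keep it when that neighbor is minority.  Both stages evaluate
    all removals against a fixed snapshot (single pass), so the result does
    not depend on scan order.

    On cleanly separated data stage 2 is degenerate — every majority point
    has a majority nearest neighbor, so the rule would empty the class.  In
    that case the majority instance closest to the minority class (the one
    the rule's own keep-condition is about) is retained, with a warning.
    """
    X, y = np.asarray(X, float), np.asarray(y, int)
    mino, maj = _split(y)
    k = params.ncr_k
    if len(maj) <= k:
        raise ValueError(f"NCR needs more than {k} majority instances")
    nb = _neighbors_excluding_self(X, maj, k)
    not_maj = (y[nb] == 1).sum(axis=1)
    drop1 = maj[not_maj > nb.shape[1] / 2]
    survivors = np.setdiff1d(np.arange(len(y)), drop1)
    Xs, ys = X[survivors], y[survivors]
    maj_pos = np.flatnonzero(ys == 0)
    nb1 = _neighbors_excluding_self(Xs, maj_pos, 1)
    drop2 = survivors[maj_pos[ys[nb1[:, 0]] == 0]]
    if len(drop2) == len(maj_pos) and len(maj_pos) > 0:
        warnings.warn(
            "NCR condensation would remove every majority instance; "
            "keeping the one closest to the minority class"
        )
        min_rows = Xs[ys == 1]
        dists = np.array([np.linalg.norm(min_rows - Xs[j], axis=1).min() for j in maj_pos])
        keep_one = survivors[maj_pos[int(np.argmin(dists))]]
        drop2 = drop2[drop2 != keep_one]
    removed = np.sort(np.concatenate([drop1, drop2]))
    keep = np.setdiff1d(np.arange(len(y)), removed)
    return SamplerResult(
        X=X[keep].copy(),
        y=y[keep].copy(),
        removed_index=removed,
        info={"stage1_removed": drop1, "stage2_removed": drop2},
    )


def tomek(X: np.ndarray, y: np.ndarray, params: SamplerParams) -> SamplerResult:
    """Remove majority members of Tomek links.

    A Tomek link is a cross-class pair that are mutual nearest neighbors.
    All minority rows are kept; every majority row participating in a link
    is dropped, in a single pass.
    """
    X, y = np.asarray(X, float), np.asarray(y, int)
    mino, maj = _split(y)
    if len(mino) == 0 or len(maj) == 0:
        raise ValueError("both classes must be nonempty")
    nn1 = _neighbors_excluding_self(X, np.arange(len(y)), 1)[:, 0]
    links_maj = [
        i for i in maj
        if y[nn1[i]] == 1 and nn1[nn1[i]] == i
    ]
    removed = np.asarray(sorted(links_maj), dtype=int)
    keep = np.setdiff1d(np.arange(len(y)), removed)
    return SamplerResult(
        X=X[keep].copy(), y=y[keep].copy(), removed_index=removed,
        info={"links": [(int(i), int(nn1[i])) for i in removed]},
    )


SAMPLERS = {
    "ros": ros,
    "smote": smote,
    "b-smote": borderline_smote,
    "svm-smote": svm_smote,
    "adasyn": adasyn,
    "rus": rus,
    "ncr": ncr,
    "tomek": tomek,
}


def apply_sampler(name: str, X: np.ndarray, y: np.ndarray, params: SamplerParams) -> SamplerResult:
    """Dispatch by method name (see :data:`SAMPLERS`); ``"none"`` passes
    the data through untouched."""
    if name == "none":
        return SamplerResult(X=np.asarray(X, float).copy(), y=np.asarray(y, int).copy())
    try:
        fn = SAMPLERS[name]
    except KeyError:
        raise ValueError(f"unknown sampler {name!r}; choose from {sorted(SAMPLERS)}") from None
    return fn(X, y, params)
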