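"""Target/nontarget SVM classification and block-level target selection.

The block decision rule of the interface: the trained binary classifier
assigns each stimulus of a test block a *target probability* from its
averaged ERP, and the stimulus with the highest probability is selected.
Since the selection is an argmax, any strictly monotone mapping of decision
values to probabilities yields the same choice; a Platt-style sigmoid
calibrator is fit anyway so reported probabilities are interpretable.

Two classifiers are provided:

* a single soft-margin SVM (``min 1/2 w'w + C sum xi`` with optional
  per-class multipliers on C — the weighted-C imbalance remedy sets them
  inversely proportional to class sizes);
* the weighted undersampling bagging (WUS) ensemble: the nontarget rows are
  split into disjoint subsets, each paired with all target rows to train
  one SVM, and members vote with rational weights 1/6, 2/6, 3/6 (three
  subsets) or 1/15 ... 5/15 (five subsets) assigned by training-accuracy
  rank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .preprocess import FeatureDataset

__all__ = [
    "SvmSpec",
    "TrainedModel",
    "EnsembleModel",
    "train_svm",
    "predict_block",
    "train_wus",
    "predict_block_wus",
    "wus_weights",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SvmSpec:
    """Soft-margin SVM configuration.

    ``class_weights`` multiply C per class as ``(nontarget, target)``;
    ``balanced=True`` overrides them with l/(2 n_class) — the weighted-C
    variant, giving the minority class a penalty inversely proportional to
    its size.
    """

    C: float = 1.0
    kernel: str = "linear"
    class_weights: tuple[float, float] = (1.0, 1.0)
    balanced: bool = False

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be > 0")


class _PlattCalibrator:
    """Sigmoid map P(target | f) = 1 / (1 + exp(A f + B)).

    Fit by logistic regression on decision values; uses out-of-fold values
    when the class sizes allow an internal stratified split, otherwise the
    resubstitution values.
    """

    def __init__(self, A: float, B: float) -> None:
        self.A = A
        self.B = B

    def __call__(self, f: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(np.clip(self.A * f + self.B, -500, 500)))

    @classmethod
    def fit(cls, f: np.ndarray, y: np.ndarray) -> "_PlattCalibrator":
        # Newton iterations on the 2-parameter logistic likelihood with the
        # standard Bayesian target smoothing
        n1 = int(np.sum(y == 1))
        n0 = len(y) - n1
        t = np.where(y == 1, (n1 + 1.0) / (n1 + 2.0), 1.0 / (n0 + 2.0))
        A, B = 0.0, float(np.log((n0 + 1.0) / (n1 + 1.0)))
        for _ in range(100):
            z = np.clip(A * f + B, -500, 500)
            p = 1.0 / (1.0 + np.exp(z))  # note: P(target) with NEGATIVE z slope
            # dL/dz of the cross-entropy between t and p is (t - p)
            d = t - p
            gA, gB = np.sum(d * f), np.sum(d)
            w = p * (1 - p)
            hAA = np.sum(w * f * f) + 1e-12
            hAB = np.sum(w * f)
            hBB = np.sum(w) + 1e-12
            det = hAA * hBB - hAB * hAB
            if abs(det) < 1e-18:
                break
            dA = (hBB * gA - hAB * gB) / det
            dB = (hAA * gB - hAB * gA) / det
            A -= dA
            B -= dB
            if abs(dA) < 1e-10 and abs(dB) < 1e-10:
                break
        return cls(A, B)


@dataclass
class TrainedModel:
    """A fitted SVM with its support-vector inventory and calibrator."""

    svc: SVC
    calibrator: _PlattCalibrator
    spec: SvmSpec

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Signed distance to the boundary, positive toward target."""
        return self.svc.decision_function(np.asarray(X, float))

    def predict_proba_target(self, X: np.ndarray) -> np.ndarray:
        return self.calibrator(self.decision_values(X))

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        """Binary target(1)/nontarget(0) call at P(target) > 0.5.

        The calibrated probability carries the class prior of the training
        data, so on imbalanced training sets this threshold is
        deliberately conservative about target calls — the bias that
        balancing is meant to remove.
        """
        return (self.predict_proba_target(X) > 0.5).astype(int)

    @property
    def support_labels(self) -> np.ndarray:
        """Class label (0/1) of each support vector."""
        return self._train_y[self.svc.support_]

    _train_y: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def train_svm(train: FeatureDataset, spec: SvmSpec = SvmSpec()) -> TrainedModel:
    """Fit the soft-margin SVM and its probability calibrator.

    Classes are encoded -1 (nontarget) / +1 (target) so the decision value
    is positive on the target side.  The calibrator is fit on 3-fold
    out-of-fold decision values when each class has >= 3 members, else on
    resubstitution values.
    """
    X, y = np.asarray(train.X, float), np.asarray(train.y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if spec.balanced:
        n1, n0 = int(np.sum(y == 1)), int(np.sum(y == 0))
        weights = {-1: len(y) / (2.0 * n0), 1: len(y) / (2.0 * n1)}
    else:
        weights = {-1: spec.class_weights[0], 1: spec.class_weights[1]}
    svc = SVC(kernel=spec.kernel, C=spec.C, class_weight=weights)
    svc.fit(X, 2 * y - 1)

    n_min = min(int(np.sum(y == 1)), int(np.sum(y == 0)))
    if n_min >= 3:
        f = np.empty(len(y))
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        for tr, te in skf.split(X, y):
            fold = SVC(kernel=spec.kernel, C=spec.C, class_weight=weights)
            fold.fit(X[tr], 2 * y[tr] - 1)
            f[te] = fold.decision_function(X[te])
    else:
        f = svc.decision_function(X)
    model = TrainedModel(svc=svc, calibrator=_PlattCalibrator.fit(f, y), spec=spec)
    model._train_y = y.copy()
    return model


def _block_rows(ds: FeatureDataset, block: int) -> tuple[np.ndarray, np.ndarray]:
    """(X rows, stimulus ids) of one block, ordered by stimulus id."""
    sel = np.flatnonzero(ds.block_id == block)
    order = np.argsort(ds.stimulus_id[sel], kind="stable")
    sel = sel[order]
    return ds.X[sel], ds.stimulus_id[sel]


def predict_block(
    model: TrainedModel,
    block_X: np.ndarray,
    use: str = "probability",
) -> tuple[np.ndarray, int]:
    """Per-stimulus target probabilities and the argmax selection.

    ``block_X`` holds one feature row per stimulus, ordered by stimulus
    index; ties go to the lowest index.  ``use="decision"`` ranks by raw
    decision value instead of the calibrated probability — the selection is
    identical because the calibration is strictly monotone.
    """
    block_X = np.atleast_2d(np.asarray(block_X, float))
    if use == "probability":
        scores = model.predict_proba_target(block_X)
    elif use == "decision":
        scores = model.decision_values(block_X)
    else:
        raise ValueError("use must be 'probability' or 'decision'")
    return scores, int(np.argmax(scores))


@dataclass
class EnsembleModel:
    """WUS ensemble: one SVM per nontarget subset, rank-weighted."""

    members: list[TrainedModel]
    weights: list[Fraction]
    subset_indices: list[np.ndarray]
    train_accuracy: list[float]

    def predict_proba_target(self, X: np.ndarray) -> np.ndarray:
        """Weighted ensemble probability sum_i w_i p_i(X)."""
        X = np.atleast_2d(np.asarray(X, float))
        out = np.zeros(X.shape[0])
        for w, m in zip(self.weights, self.members):
            out += float(w) * m.predict_proba_target(X)
        return out

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba_target(np.atleast_2d(X)) > 0.5).astype(int)


def wus_weights(n_subsets: int) -> list[Fraction]:
    """The rational weight ladder 1/T, 2/T, ..., n/T with T = n(n+1)/2.

    For 3 subsets: 1/6, 2/6, 3/6; for 5: 1/15 ... 5/15.  Exact fractions so
    the ensemble weights sum to 1 identically.
    """
    total = n_subsets * (n_subsets + 1) // 2
    return [Fraction(i, total) for i in range(1, n_subsets + 1)]


def train_wus(
    train: FeatureDataset,
    n_subsets: int = 3,
    spec: SvmSpec = SvmSpec(),
    seed: int = 0,
) -> EnsembleModel:
    """Weighted undersampling bagging.

    The shuffled nontarget rows are split into ``n_subsets`` near-equal
    disjoint subsets (sizes differ by at most one); each subset plus all
    target rows trains one SVM.  Members are ranked by resubstitution
    training accuracy (ties broken by subset index) and assigned the
    rational weights of :func:`wus_weights`, lowest accuracy getting the
    smallest weight.
    """
    if n_subsets < 2:
        raise ValueError("n_subsets must be >= 2")
    X, y = np.asarray(train.X, float), np.asarray(train.y, int)
    maj = np.flatnonzero(y == 0)
    mino = np.flatnonzero(y == 1)
    if len(maj) < n_subsets:
        raise ValueError("fewer nontarget rows than subsets")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(maj)
    subsets = np.array_split(shuffled, n_subsets)

    members, accs = [], []
    for sub in subsets:
        rows = np.concatenate([mino, sub])
        part = FeatureDataset(
            X=X[rows],
            y=y[rows],
            block_id=np.asarray(train.block_id)[rows],
            stimulus_id=np.asarray(train.stimulus_id)[rows],
        )
        m = train_svm(part, spec)
        accs.append(float(np.mean(m.predict_label(X[rows]) == y[rows])))
        members.append(m)

    # rank members by accuracy, stable in subset index; weight by rank
    order = np.argsort(np.asarray(accs), kind="stable")  # ascending accuracy
    ladder = wus_weights(n_subsets)
    weights: list[Fraction] = [Fraction(0)] * n_subsets
    for rank, member_idx in enumerate(order):
        weights[member_idx] = ladder[rank]
    return EnsembleModel(
        members=members,
        weights=weights,
        subset_indices=[s.copy() for s in subsets],
        train_accuracy=accs,
    )


def predict_block_wus(
    ensemble: EnsembleModel, block_X: np.ndarray
) -> tuple[np.ndarray, int]:
    """argmax_j sum_i w_i p_ij over the stimuli of one block."""
    scores = ensemble.predict_proba_target(np.atleast_2d(np.asarray(block_X, float)))
    return scores, int(np.argmax(scores))


# ---------------------------------------------------------------------------
# Model persistence: JSON manifest + .npy arrays in one directory.


def save_model(model: TrainedModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    svc = model.svc
    np.save(path / "support_vectors.npy", svc.support_vectors_)
    np.save(path / "dual_coef.npy", svc.dual_coef_)
    np.save(path / "support.npy", svc.support_)
    np.save(path / "train_y.npy", model._train_y)
    manifest = {
        "spec": {
            "C": model.spec.C,
            "kernel": model.spec.kernel,
            "class_weights": list(model.spec.class_weights),
            "balanced": model.spec.balanced,
        },
        "intercept": svc.intercept_.tolist(),
        "calibrator": {"A": model.calibrator.A, "B": model.calibrator.B},
        "n_features": int(svc.support_vectors_.shape[1]),
    }
    (path / "model.json").write_text(json.dumps(manifest))


def load_model(path: str | Path) -> TrainedModel:
    """Rebuild a saved linear model as a light decision-function wrapper."""
    path = Path(path)
    manifest = json.loads((path / "model.json").read_text())
    if manifest["spec"]["kernel"] != "linear":
        raise ValueError("only linear models can be reloaded from disk")
    sv = np.load(path / "support_vectors.npy")
    dual = np.load(path / "dual_coef.npy")
    support = np.load(path / "support.npy")
    train_y = np.load(path / "train_y.npy")
    spec = SvmSpec(
        C=manifest["spec"]["C"],
        kernel=manifest["spec"]["kernel"],
        class_weights=tuple(manifest["spec"]["class_weights"]),
        balanced=manifest["spec"]["balanced"],
    )
    w = dual @ sv
    b = np.asarray(manifest["intercept"])

    class _LinearStub:
        support_vectors_ = sv
        dual_coef_ = dual
        support_ = support
        intercept_ = b

        @staticmethod
        def decision_function(X: np.ndarray) -> np.ndarray:
            return (np.asarray(X, float) @ w.T).ravel() + b

    cal = _PlattCalibrator(manifest["calibrator"]["A"], manifest["calibrator"]["B"])
    model = TrainedModel(svc=_LinearStub(), calibrator=cal, spec=spec)  # type: ignore[arg-type]
    model._train_y = train_y
    return model
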