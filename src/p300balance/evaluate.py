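"""Performance metrics and the result-level experiments.

Block accuracy is the fraction of test blocks whose argmax-selected
stimulus matches the planted target.  Binary (per-stimulus) recall,
precision and F1 come from the target/nontarget confusion matrix of the
classifier's thresholded calls on every test sample.  The information
transfer rate converts block accuracy into bits per minute.

Experiment drivers:

* :func:`run_subject` — one subject, one balancing method, full pipeline;
* :func:`run_comparison` — a cohort crossed with a method list, plus a
  paired Wilcoxon test of each method against no balancing and the
  poor-performer subset (subjects below the cohort's mean no-balancing
  accuracy);
* :func:`ratio_sweep` — borderline-SMOTE at a grid of minority/majority
  target ratios, recording train/test binary metrics and block accuracy,
  with Pearson correlations of each measure against block accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .balance import SamplerParams, apply_sampler
from .classify import (
    EnsembleModel,
    SvmSpec,
    TrainedModel,
    predict_block,
    predict_block_wus,
    train_svm,
    train_wus,
)
from .preprocess import FeatureDataset, session_features
from .synth import SessionRecording

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion_metrics",
    "itr",
    "sv_introspection",
    "run_subject",
    "run_comparison",
    "ratio_sweep",
    "sweep_correlations",
    "METHODS",
]

#: all balancing conditions of the study: none, five oversamplers, three
#: undersamplers, the WUS ensemble and the weighted-C SVM variant.
METHODS = [
    "none",
    "ros",
    "smote",
    "b-smote",
    "svm-smote",
    "adasyn",
    "rus",
    "ncr",
    "tomek",
    "wus",
    "weighted-c",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def f1(self) -> float | None:
        r, p = self.recall, self.precision
        if r is None or p is None or (r + p) == 0:
            return None
        return 2 * p * r / (p + r)

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.total if self.total else None


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Target/nontarget confusion counts; 1 = target (positive class).

    Undefined rates (empty denominator) are reported as ``None`` rather
    than coerced to 0.
    """
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def itr(N: int, P: float, T: float) -> float:
    """Information transfer rate in bits per minute.

    ``ITR = [log2 N + P log2 P + (1-P) log2((1-P)/(N-1))] / T`` with ``N``
    the number of selectable stimuli, ``P`` the block accuracy fraction and
    ``T`` the time per selection in minutes.  The ``x log2 x`` terms are
    continuous limits at P = 0 and P = 1; chance accuracy (P = 1/N) gives
    exactly 0 bits.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if T <= 0:
        raise ValueError("T must be > 0")
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    bits = math.log2(N)
    if P > 0:
        bits += P * math.log2(P)
    if P < 1:
        bits += (1 - P) * math.log2((1 - P) / (N - 1))
    return bits / T


def sv_introspection(model: TrainedModel) -> dict:
    """Support-vector census of a fitted single SVM.

    Returns per-class SV counts, the target/nontarget count ratio, and the
    mean relative distance of the support vectors to the decision boundary
    (``|w'x + b| / ||w||``, averaged over SVs) — the margin quantity that a
    borderline oversampler is expected to enlarge.
    """
    if isinstance(model, EnsembleModel):
        raise TypeError("introspection applies to a single SVM, not an ensemble")
    sv_labels = model.support_labels
    n_t = int(np.sum(sv_labels == 1))
    n_nt = int(np.sum(sv_labels == 0))
    f = model.decision_values(model.svc.support_vectors_)
    w = model.svc.dual_coef_ @ model.svc.support_vectors_
    w_norm = float(np.linalg.norm(w))
    mean_dist = float(np.mean(np.abs(f)) / w_norm) if w_norm > 0 else float("nan")
    return {
        "sv_count_target": n_t,
        "sv_count_nontarget": n_nt,
        "sv_ratio": n_t / n_nt if n_nt else float("inf"),
        "mean_relative_sv_distance": mean_dist,
    }


@dataclass
class EvalReport:
    """One subject x one method."""

    method: str
    block_accuracy: float
    confusion: ConfusionCounts
    itr_bpm: float
    n_test_blocks: int
    sv: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "block_accuracy": self.block_accuracy,
            "recall": self.confusion.recall,
            "precision": self.confusion.precision,
            "f1": self.confusion.f1,
            "binary_accuracy": self.confusion.accuracy,
            "itr_bpm": self.itr_bpm,
            "tp": self.confusion.tp,
            "fp": self.confusion.fp,
            "fn": self.confusion.fn,
            "tn": self.confusion.tn,
            **{k: self.sv.get(k) for k in ("sv_count_target", "sv_count_nontarget",
                                           "sv_ratio", "mean_relative_sv_distance")},
    }


def _fit_method(
    train: FeatureDataset,
    method: str,
    params: SamplerParams,
    spec: SvmSpec,
    n_subsets: int,
) -> TrainedModel | EnsembleModel:
    if method == "wus":
        return train_wus(train, n_subsets=n_subsets, spec=spec, seed=params.seed)
    if method == "weighted-c":
        return train_svm(train, SvmSpec(C=spec.C, kernel=spec.kernel, balanced=True))
    res = apply_sampler(method, train.X, train.y, params)
    resampled = FeatureDataset(
        X=res.X,
        y=res.y,
        block_id=np.full(len(res.y), -1),
        stimulus_id=np.full(len(res.y), -1),
    )
    return train_svm(resampled, spec)


def _evaluate_on_session(
    model: TrainedModel | EnsembleModel,
    test: FeatureDataset,
    session: SessionRecording,
    method: str,
    selection_minutes: float,
) -> EvalReport:
    cfg = session.config
    n_blocks = cfg.n_test_blocks
    correct = 0
    for b, block in enumerate(session.test_blocks):
        sel = np.flatnonzero(test.block_id == b)
        order = np.argsort(test.stimulus_id[sel], kind="stable")
        rows = test.X[sel][order]
        if isinstance(model, EnsembleModel):
            _, chosen = predict_block_wus(model, rows)
        else:
            _, chosen = predict_block(model, rows)
        correct += int(chosen == block.target_id)
    block_acc = correct / n_blocks
    cm = confusion_metrics(test.y, model.predict_label(test.X))
    sv = sv_introspection(model) if isinstance(model, TrainedModel) else {}
    return EvalReport(
        method=method,
        block_accuracy=block_acc,
        confusion=cm,
        itr_bpm=itr(cfg.n_stimuli, block_acc, selection_minutes),
        n_test_blocks=n_blocks,
        sv=sv,
    )


def run_subject(
    session: SessionRecording,
    method: str = "none",
    params: SamplerParams = SamplerParams(),
    spec: SvmSpec = SvmSpec(),
    selection_minutes: float = 10.0 / 60.0,
    features: tuple[FeatureDataset, FeatureDataset] | None = None,
) -> EvalReport:
    """Full pipeline for one subject under one balancing condition.

    ``selection_minutes`` is the time attributed to one block selection
    when converting accuracy to ITR; it is an explicit input, never
    inferred from the recording.  Precomputed ``(train, test)`` features
    can be passed to amortize preprocessing across methods.
    """
    if features is None:
        features = session_features(session)
    train, test = features
    n_subsets = 3 if session.config.n_stimuli == 4 else 5
    model = _fit_method(train, method, params, spec, n_subsets)
    return _evaluate_on_session(model, test, session, method, selection_minutes)


def run_comparison(
    cohort: list[SessionRecording],
    methods: list[str] | None = None,
    params: SamplerParams = SamplerParams(),
    spec: SvmSpec = SvmSpec(),
    selection_minutes: float = 10.0 / 60.0,
) -> dict:
    """Cohort x method factorial with paired significance vs no balancing.

    Returns a dict with ``table`` (tidy DataFrame, one row per subject and
    method), ``significance`` (per method: two-sided Wilcoxon signed-rank
    p-value of block accuracy against the no-balancing column), and
    ``poor_performers`` (subjects whose no-balancing accuracy is below the
    cohort mean, with their per-method means).
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    methods = list(METHODS) if methods is None else list(methods)
    if "none" not in methods:
        methods = ["none"] + methods
    rows = []
    for s, session in enumerate(cohort):
        feats = session_features(session)
        for method in methods:
            rep = run_subject(
                session, method, params=params, spec=spec,
                selection_minutes=selection_minutes, features=feats,
            )
            row = rep.as_row()
            row["subject"] = s
            rows.append(row)
    table = pd.DataFrame(rows)

    acc = table.pivot(index="subject", columns="method", values="block_accuracy")
    significance = {}
    for method in methods:
        if method == "none":
            continue
        diff = acc[method] - acc["none"]
        if np.allclose(diff, 0):
            significance[method] = {"p_value": 1.0, "mean_difference": 0.0}
        else:
            stat = stats.wilcoxon(acc[method], acc["none"], zero_method="wilcox")
            significance[method] = {
                "p_value": float(stat.pvalue),
                "mean_difference": float(diff.mean()),
            }

    cohort_mean = float(acc["none"].mean())
    poor = acc.index[acc["none"] < cohort_mean]
    return {
        "table": table,
        "significance": significance,
        "poor_performers": {
            "subjects": list(map(int, poor)),
            "threshold": cohort_mean,
            "mean_accuracy": acc.loc[poor].mean().to_dict() if len(poor) else {},
        },
    }


def ratio_sweep(
    session: SessionRecording,
    ratios: list[float] | None = None,
    params: SamplerParams = SamplerParams(),
    spec: SvmSpec = SvmSpec(),
    method: str = "b-smote",
    selection_minutes: float = 10.0 / 60.0,
) -> pd.DataFrame:
    """Oversample toward a grid of minority/majority ratios and score each.

    The natural ratio of the design is 1/(n_stimuli - 1); ratios below it
    are rejected (an oversampler cannot shrink the minority).  At the
    natural ratio no synthesis happens and the row equals the no-balancing
    run.  Returns one row per ratio with train and test binary metrics and
    the block-level interface accuracy.
    """
    cfg = session.config
    natural = 1.0 / (cfg.n_stimuli - 1)
    if ratios is None:
        ratios = list(np.linspace(natural, 1.0, 7))
    for r in ratios:
        if r < natural - 1e-9 or r > 1.0 + 1e-9:
            raise ValueError(f"ratio {r} outside [{natural:.4f}, 1]")
    train, test = session_features(session)
    rows = []
    for r in ratios:
        p = SamplerParams(
            k=params.k, m=params.m, beta=params.beta,
            sampling_ratio=min(float(r), 1.0), ncr_k=params.ncr_k, seed=params.seed,
        )
        res = apply_sampler(method, train.X, train.y, p)
        resampled = FeatureDataset(
            X=res.X, y=res.y,
            block_id=np.full(len(res.y), -1),
            stimulus_id=np.full(len(res.y), -1),
        )
        model = train_svm(resampled, spec)
        rep = _evaluate_on_session(model, test, session, method, selection_minutes)
        train_cm = confusion_metrics(train.y, model.predict_label(train.X))
        rows.append({
            "ratio": float(r),
            "n_synthesized": len(res.synthetic_parent),
            "train_recall": train_cm.recall,
            "train_precision": train_cm.precision,
            "train_f1": train_cm.f1,
            "train_accuracy": train_cm.accuracy,
            "test_recall": rep.confusion.recall,
            "test_precision": rep.confusion.precision,
            "test_f1": rep.confusion.f1,
            "test_accuracy": rep.confusion.accuracy,
            "bci_accuracy": rep.block_accuracy,
        })
    return pd.DataFrame(rows)


def sweep_correlations(sweeps: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each binary measure with block accuracy.

    ``sweeps`` may pool several subjects' sweep tables; correlations are
    computed across all rows, separately for the train- and test-session
    measures, with t-approximation p-values.
    """
    out = []
    for split in ("train", "test"):
        for measure in ("recall", "precision", "f1", "accuracy"):
            col = f"{split}_{measure}"
            x = sweeps[col].astype(float)
            y = sweeps["bci_accuracy"].astype(float)
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
                r_val, p_val = float("nan"), float("nan")
            else:
                r_val, p_val = stats.pearsonr(x[ok], y[ok])
            out.append({"session": split, "measure": measure,
                        "corrcoef": float(r_val), "p_value": float(p_val)})
    return pd.DataFrame(out)
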