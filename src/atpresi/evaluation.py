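"""Evaluation: confusion-matrix metrics, ROC/AUC, the 5-fold CV protocol
and the independent-test protocol.

Per-residue binding prediction is heavily imbalanced (roughly 1 binding
residue in 27), so accuracy alone is uninformative; the headline metric is
the Matthews correlation coefficient, reported alongside sensitivity,
specificity, accuracy and AUC.  Cross-validation pools held-out predictions
across folds (micro-average); per-fold reports are kept for transparency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.metrics import roc_curve
from sklearn.preprocessing import StandardScaler

from .chains import DatasetSplit, ProteinChain, fragments_of
from .classifiers import DECISION_THRESHOLD
from .features import FragmentFeaturizer
from .resampling import ResampleConfig, SMOTESampler, rus_balance

__all__ = [
    "EvalReport",
    "confusion_metrics",
    "roc_auc",
    "run_cv",
    "run_independent_test",
]


@dataclass
class EvalReport:
    """Confusion counts and derived metrics for one evaluation.

    Sn, Sp and ACC are percentages; MCC is in [-1, 1] with the convention
    MCC = 0 whenever a denominator factor vanishes; AUC is present when
    scores were available.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float | None = None
    roc_points: np.ndarray | None = None  # (n, 2) of (FPR, TPR)
    per_fold: list["EvalReport"] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def summary(self) -> dict:
        out = {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "Sn": round(self.sn, 2), "Sp": round(self.sp, 2),
            "ACC": round(self.acc, 2), "MCC": round(self.mcc, 4),
        }
        if self.auc is not None:
            out["AUC"] = round(self.auc, 4)
        return out


def confusion_metrics(y_true, y_pred) -> EvalReport:
    """Sn, Sp, ACC (percent) and MCC from binary predictions.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), ACC = (TP+TN)/N, and
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
    defined as 0 when any factor of the denominator is zero.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted"
        )
    if y_true.size == 0:
        raise ValueError("empty evaluation")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    sn = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    sp = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, sn=sn, sp=sp, acc=acc, mcc=mcc)


def roc_auc(y_true, scores) -> tuple[float, np.ndarray]:
    """AUC via the midrank statistic, plus ROC curve points (FPR, TPR).

    The rank form AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg), with
    midranks for tied scores, equals trapezoidal integration of the ROC
    curve.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    ranks = rankdata(scores)  # midrank convention for ties
    auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y_true, scores)
    return float(auc), np.column_stack([fpr, tpr])


def _with_auc(report: EvalReport, y_true, scores) -> EvalReport:
    report.auc, report.roc_points = roc_auc(y_true, scores)
    return report


def _fit_predict(
    train_fragments,
    eval_fragments,
    feature_set: str,
    resample: ResampleConfig,
    model,
    seed: int,
    featurizer_kwargs: dict | None = None,
):
    """Featurize (train-fitted), scale, resample the training side only,
    fit one model per RUS repeat (1 otherwise) and score the eval side.

    Returns (y_true, list of score vectors, one per trained model).
    """
    featurizer = FragmentFeaturizer(feature_set=feature_set, **(featurizer_kwargs or {}))
    featurizer.fit(train_fragments)
    X_tr = featurizer.transform(train_fragments)
    y_tr = np.array([f.label for f in train_fragments])
    X_ev = featurizer.transform(eval_fragments)
    y_ev = np.array([f.label for f in eval_fragments])
    if not (y_tr == 1).any():
        raise ValueError("training portion has no positive fragments")

    scaler = StandardScaler().fit(X_tr)
    X_tr, X_ev = scaler.transform(X_tr), scaler.transform(X_ev)

    train_sets = []
    if resample.method == "smote":
        sampler = SMOTESampler(k_neighbors=resample.k_neighbors, random_state=seed)
        train_sets.append(sampler.fit_resample(X_tr, y_tr))
    elif resample.method == "rus":
        pos = np.flatnonzero(y_tr == 1)
        neg = np.flatnonzero(y_tr == 0)
        for rep in range(resample.rus_repeats):
            keep = np.concatenate([pos, rus_balance(neg, len(pos), seed=seed + rep)])
            train_sets.append((X_tr[keep], y_tr[keep]))
    else:
        train_sets.append((X_tr, y_tr))

    score_sets = []
    for rep, (Xb, yb) in enumerate(train_sets):
        est = clone(model)
        if "random_state" in est.get_params():
            est.set_params(random_state=seed + rep)
        est.fit(Xb, yb)
        score_sets.append(est.predict_proba(X_ev)[:, 1])
    return y_ev, score_sets


def run_cv(
    split: DatasetSplit,
    feature_set: str = "B+F+PP+E",
    resample: ResampleConfig | None = None,
    model=None,
    L: int = 17,
    seed: int = 0,
    featurizer_kwargs: dict | None = None,
) -> EvalReport:
    """Chain-level k-fold cross-validation of the full pipeline.

    Per fold, encoders are fitted on the training chains only, the training
    fragments are balanced per ``resample``, the model is trained and the
    held-out fold is scored.  Held-out predictions are pooled across folds;
    with RUS resampling the whole procedure is repeated per undersampling
    draw and metrics are averaged over repeats (pooled counts are from the
    first repeat).
    """
    resample = resample or ResampleConfig(method="none")
    if model is None:
        from .classifiers import DCNNClassifier

        model = DCNNClassifier()
    folds = split.folds()
    if not folds:
        raise ValueError("split carries no fold assignments")
    n_repeats = resample.rus_repeats if resample.method == "rus" else 1
    y_all: list[np.ndarray] = []
    scores_all: list[list[np.ndarray]] = [[] for _ in range(n_repeats)]
    per_fold = []
    for fold in folds:
        train_chains, held_chains = split.fold_chains(fold)
        train_frags = fragments_of(train_chains, L=L)
        held_frags = fragments_of(held_chains, L=L)
        if not any(f.label for f in held_frags):
            raise ValueError(f"fold {fold} has no positive fragments")
        y_ev, score_sets = _fit_predict(
            train_frags, held_frags, feature_set, resample, model,
            seed=seed + 1000 * fold, featurizer_kwargs=featurizer_kwargs,
        )
        y_all.append(y_ev)
        for rep in range(n_repeats):
            scores_all[rep].append(score_sets[rep])
        fold_pred = (score_sets[0] >= DECISION_THRESHOLD).astype(int)
        per_fold.append(_with_auc(confusion_metrics(y_ev, fold_pred), y_ev, score_sets[0]))

    y_pooled = np.concatenate(y_all)
    repeat_reports = []
    for rep in range(n_repeats):
        s = np.concatenate(scores_all[rep])
        rep_report = confusion_metrics(y_pooled, (s >= DECISION_THRESHOLD).astype(int))
        repeat_reports.append(_with_auc(rep_report, y_pooled, s))
    report = repeat_reports[0]
    if n_repeats > 1:
        report.extra["rus_repeat_metrics"] = [r.summary() for r in repeat_reports]
        report.extra["rus_mean"] = {
            key: float(np.mean([r.summary()[key] for r in repeat_reports]))
            for key in ("Sn", "Sp", "ACC", "MCC", "AUC")
        }
    report.per_fold = per_fold
    return report


def run_independent_test(
    train_chains: list[ProteinChain],
    test_chains: list[ProteinChain],
    feature_set: str = "B+F+PP+E",
    resample: ResampleConfig | None = None,
    model=None,
    L: int = 17,
    seed: int = 0,
    featurizer_kwargs: dict | None = None,
) -> EvalReport:
    """Fit encoders and model on the full training set, score the test set.

    Train and test chain-id sets must be disjoint.
    """
    overlap = {c.chain_id for c in train_chains} & {c.chain_id for c in test_chains}
    if overlap:
        raise ValueError(f"train/test chain ids overlap: {sorted(overlap)}")
    resample = resample or ResampleConfig(method="none")
    if model is None:
        from .classifiers import DCNNClassifier

        model = DCNNClassifier()
    y_ev, score_sets = _fit_predict(
        fragments_of(train_chains, L=L),
        fragments_of(test_chains, L=L),
        feature_set, resample, model, seed=seed,
        featurizer_kwargs=featurizer_kwargs,
    )
    scores = np.mean(score_sets, axis=0) if len(score_sets) > 1 else score_sets[0]
    report = confusion_metrics(y_ev, (scores >= DECISION_THRESHOLD).astype(int))
    return _with_auc(report, y_ev, scores)
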