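"""Intra-/inter-subject 3-class emotion classification and evaluation.

Datasets are evaluated with stratified ten-fold cross-validation using
three classifier families (RBF-kernel SVM, k-nearest neighbors, random
forest).  Features are z-scored with training-fold statistics only, so no
test information leaks into the scaling.  Reported metrics follow the
standard multiclass realization: accuracy = trace of the pooled confusion
matrix over its total (the micro-averaged one-vs-rest accuracy), macro
precision/recall with a zero convention for empty denominators, and F1 as
the harmonic mean of macro precision and macro recall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import CLASS_ORDER, AffectState, FeatureVector

CLASSIFIER_NAMES = ("svm", "knn", "random_forest")
_ALIASES = {"rf": "random_forest"}


@dataclass
class Dataset:
    """Feature matrix + labels for one evaluation unit.

    mode "intra_subject": exactly one subject's windows; mode
    "inter_subject": the pooled cohort.
    """

    X: np.ndarray
    y: np.ndarray  # integer indices into CLASS_ORDER
    mode: str
    subject_scope: tuple[str, ...]
    scheme: str = ""
    window_s: float = float("nan")

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.mode not in ("intra_subject", "inter_subject"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")

    @property
    def n(self) -> int:
        return int(self.y.size)

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.y).size)


@dataclass
class EvalReport:
    """Cross-validation result: per-fold accuracies, pooled 3x3 confusion
    matrix (rows = true Neg/Pos/Nu, columns = predicted), and macro metrics."""

    classifier_name: str
    scheme: str
    mode: str
    window_s: float
    seed: int
    per_fold_accuracy: list[float]
    confusion: np.ndarray
    subject_scope: tuple[str, ...] = ()

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    @property
    def macro_precision(self) -> float:
        return macro_prf(self.confusion)[0]

    @property
    def macro_recall(self) -> float:
        return macro_prf(self.confusion)[1]

    @property
    def f1(self) -> float:
        return macro_prf(self.confusion)[2]

    def to_dict(self) -> dict:
        p, r, f = macro_prf(self.confusion)
        return {
            "classifier": self.classifier_name,
            "scheme": self.scheme,
            "mode": self.mode,
            "window_s": self.window_s,
            "seed": self.seed,
            "subjects": list(self.subject_scope),
            "per_fold_accuracy": [float(a) for a in self.per_fold_accuracy],
            "mean_accuracy": self.mean_accuracy,
            "confusion": self.confusion.astype(int).tolist(),
            "macro_precision": p,
            "macro_recall": r,
            "f1": f,
        }


def labels_to_indices(labels: Iterable[AffectState]) -> np.ndarray:
    return np.array([CLASS_ORDER.index(l) for l in labels], dtype=int)


def features_to_matrix(
    features: Sequence[FeatureVector],
) -> tuple[np.ndarray, np.ndarray]:
    lengths = {f.values.size for f in features}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent feature lengths: {sorted(lengths)}")
    X = np.vstack([f.values for f in features])
    y = labels_to_indices(f.label for f in features)
    return X, y


def build_dataset(
    features_by_subject: dict[str, Sequence[FeatureVector]],
    mode: str,
    k: int = 10,
) -> list[Dataset]:
    """Assemble evaluation datasets: one per subject (intra) or one pooled (inter)."""
    if mode not in ("intra_subject", "inter_subject"):
        raise ValueError(f"unknown mode {mode!r}")
    for sid, feats in features_by_subject.items():
        if len(feats) < k:
            raise ValueError(
                f"subject {sid} has only {len(feats)} windows, fewer than k={k}; "
                f"use a smaller k"
            )
    datasets: list[Dataset] = []
    if mode == "intra_subject":
        for sid, feats in features_by_subject.items():
            X, y = features_to_matrix(list(feats))
            if np.unique(y).size < 2:
                raise ValueError(
                    f"subject {sid} has windows of a single class; "
                    f"intra-subject training is degenerate"
                )
            datasets.append(
                Dataset(
                    X=X,
                    y=y,
                    mode=mode,
                    subject_scope=(sid,),
                    scheme=feats[0].scheme,
                )
            )
    else:
        all_feats = [f for feats in features_by_subject.values() for f in feats]
        X, y = features_to_matrix(all_feats)
        datasets.append(
            Dataset(
                X=X,
                y=y,
                mode=mode,
                subject_scope=tuple(sorted(features_by_subject)),
                scheme=all_feats[0].scheme,
            )
        )
    return datasets


def make_classifier(name: str, seed: int = 0) -> Pipeline:
    """Classifier with fold-local z-scoring.

    Defaults: RBF SVM (C=1, gamma='scale'); 5-NN with Euclidean distance;
    100-tree random forest with Gini impurity.
    """
    name = _ALIASES.get(name, name)
    if name == "svm":
        clf = SVC(C=1.0, kernel="rbf", gamma="scale", random_state=seed)
    elif name == "knn":
        clf = KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    elif name == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=100, criterion="gini", random_state=seed
        )
    else:
        raise ValueError(f"unknown classifier {name!r}; use one of {CLASSIFIER_NAMES}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def stratified_folds(
    y: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled stratified k-fold split; re-drawn once if a training split
    misses a class, then it errors."""
    y = np.asarray(y)
    for attempt_seed in (seed, seed + 1):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=attempt_seed)
        folds = list(skf.split(np.zeros_like(y)[:, None], y))
        if all(np.unique(y[tr]).size == np.unique(y).size for tr, _ in folds):
            return folds
    raise RuntimeError(
        f"a class is absent from a training split even after a re-draw (k={k})"
    )


def kfold_cv(
    dataset: Dataset,
    classifier: str = "svm",
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation with a pooled confusion matrix."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if dataset.n < k:
        raise ValueError(f"dataset of size {dataset.n} cannot be split into {k} folds")
    if dataset.n_classes < 2:
        raise ValueError("dataset must contain at least two classes")

    conf = np.zeros((3, 3), dtype=int)
    per_fold_acc: list[float] = []
    for tr, te in stratified_folds(dataset.y, k, seed):
        model = make_classifier(classifier, seed=seed)
        model.fit(dataset.X[tr], dataset.y[tr])
        pred = model.predict(dataset.X[te])
        per_fold_acc.append(float(np.mean(pred == dataset.y[te])))
        for t, p in zip(dataset.y[te], pred):
            conf[t, p] += 1

    return EvalReport(
        classifier_name=_ALIASES.get(classifier, classifier),
        scheme=dataset.scheme,
        mode=dataset.mode,
        window_s=dataset.window_s,
        seed=seed,
        per_fold_accuracy=per_fold_acc,
        confusion=conf,
        subject_scope=dataset.subject_scope,
    )


def accuracy(conf: np.ndarray) -> float:
    """Multiclass accuracy: trace over total of the confusion matrix.

    This equals the binary TP+TN / (TP+TN+FP+FN) formula evaluated
    one-vs-rest and micro-averaged.
    """
    conf = np.asarray(conf)
    total = conf.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    return float(np.trace(conf) / total)


def macro_prf(conf: np.ndarray) -> tuple[float, float, float]:
    """Macro precision/recall over the three classes and their harmonic-mean F1.

    A class never predicted (or absent from the truth) contributes 0 to the
    corresponding macro average.
    """
    conf = np.asarray(conf, dtype=float)
    if conf.sum() <= 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(conf)
    pred_tot = conf.sum(axis=0)
    true_tot = conf.sum(axis=1)
    prec = np.divide(tp, pred_tot, out=np.zeros(3), where=pred_tot > 0)
    rec = np.divide(tp, true_tot, out=np.zeros(3), where=true_tot > 0)
    mp, mr = float(prec.mean()), float(rec.mean())
    f1 = 0.0 if mp + mr == 0 else 2 * mp * mr / (mp + mr)
    return mp, mr, f1


def evaluate_grid(
    features_by_subject_by_scheme: dict[str, dict[str, Sequence[FeatureVector]]],
    classifiers: Sequence[str] = CLASSIFIER_NAMES,
    modes: Sequence[str] = ("inter_subject", "intra_subject"),
    k: int = 10,
    seed: int = 0,
    window_s: float = float("nan"),
) -> list[EvalReport]:
    """Run the scheme x classifier (x subject, for intra) evaluation grid."""
    reports: list[EvalReport] = []
    for scheme, by_subject in features_by_subject_by_scheme.items():
        for mode in modes:
            for ds in build_dataset(by_subject, mode, k=k):
                ds.window_s = window_s
                for clf in classifiers:
                    reports.append(kfold_cv(ds, classifier=clf, k=k, seed=seed))
    return reports


def reports_to_table(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Flatten evaluation reports into a tidy table (one row per report)."""
    rows = []
    for r in reports:
        p, rec, f1 = macro_prf(r.confusion)
        rows.append(
            {
                "mode": r.mode,
                "scheme": r.scheme,
                "classifier": r.classifier_name,
                "window_s": r.window_s,
                "subjects": "+".join(r.subject_scope),
                "mean_accuracy": r.mean_accuracy,
                "macro_precision": p,
                "macro_recall": rec,
                "f1": f1,
            }
        )
    return pd.DataFrame(rows)


def compare_schemes(
    sessions,
    window_s_list: Sequence[float] = (2.0, 3.0, 5.0),
    schemes: Sequence[str] = ("raw_hr", "dwt"),
    classifiers: Sequence[str] = CLASSIFIER_NAMES,
    modes: Sequence[str] = ("inter_subject", "intra_subject"),
    threshold: float = 0.5,
    k: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[EvalReport]]:
    """Grid of evaluations over window size x scheme x classifier (x mode).

    Each session is annotated with its ground-truth-backed human oracle at
    the given escalation threshold, featurized under both schemes, and
    evaluated with stratified k-fold CV.  Returns a tidy summary table plus
    the full reports.
    """
    from .annotation import TruthOracle, annotate_session
    from .features import assemble_features

    all_reports: list[EvalReport] = []
    for window_s in window_s_list:
        feats_by_scheme: dict[str, dict[str, list[FeatureVector]]] = {
            s: {} for s in schemes
        }
        for sess in sessions:
            oracle = TruthOracle(sess.truth, window_s)
            windows, _ = annotate_session(
                sess.fer,
                sess.hr,
                fps=_infer_fps(sess),
                window_s=window_s,
                threshold=threshold,
                oracle=oracle,
            )
            for scheme in schemes:
                feats_by_scheme[scheme][sess.subject_id] = assemble_features(
                    windows, scheme=scheme
                )
        all_reports.extend(
            evaluate_grid(
                feats_by_scheme,
                classifiers=classifiers,
                modes=modes,
                k=k,
                seed=seed,
                window_s=window_s,
            )
        )
    return reports_to_table(all_reports), all_reports


def _infer_fps(session) -> float:
    return len(session.fer) / session.truth.duration_s
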