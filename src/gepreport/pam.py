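"""Nearest-shrunken-centroid (PAM-style) classification and identity control.

The classifier implements the standard shrunken-centroid rule: per-feature
class deviations

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),   m_k = sqrt(1/n_k - 1/n)

are soft-thresholded at Delta, shrunken centroids are reconstructed as
``xbar_i + m_k * (s_i + s0) * d'_ik``, and classification minimises

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log(pi_k)

with posteriors given by softmax(-delta_k / 2). ``s0`` defaults to the
median of the pooled within-class standard deviations.

Identity control trains one classifier per axis (sex, IgL, IgH), compares
predictions to the recorded labels, and flags potential sample interchanges
when a sample mismatches on at least two of the three axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from ._utils import round_half_up
from .cohort import ExpressionMatrix


class FeatureAlignmentError(ValueError):
    """Query matrix does not carry the features the classifier was trained on."""


class ShrunkenCentroidClassifier(ClassifierMixin, BaseEstimator):
    """Nearest shrunken centroids with class priors and posteriors.

    Parameters
    ----------
    delta:
        Soft-threshold amount (>= 0). ``None`` selects Delta by stratified
        cross-validation over a grid of observed deviation magnitudes, with
        ties broken toward the larger (sparser) Delta.
    priors:
        ``"empirical"`` (class frequencies), ``"uniform"``, or an array.
    s0:
        Fudge constant added to pooled SDs; ``"median"`` uses the median
        pooled SD.
    cv_folds:
        Folds used when ``delta`` is selected by cross-validation.
    """

    def __init__(self, delta: float | None = 0.0, priors="empirical",
                 s0="median", cv_folds: int = 5):
        self.delta = delta
        self.priors = priors
        self.s0 = s0
        self.cv_folds = cv_folds

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x features)")
        if hasattr(X, "columns"):  # pragma: no cover - ndarray after asarray
            pass
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes to train")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            small = classes[np.argmin(counts)]
            raise ValueError(f"class {small!r} has fewer than 2 samples")
        n, p = X.shape
        overall = X.mean(axis=0)
        centroids = np.vstack([X[y_idx == k].mean(axis=0)
                               for k in range(len(classes))])
        # pooled within-class variance with n - K degrees of freedom
        ss = np.zeros(p)
        for k in range(len(classes)):
            ss += ((X[y_idx == k] - centroids[k]) ** 2).sum(axis=0)
        s = np.sqrt(ss / (n - len(classes)))
        s0 = float(np.median(s)) if self.s0 == "median" else float(self.s0)
        m = np.sqrt(np.maximum(1.0 / counts - 1.0 / n, 1e-12))

        if self.priors == "empirical":
            priors = counts / n
        elif self.priors == "uniform":
            priors = np.full(len(classes), 1.0 / len(classes))
        else:
            priors = np.asarray(self.priors, dtype=float)
            priors = priors / priors.sum()

        d = (centroids - overall) / (m[:, None] * (s + s0))
        delta = self.delta
        if delta is None:
            delta = self._select_delta(X, y, d)
        if delta < 0:
            raise ValueError("delta must be >= 0")
        d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)

        self.classes_ = classes
        self.class_counts_ = counts
        self.overall_centroid_ = overall
        self.pooled_sd_ = s
        self.s0_ = s0
        self.m_k_ = m
        self.priors_ = priors
        self.delta_ = float(delta)
        self.deviations_ = d_shrunk
        self.shrunken_centroids_ = overall + m[:, None] * (s + s0) * d_shrunk
        self.active_features_ = np.flatnonzero(
            np.any(d_shrunk != 0.0, axis=0))
        self.n_features_in_ = p
        return self

    def _select_delta(self, X, y, d) -> float:
        grid = np.quantile(np.abs(d), np.linspace(0.0, 1.0, 21))
        grid = np.unique(np.concatenate([[0.0], grid]))
        counts = np.bincount(np.unique(y, return_inverse=True)[1])
        folds = int(min(self.cv_folds, counts.min()))
        if folds < 2:
            return 0.0
        skf = StratifiedKFold(n_splits=folds, shuffle=False)
        errors = np.zeros(len(grid))
        for train, test in skf.split(X, y):
            for gi, delta in enumerate(grid):
                clf = ShrunkenCentroidClassifier(
                    delta=float(delta), priors=self.priors, s0=self.s0)
                clf.fit(X[train], y[train])
                errors[gi] += np.sum(clf.predict(X[test]) != y[test])
        best = errors.min()
        # ties broken toward larger delta -> sparser model
        return float(grid[np.flatnonzero(errors == best)[-1]])

    # -- prediction --------------------------------------------------------
    def discriminant(self, X) -> np.ndarray:
        """delta_k(x) for every sample (rows) and class (columns)."""
        check_is_fitted(self, "shrunken_centroids_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise FeatureAlignmentError(
                f"query has {X.shape[1]} features, classifier was trained "
                f"on {self.n_features_in_}")
        denom = (self.pooled_sd_ + self.s0_) ** 2
        scores = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            scores[:, k] = (((X - self.shrunken_centroids_[k]) ** 2) / denom
                            ).sum(axis=1) - 2.0 * np.log(self.priors_[k])
        return scores

    def predict(self, X):
        return self.classes_[np.argmin(self.discriminant(X), axis=1)]

    def predict_proba(self, X):
        z = -0.5 * self.discriminant(X)
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # -- persistence -------------------------------------------------------
    def to_json(self, feature_names: list[str] | None = None) -> str:
        check_is_fitted(self, "shrunken_centroids_")
        payload = {
            "format": "gepreport-shrunken-centroid-v1",
            "classes": [str(c) for c in self.classes_],
            "class_counts": self.class_counts_.tolist(),
            "overall_centroid": self.overall_centroid_.tolist(),
            "shrunken_centroids": self.shrunken_centroids_.tolist(),
            "pooled_sd": self.pooled_sd_.tolist(),
            "s0": self.s0_,
            "delta": self.delta_,
            "priors": self.priors_.tolist(),
            "feature_names": feature_names,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ShrunkenCentroidClassifier":
        payload = json.loads(text)
        if payload.get("format") != "gepreport-shrunken-centroid-v1":
            raise ValueError("not a shrunken-centroid classifier artifact")
        clf = cls(delta=payload["delta"])
        clf.classes_ = np.asarray(payload["classes"])
        clf.class_counts_ = np.asarray(payload["class_counts"])
        clf.overall_centroid_ = np.asarray(payload["overall_centroid"])
        clf.shrunken_centroids_ = np.asarray(payload["shrunken_centroids"])
        clf.pooled_sd_ = np.asarray(payload["pooled_sd"])
        clf.s0_ = payload["s0"]
        clf.delta_ = payload["delta"]
        clf.priors_ = np.asarray(payload["priors"])
        clf.deviations_ = None
        clf.n_features_in_ = len(clf.pooled_sd_)
        clf.active_features_ = np.flatnonzero(
            np.any(clf.shrunken_centroids_ != clf.overall_centroid_, axis=0))
        clf.feature_names_ = payload.get("feature_names")
        return clf


def train_centroid_classifier(matrix: ExpressionMatrix, labels: pd.Series,
                              delta: float | None = 0.0,
                              features: list[str] | None = None,
                              priors="empirical") -> ShrunkenCentroidClassifier:
    """Train a shrunken-centroid classifier on (a feature subset of) a matrix.

    ``labels`` is indexed by sample id; samples with missing labels are
    dropped from training.
    """
    labels = labels.dropna()
    labels = labels[labels.astype(str) != "unknown"]
    use = [s for s in matrix.samples if s in labels.index]
    if features is None:
        features = matrix.features
    X = matrix.data.loc[features, use].T.to_numpy(float)
    clf = ShrunkenCentroidClassifier(delta=delta, priors=priors)
    clf.fit(X, labels.loc[use].to_numpy())
    clf.feature_names_ = list(features)
    return clf


# -- identity control ------------------------------------------------------

IDENTITY_AXES = ("sex", "IgL", "IgH")


@dataclass
class ConfusionTable:
    """Per-axis confusion of recorded (rows) vs predicted (columns) labels."""

    axis: str
    table: pd.DataFrame
    mismatched_samples: list = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return int(self.table.to_numpy().sum()) == 0

    @property
    def class_totals(self) -> pd.Series:
        return self.table.sum(axis=1)


@dataclass
class ErrorRateReport:
    per_axis: dict  # axis -> {"per_class": {...}, "overall": pct, "n": int}
    interchange_flags: dict  # sample_id -> number of failed axes
    n_failed_all_axes: int = 0
    min_axes_for_flag: int = 2


def predict_identity(classifiers: dict, matrix: ExpressionMatrix) -> dict:
    """Apply per-axis classifiers; returns axis -> DataFrame per sample.

    Each frame holds a ``predicted`` column plus one posterior column per
    class (``posterior_<class>``).
    """
    out = {}
    for axis, clf in classifiers.items():
        features = getattr(clf, "feature_names_", None)
        if features is None:
            raise FeatureAlignmentError(
                f"classifier for axis {axis!r} has no stored feature names")
        missing = [f for f in features if f not in matrix.data.index]
        if missing:
            raise FeatureAlignmentError(
                f"axis {axis!r}: matrix lacks trained features {missing[:5]}")
        X = matrix.data.loc[features].T.to_numpy(float)
        proba = clf.predict_proba(X)
        frame = pd.DataFrame(
            proba, index=matrix.samples,
            columns=[f"posterior_{c}" for c in clf.classes_])
        frame.insert(0, "predicted", clf.classes_[np.argmax(proba, axis=1)])
        out[axis] = frame
    return out


def _recorded_label(record, axis: str):
    if axis == "sex":
        val = record.sex
    elif axis == "IgL":
        val = record.igl_type
    elif axis == "IgH":
        val = record.igh_type
    else:
        raise ValueError(f"unknown identity axis {axis!r}")
    if val in ("unknown", "none", None) or (isinstance(val, float) and np.isnan(val)):
        return None
    return val


def compare_identity(predictions: dict, records: list) -> list[ConfusionTable]:
    """Confusion tables of recorded vs predicted labels, one per axis.

    Samples without a recorded label on an axis are excluded from that
    axis's totals (they are predicted but not scored).
    """
    by_id = {r.sample_id: r for r in records}
    tables = []
    for axis, frame in predictions.items():
        truths, preds, ids = [], [], []
        for sid, row in frame.iterrows():
            rec = by_id.get(sid)
            if rec is None:
                continue
            truth = _recorded_label(rec, axis)
            if truth is None:
                continue
            truths.append(truth)
            preds.append(row["predicted"])
            ids.append(sid)
        classes = sorted(set(truths) | set(preds))
        table = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        mismatched = []
        for sid, t, p in zip(ids, truths, preds):
            table.loc[t, p] += 1
            if t != p:
                mismatched.append(sid)
        table.index.name = "recorded"
        table.columns.name = "predicted"
        tables.append(ConfusionTable(axis=axis, table=table,
                                     mismatched_samples=mismatched))
    return tables


def error_rates(tables: list[ConfusionTable],
                min_axes_for_flag: int = 2) -> ErrorRateReport:
    """Per-class and overall error percentages plus interchange flagging.

    Percentages are misclassified/total x 100, rounded half-up to one
    decimal. A sample is flagged as a potential interchange when its
    prediction mismatches the recorded label on >= ``min_axes_for_flag``
    axes; the count of samples failing on every axis is reported separately.
    """
    if not tables:
        raise ValueError("error_rates needs at least one confusion table")
    per_axis = {}
    fails = {}
    for ct in tables:
        totals = ct.class_totals
        n = int(totals.sum())
        per_class = {}
        wrong_total = 0
        for cls in ct.table.index:
            total = int(totals.loc[cls])
            wrong = int(total - ct.table.loc[cls, cls]) if total else 0
            wrong_total += wrong
            per_class[cls] = round_half_up(100.0 * wrong / total, 1) if total else 0.0
        per_axis[ct.axis] = {
            "per_class": per_class,
            "overall": round_half_up(100.0 * wrong_total / n, 1) if n else 0.0,
            "n": n,
        }
        for sid in ct.mismatched_samples:
            fails[sid] = fails.get(sid, 0) + 1
    flags = {sid: k for sid, k in sorted(fails.items())
             if k >= min_axes_for_flag}
    n_all = sum(1 for k in fails.values() if k == len(tables))
    return ErrorRateReport(per_axis=per_axis, interchange_flags=flags,
                           n_failed_all_axes=n_all,
                           min_axes_for_flag=min_axes_for_flag)


def save_classifier(clf: ShrunkenCentroidClassifier, path: str | Path) -> None:
    Path(path).write_text(clf.to_json(getattr(clf, "feature_names_", None)))


def load_classifier(path: str | Path) -> ShrunkenCentroidClassifier:
    return ShrunkenCentroidClassifier.from_json(Path(path).read_text())
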