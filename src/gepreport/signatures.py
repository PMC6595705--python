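"""Gene-expression risk scores, t(4;14) prediction and target-presence calls.

Signature scores are simple aggregates of log2 expression: ``mean(up genes)``
or ``mean(up) - mean(down)``. Strata are assigned by fixed cut points or by
cohort quantiles; quantile cut points are computed once on a training cohort
and frozen (prospective-use contract), so new samples are scored against the
stored values.

The shipped signature definitions are documented placeholders keyed to the
synthetic feature panel: the scoring machinery is the contract here, not a
clinically validated gene list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from . import simulate
from .cohort import ExpressionMatrix
from .pam import ShrunkenCentroidClassifier, train_centroid_classifier


class SignatureError(ValueError):
    """A signature cannot be evaluated on the given matrix."""


@dataclass(frozen=True)
class ThresholdSpec:
    """Either a fixed cut value or a quantile of the training cohort."""

    kind: str  # "fixed" | "quantile"
    value: float

    def __post_init__(self):
        if self.kind not in ("fixed", "quantile"):
            raise SignatureError(f"unknown threshold kind {self.kind!r}")
        if self.kind == "quantile" and not 0.0 < self.value < 1.0:
            raise SignatureError("quantile threshold must be in (0, 1)")


@dataclass(frozen=True)
class SignatureDefinition:
    name: str
    up_genes: tuple
    down_genes: tuple = ()
    aggregation: str = "mean-difference"  # or "mean"
    thresholds: tuple = ()  # ascending ThresholdSpecs
    strata: tuple = ("low", "high")  # len(thresholds) + 1, ascending risk
    version: str = "1"

    def __post_init__(self):
        if not self.up_genes:
            raise SignatureError(f"signature {self.name!r} has no up-genes")
        if self.aggregation not in ("mean-difference", "mean"):
            raise SignatureError(
                f"signature {self.name!r}: unknown aggregation "
                f"{self.aggregation!r}")
        if len(self.strata) != len(self.thresholds) + 1:
            raise SignatureError(
                f"signature {self.name!r}: need one stratum more than "
                f"thresholds")


@dataclass
class ScoreResult:
    sample_id: str
    score: float
    stratum: str
    thresholds: tuple
    signature: str
    version: str


# Placeholder definitions keyed to the synthetic feature panel. The quantile
# cut points mirror the high-risk fractions the generator plants (24.8% and
# 23.2% high risk; 7.9/41.9/50.2% proliferation strata).
GEP70_LIKE = SignatureDefinition(
    name="GEP70-like", up_genes=tuple(simulate.GEP70_UP),
    down_genes=tuple(simulate.GEP70_DOWN), aggregation="mean-difference",
    thresholds=(ThresholdSpec("quantile", 0.752),), strata=("low", "high"))
IFM15_LIKE = SignatureDefinition(
    name="IFM15-like", up_genes=tuple(simulate.IFM15_UP),
    aggregation="mean", thresholds=(ThresholdSpec("quantile", 0.768),),
    strata=("low", "high"))
GPI_DEFAULT = SignatureDefinition(
    name="GPI", up_genes=tuple(simulate.PROLIFERATION_GENES),
    aggregation="mean",
    thresholds=(ThresholdSpec("quantile", 0.498),
                ThresholdSpec("quantile", 0.921)),
    strata=("GPI_low", "GPI_medium", "GPI_high"))


class SignatureScorer(BaseEstimator):
    """Compute a signature score and assign strata with frozen thresholds.

    ``fit`` resolves gene lists against the training matrix (missing genes
    are warned about and skipped; no resolvable up-gene is an error) and
    freezes quantile thresholds on the training cohort. ``transform`` returns
    continuous scores, ``predict`` the stratum labels.
    """

    def __init__(self, signature: SignatureDefinition):
        self.signature = signature

    def _resolve(self, genes, frame) -> list[str]:
        present = [g for g in genes if g in frame.columns]
        missing = sorted(set(genes) - set(present))
        if missing:
            warnings.warn(
                f"signature {self.signature.name!r}: skipping unresolved "
                f"genes {missing}", stacklevel=3)
        return present

    def fit(self, X: pd.DataFrame, y=None):
        sig = self.signature
        self.up_genes_ = self._resolve(sig.up_genes, X)
        if not self.up_genes_:
            raise SignatureError(
                f"signature {sig.name!r}: no up-gene resolvable")
        self.down_genes_ = self._resolve(sig.down_genes, X)
        if sig.aggregation == "mean-difference" and sig.down_genes \
                and not self.down_genes_:
            raise SignatureError(
                f"signature {sig.name!r}: no down-gene resolvable")
        scores = self._score(X)
        cuts = []
        for spec in sig.thresholds:
            if spec.kind == "fixed":
                cuts.append(float(spec.value))
            else:
                cuts.append(float(np.quantile(scores, spec.value)))
        if cuts != sorted(cuts):
            raise SignatureError(
                f"signature {sig.name!r}: thresholds not ascending")
        self.thresholds_ = tuple(cuts)
        return self

    def _score(self, X: pd.DataFrame) -> np.ndarray:
        up = X[self.up_genes_].mean(axis=1).to_numpy(float)
        if self.signature.aggregation == "mean":
            return up
        if not self.down_genes_:
            return up
        return up - X[self.down_genes_].mean(axis=1).to_numpy(float)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        return self._score(X)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scores = self.transform(X)
        idx = np.searchsorted(np.asarray(self.thresholds_), scores,
                              side="left")
        return np.asarray(self.signature.strata, dtype=object)[idx]

    def score_results(self, X: pd.DataFrame) -> list[ScoreResult]:
        scores = self.transform(X)
        strata = self.predict(X)
        return [
            ScoreResult(sample_id=str(sid), score=float(s), stratum=str(st),
                        thresholds=self.thresholds_,
                        signature=self.signature.name,
                        version=self.signature.version)
            for sid, s, st in zip(X.index, scores, strata)
        ]


def score_signature(matrix: ExpressionMatrix, sig: SignatureDefinition,
                    train: ExpressionMatrix | None = None) -> list[ScoreResult]:
    """Score every sample; quantile thresholds frozen on ``train`` (defaults
    to the scored cohort itself)."""
    frame = matrix.to_frame()
    scorer = SignatureScorer(sig).fit((train or matrix).to_frame())
    return scorer.score_results(frame)


def score_gpi(matrix: ExpressionMatrix,
              sig: SignatureDefinition = GPI_DEFAULT,
              train: ExpressionMatrix | None = None) -> list[ScoreResult]:
    """Proliferation index with GPI_low / GPI_medium / GPI_high strata."""
    if len(sig.strata) != 3:
        raise SignatureError("GPI signature must define exactly 3 strata")
    return score_signature(matrix, sig, train=train)


def scores_frame(results: list[ScoreResult]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [{"sample_id": r.sample_id, "signature": r.signature,
          "score": r.score, "stratum": r.stratum} for r in results])
    return frame.set_index("sample_id")


# -- t(4;14) prediction ----------------------------------------------------

def train_t4_14_classifier(matrix: ExpressionMatrix, labels: pd.Series,
                           delta: float = 0.0) -> ShrunkenCentroidClassifier:
    """PAM predictor on the translocation spike-gene features."""
    spikes = matrix.features_with_role("spike:t_4_14")
    if not spikes:
        raise SignatureError("matrix has no t(4;14) spike features")
    return train_centroid_classifier(matrix, labels, delta=delta,
                                     features=spikes)


def predict_t4_14(classifier: ShrunkenCentroidClassifier,
                  matrix: ExpressionMatrix,
                  ifish: pd.Series | None = None):
    """Binary expression-based t(4;14) call with posterior.

    Returns ``(calls, discrepancy)`` where ``calls`` has columns
    ``call``/``posterior_positive`` and ``discrepancy`` is a 2x2 table of
    expression call vs iFISH where iFISH is known (``None`` without iFISH).
    """
    features = getattr(classifier, "feature_names_", None)
    if features is None or any(f not in matrix.data.index for f in features):
        from .pam import FeatureAlignmentError
        raise FeatureAlignmentError(
            "matrix lacks the spike features the t(4;14) predictor uses")
    X = matrix.data.loc[features].T.to_numpy(float)
    proba = classifier.predict_proba(X)
    pos_col = int(np.flatnonzero(classifier.classes_ == "positive")[0])
    calls = pd.DataFrame({
        "call": classifier.classes_[np.argmax(proba, axis=1)],
        "posterior_positive": proba[:, pos_col],
    }, index=pd.Index(matrix.samples, name="sample_id"))
    discrepancy = None
    if ifish is not None:
        known = ifish[ifish.isin(["present", "absent"])]
        joined = calls.loc[calls.index.intersection(known.index)]
        discrepancy = pd.crosstab(
            joined["call"].rename("expression_call"),
            known.loc[joined.index].rename("ifish"))
        discrepancy = discrepancy.reindex(
            index=["negative", "positive"], columns=["absent", "present"],
            fill_value=0)
    return calls, discrepancy


# -- presence / absence calls ---------------------------------------------

@dataclass
class TargetCall:
    sample_id: str
    gene: str
    call: str  # "expressed" | "absent"
    evidence: float  # posterior (mixture) or score margin (threshold)
    method: str


class GaussianPresenceCaller(BaseEstimator):
    """Two-component Gaussian mixture presence/absence caller.

    Fit on the cohort-wide distribution of one gene; a sample is called
    ``expressed`` when the posterior of the higher-mean component exceeds
    0.5. If the fit is degenerate — Ashman's bimodality statistic
    ``D = sqrt(2) |mu1 - mu0| / sqrt(sd0^2 + sd1^2)`` below
    ``min_separation`` (a unimodal Gaussian split in half scores about 2.2),
    or a vanishing component weight — the caller falls back to a fixed
    threshold with a warning.
    """

    def __init__(self, min_separation: float = 2.5,
                 fallback_threshold: float | None = None,
                 random_state: int = 0):
        self.min_separation = min_separation
        self.fallback_threshold = fallback_threshold
        self.random_state = random_state

    def fit(self, values):
        x = np.asarray(values, dtype=float).reshape(-1, 1)
        gm = GaussianMixture(n_components=2, n_init=5,
                             random_state=self.random_state)
        gm.fit(x)
        mus = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        sep = np.sqrt(2.0) * abs(mus[1] - mus[0]) / np.sqrt((sds ** 2).sum())
        self.degenerate_ = bool(sep < self.min_separation
                                or gm.weights_.min() < 0.02)
        if self.degenerate_:
            thr = (self.fallback_threshold
                   if self.fallback_threshold is not None
                   else float(np.mean(x)))
            warnings.warn(
                "mixture components collapsed; falling back to fixed "
                f"threshold {thr:.3g}", stacklevel=2)
            self.threshold_ = float(thr)
            self.method_ = "threshold-fallback"
        else:
            self.mixture_ = gm
            self.expressed_component_ = int(np.argmax(mus))
            self.method_ = "mixture"
        return self

    def predict_proba_expressed(self, values) -> np.ndarray:
        check_is_fitted(self, "method_")
        x = np.asarray(values, dtype=float).reshape(-1, 1)
        if self.method_ == "mixture":
            return self.mixture_.predict_proba(x)[:, self.expressed_component_]
        return (x.ravel() > self.threshold_).astype(float)

    def predict(self, values) -> np.ndarray:
        post = self.predict_proba_expressed(values)
        return np.where(post > 0.5, "expressed", "absent")


def call_presence(matrix: ExpressionMatrix, gene: str,
                  method: str = "mixture",
                  params: dict | None = None) -> list[TargetCall]:
    """Presence/absence calls for one gene across the cohort.

    ``method="threshold"`` uses a fixed log2 cut (``params["threshold"]``);
    ``method="mixture"`` (default) fits a cohort-level two-component
    Gaussian mixture and calls the higher-mean component.
    """
    params = dict(params or {})
    if gene not in matrix.data.index:
        raise SignatureError(f"gene {gene!r} not present in matrix")
    values = matrix.data.loc[gene].to_numpy(float)
    if method == "threshold":
        thr = float(params["threshold"])
        calls = np.where(values > thr, "expressed", "absent")
        return [TargetCall(sample_id=s, gene=gene, call=str(c),
                           evidence=float(v - thr),
                           method=f"threshold@{thr:g}")
                for s, c, v in zip(matrix.samples, calls, values)]
    if method != "mixture":
        raise ValueError(f"unknown presence-call method {method!r}")
    caller = GaussianPresenceCaller(**params).fit(values)
    post = caller.predict_proba_expressed(values)
    calls = caller.predict(values)
    return [TargetCall(sample_id=s, gene=gene, call=str(c),
                       evidence=float(p), method=caller.method_)
            for s, c, p in zip(matrix.samples, calls, post)]


def calls_frame(calls: list[TargetCall]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [{"sample_id": c.sample_id, "gene": c.gene, "call": c.call,
          "evidence": c.evidence, "method": c.method} for c in calls])
    return frame.set_index("sample_id")


# -- YAML signature interchange -------------------------------------------

def signature_to_yaml(sig: SignatureDefinition) -> str:
    return yaml.safe_dump({
        "name": sig.name,
        "up_genes": list(sig.up_genes),
        "down_genes": list(sig.down_genes),
        "aggregation": sig.aggregation,
        "thresholds": [{"kind": t.kind, "value": t.value}
                       for t in sig.thresholds],
        "strata": list(sig.strata),
        "version": sig.version,
    }, sort_keys=False)


def signature_from_yaml(text: str) -> SignatureDefinition:
    d = yaml.safe_load(text)
    return SignatureDefinition(
        name=d["name"], up_genes=tuple(d["up_genes"]),
        down_genes=tuple(d.get("down_genes", ())),
        aggregation=d.get("aggregation", "mean-difference"),
        thresholds=tuple(ThresholdSpec(t["kind"], float(t["value"]))
                         for t in d.get("thresholds", ())),
        strata=tuple(d.get("strata", ("low", "high"))),
        version=str(d.get("version", "1")))
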