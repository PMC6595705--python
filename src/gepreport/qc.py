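"""Per-sample quality control.

Seven per-sample quality metrics are evaluated against configurable bands:
inside the pass band -> ``pass``; inside the wider minor band -> a
``minor_warning``; outside the minor band -> ``major_fail``. A sample is
excluded if and only if at least one metric is a major failure; minor
warnings are counted but never exclude.

The seven metrics (all computed on log2 intensities):

1. ``median_intensity``    - per-sample median over all features
2. ``dynamic_range``       - 99th minus 1st intensity percentile
3. ``pct_above_background``- fraction of features above a background level
4. ``median_correlation``  - Spearman correlation to the cohort median profile
5. ``identity_marker_intensity`` - mean intensity over identity-marker features
6. ``signature_coverage``  - fraction of configured signature features present
7. ``missing_fraction``    - fraction of missing (NaN) values
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ExpressionMatrix

METRICS = (
    "median_intensity",
    "dynamic_range",
    "pct_above_background",
    "median_correlation",
    "identity_marker_intensity",
    "signature_coverage",
    "missing_fraction",
)

PASS = "pass"
MINOR = "minor_warning"
MAJOR = "major_fail"


@dataclass(frozen=True)
class Band:
    """Nested acceptance bands: pass within [pass_lo, pass_hi], minor within
    [minor_lo, minor_hi], major outside. One-sided bands use +-inf."""

    pass_lo: float = -np.inf
    pass_hi: float = np.inf
    minor_lo: float = -np.inf
    minor_hi: float = np.inf

    def status(self, value: float) -> str:
        if not np.isfinite(value):
            return MINOR  # incomputable metrics degrade to a minor warning
        if self.pass_lo <= value <= self.pass_hi:
            return PASS
        if self.minor_lo <= value <= self.minor_hi:
            return MINOR
        return MAJOR


@dataclass
class QCConfig:
    bands: dict = field(default_factory=lambda: {
        "median_intensity": Band(5.5, 8.5, 4.5, 9.5),
        "dynamic_range": Band(3.0, np.inf, 2.0, np.inf),
        "pct_above_background": Band(0.80, 1.0, 0.60, 1.0),
        "median_correlation": Band(0.60, 1.0, 0.30, 1.0),
        "identity_marker_intensity": Band(5.0, np.inf, 4.0, np.inf),
        "signature_coverage": Band(0.90, 1.0, 0.70, 1.0),
        "missing_fraction": Band(0.0, 0.02, 0.0, 0.10),
    })
    background_level: float = 4.0  # log2 units, metric 3
    signature_features: tuple = ()  # expected ids for metric 6; empty -> roles

    def validate(self) -> None:
        missing = [m for m in METRICS if m not in self.bands]
        if missing:
            raise ValueError(f"QCConfig missing bands for metrics: {missing}")


@dataclass
class QCResult:
    sample_id: str
    metrics: dict  # metric -> (value, status)
    n_minor_warnings: int
    excluded: bool

    def status_of(self, metric: str) -> str:
        return self.metrics[metric][1]


def _expected_signature_features(matrix: ExpressionMatrix,
                                 config: QCConfig) -> list[str]:
    if config.signature_features:
        return list(config.signature_features)
    return matrix.features_with_role("signature:")


def run_quality_control(matrix: ExpressionMatrix,
                        qc_config: QCConfig | None = None) -> list[QCResult]:
    """Evaluate the 7 quality metrics for every sample in the matrix."""
    config = qc_config or QCConfig()
    config.validate()
    if not matrix.samples:
        raise ValueError("quality control needs a non-empty matrix")

    data = matrix.data
    median_profile = data.median(axis=1)
    identity_features = matrix.features_with_role("identity:")
    expected_sig = _expected_signature_features(matrix, config)
    present = set(matrix.features)
    coverage = (np.mean([f in present for f in expected_sig])
                if expected_sig else 1.0)
    single_sample = len(matrix.samples) < 2

    results = []
    for sid in matrix.samples:
        col = data[sid]
        vals = col.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        missing_fraction = 1.0 - len(finite) / len(vals) if len(vals) else 1.0

        def _pct(q):
            return float(np.percentile(finite, q)) if len(finite) else np.nan

        metric_values = {
            "median_intensity": _pct(50),
            "dynamic_range": _pct(99) - _pct(1) if len(finite) else np.nan,
            "pct_above_background": (
                float(np.mean(finite > config.background_level))
                if len(finite) else np.nan),
            "median_correlation": np.nan,
            "identity_marker_intensity": (
                float(np.nanmean(marker_vals))
                if identity_features
                and np.isfinite(marker_vals := col.loc[identity_features]
                                .to_numpy(float)).any()
                else np.nan),
            "signature_coverage": float(coverage),
            "missing_fraction": float(missing_fraction),
        }
        if not single_sample and len(finite) >= 3:
            mask = np.isfinite(vals) & np.isfinite(median_profile.to_numpy(float))
            if mask.sum() >= 3:
                rho = stats.spearmanr(vals[mask],
                                      median_profile.to_numpy(float)[mask]).statistic
                metric_values["median_correlation"] = float(rho)

        metrics = {m: (metric_values[m], config.bands[m].status(metric_values[m]))
                   for m in METRICS}
        statuses = [s for _, s in metrics.values()]
        results.append(QCResult(
            sample_id=sid,
            metrics=metrics,
            n_minor_warnings=statuses.count(MINOR),
            excluded=MAJOR in statuses,
        ))
    return results


def qc_frame(results: list[QCResult]) -> pd.DataFrame:
    """One row per sample: metric values, statuses, warning count, exclusion."""
    rows = {}
    for r in results:
        row = {}
        for m, (value, status) in r.metrics.items():
            row[m] = value
            row[f"{m}_status"] = status
        row["n_minor_warnings"] = r.n_minor_warnings
        row["excluded"] = r.excluded
        rows[r.sample_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    return frame
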