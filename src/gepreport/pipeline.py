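"""File-based pipeline stages over a cohort directory.

Directory contract::

    cohort/   expression.tsv, features.tsv, samples.csv, config.yaml
    outputs/  qc.csv, identity.csv, identity_summary.json, scores.csv,
              t414.csv, targets.csv, staging.csv, metascore.csv,
              evaluation.json, reports/<sample>.json|.md

Each stage reads only the documented files, so stages can be re-run
individually. All randomness flows from a single pipeline seed; stages that
need their own stream derive sub-seeds through ``_utils.child_seed``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from . import qc as qc_mod
from . import signatures as sig_mod
from ._utils import child_seed, config_hash
from .cohort import ExpressionMatrix, SampleRecord, read_cohort, write_cohort
from .pam import (IDENTITY_AXES, compare_identity, error_rates,
                  predict_identity, train_centroid_classifier)
from .report import render_report
from .simulate import CohortConfig, generate_cohort
from .staging import MetascoreConfig, compute_iss, compute_metascore, compute_riss
from .survival import (CoxRiskModel, KaplanMeierReference,
                       compare_prediction_error, cv_prediction_error)

SIGNATURES = {
    "gep70": sig_mod.GEP70_LIKE,
    "ifm15": sig_mod.IFM15_LIKE,
    "gpi": sig_mod.GPI_DEFAULT,
}
TARGETS = ("AURKA", "IGF1R", "FGFR3")


def write_config(config: CohortConfig, path: Path) -> None:
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def read_config(path: Path) -> CohortConfig:
    return CohortConfig.from_dict(yaml.safe_load(path.read_text()))


def run_simulate(config: CohortConfig, cohort_dir: str | Path) -> Path:
    cohort_dir = Path(cohort_dir)
    matrix, records = generate_cohort(config)
    write_cohort(matrix, records, cohort_dir)
    write_config(config, cohort_dir / "config.yaml")
    return cohort_dir


def _load(cohort_dir) -> tuple[ExpressionMatrix, list[SampleRecord]]:
    return read_cohort(Path(cohort_dir))


def run_qc(cohort_dir, out_dir) -> pd.DataFrame:
    matrix, _ = _load(cohort_dir)
    frame = qc_mod.qc_frame(qc_mod.run_quality_control(matrix))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_dir / "qc.csv")
    return frame


def _axis_labels(records, axis) -> pd.Series:
    vals = {}
    for r in records:
        v = {"sex": r.sex, "IgL": r.igl_type, "IgH": r.igh_type}[axis]
        if v not in ("unknown", "none"):
            vals[r.sample_id] = v
    return pd.Series(vals, dtype=object)


def train_identity_classifiers(matrix: ExpressionMatrix, records,
                               delta: float = 0.0) -> dict:
    role_of = {"sex": "identity:sex", "IgL": "identity:igl",
               "IgH": "identity:igh"}
    classifiers = {}
    for axis in IDENTITY_AXES:
        features = matrix.features_with_role(role_of[axis])
        labels = _axis_labels(records, axis)
        # classes with a single training sample cannot be learned; drop them
        counts = labels.value_counts()
        labels = labels[labels.isin(counts.index[counts >= 2])]
        classifiers[axis] = train_centroid_classifier(
            matrix, labels, delta=delta, features=features)
    return classifiers


def run_identity(cohort_dir, out_dir, delta: float = 0.0) -> pd.DataFrame:
    matrix, records = _load(cohort_dir)
    classifiers = train_identity_classifiers(matrix, records, delta=delta)
    predictions = predict_identity(classifiers, matrix)
    tables = compare_identity(predictions, records)
    report = error_rates(tables)

    frame = pd.DataFrame(index=pd.Index(matrix.samples, name="sample_id"))
    recorded = {axis: _axis_labels(records, axis) for axis in predictions}
    for axis, pred in predictions.items():
        frame[f"{axis}_predicted"] = pred["predicted"]
        frame[f"{axis}_recorded"] = recorded[axis].reindex(frame.index)
        post_cols = [c for c in pred.columns if c.startswith("posterior_")]
        frame[f"{axis}_posterior"] = pred[post_cols].max(axis=1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_dir / "identity.csv")
    summary = {
        "per_axis": report.per_axis,
        "interchange_flags": report.interchange_flags,
        "n_failed_all_axes": report.n_failed_all_axes,
        "confusion": {t.axis: t.table.to_dict() for t in tables},
    }
    (out_dir / "identity_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
    return frame


def run_scores(cohort_dir, out_dir) -> pd.DataFrame:
    matrix, records = _load(cohort_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    frame = pd.DataFrame(index=pd.Index(matrix.samples, name="sample_id"))
    for key, sig in SIGNATURES.items():
        results = sig_mod.score_signature(matrix, sig)
        frame[f"{key}_score"] = [r.score for r in results]
        frame[f"{key}_stratum"] = [r.stratum for r in results]
    frame.to_csv(out_dir / "scores.csv")

    # expression-based t(4;14) call, trained against iFISH where known
    ifish = pd.Series({r.sample_id: r.cytogenetics.get("t_4_14", "unknown")
                       for r in records})
    labels = ifish[ifish.isin(["present", "absent"])].map(
        {"present": "positive", "absent": "negative"})
    clf = sig_mod.train_t4_14_classifier(matrix, labels)
    calls, discrepancy = sig_mod.predict_t4_14(clf, matrix, ifish=ifish)
    calls.to_csv(out_dir / "t414.csv")
    if discrepancy is not None:
        discrepancy.to_csv(out_dir / "t414_discrepancy.csv")

    target_rows = {}
    for gene in TARGETS:
        for call in sig_mod.call_presence(matrix, gene):
            target_rows.setdefault(call.sample_id, {})[gene] = call.call
            target_rows[call.sample_id][f"{gene}_evidence"] = call.evidence
    targets = pd.DataFrame.from_dict(target_rows, orient="index")
    targets.index.name = "sample_id"
    targets.to_csv(out_dir / "targets.csv")
    return frame


def run_staging(cohort_dir, out_dir) -> pd.DataFrame:
    _, records = _load(cohort_dir)
    rows = {}
    for r in records:
        iss = compute_iss(r.b2m, r.albumin)
        riss = compute_riss(iss, r.cytogenetics, r.ldh, r.ldh_uln)
        rows[r.sample_id] = {
            "iss": iss, "riss": riss.stage, "riss_note": riss.note,
            "del17p13": r.cytogenetics.get("del17p13", "unknown"),
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_dir / "staging.csv")
    return frame


def _factor_frame(out_dir: Path) -> pd.DataFrame:
    """Join upstream outputs into one factor-level table per sample."""
    scores = pd.read_csv(out_dir / "scores.csv", index_col="sample_id")
    staging = pd.read_csv(out_dir / "staging.csv", index_col="sample_id")
    t414 = pd.read_csv(out_dir / "t414.csv", index_col="sample_id")
    targets = pd.read_csv(out_dir / "targets.csv", index_col="sample_id")
    frame = pd.DataFrame(index=scores.index)
    frame["iss"] = staging["iss"]
    frame["riss"] = staging["riss"]
    frame["del17p13"] = staging["del17p13"]
    frame["t_4_14"] = t414["call"]
    frame["gep70"] = scores["gep70_stratum"]
    frame["ifm15"] = scores["ifm15_stratum"]
    frame["gpi"] = scores["gpi_stratum"]
    frame["aurka"] = targets["AURKA"]
    frame["igf1r"] = targets["IGF1R"]
    return frame


def run_metascore(cohort_dir, out_dir,
                  config: MetascoreConfig | None = None) -> pd.DataFrame:
    config = config or MetascoreConfig()
    out_dir = Path(out_dir)
    factors = _factor_frame(out_dir)
    rows = {}
    for sid, row in factors.iterrows():
        res = compute_metascore(row.to_dict(), config, sample_id=str(sid))
        rows[sid] = {"total": res.total, "stratum": res.stratum,
                     "missing_factors": ";".join(res.missing_factors),
                     "version": res.version,
                     **{f"pts_{k}": v for k, v in res.contributions.items()}}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    frame.to_csv(out_dir / "metascore.csv")
    return frame


def evaluation_frame(cohort_dir, out_dir, endpoint: str = "os") -> pd.DataFrame:
    """Complete-case model matrix for prediction-error evaluation."""
    _, records = _load(cohort_dir)
    out_dir = Path(out_dir)
    factors = _factor_frame(out_dir)
    meta = pd.read_csv(out_dir / "metascore.csv", index_col="sample_id")
    surv = pd.DataFrame(
        {"time": [getattr(r, f"{endpoint}_months") for r in records],
         "event": [getattr(r, f"{endpoint}_event") for r in records]},
        index=pd.Index([r.sample_id for r in records], name="sample_id"))
    df = factors.join(meta[["stratum"]].rename(columns={"stratum": "ms"}))
    df = df.join(surv)
    complete = df.dropna(subset=["iss", "riss", "time"])
    complete = complete[~(meta.loc[complete.index, "missing_factors"]
                          .fillna("").astype(bool))]
    model = pd.DataFrame(index=complete.index)
    model["time"] = complete["time"]
    model["event"] = complete["event"].astype(int)
    model["ms_medium"] = (complete["ms"] == "medium").astype(float)
    model["ms_high"] = (complete["ms"] == "high").astype(float)
    model["riss_II"] = (complete["riss"] == "II").astype(float)
    model["riss_III"] = (complete["riss"] == "III").astype(float)
    model["gep70_high"] = (complete["gep70"] == "high").astype(float)
    model["ifm15_high"] = (complete["ifm15"] == "high").astype(float)
    return model


def standard_models() -> dict:
    return {
        "HM-metascore": CoxRiskModel(covariates=("ms_medium", "ms_high")),
        "rISS": CoxRiskModel(covariates=("riss_II", "riss_III")),
        "GEP70": CoxRiskModel(covariates=("gep70_high",)),
        "IFM15": CoxRiskModel(covariates=("ifm15_high",)),
        "Reference": KaplanMeierReference(),
    }


def run_evaluate(cohort_dir, out_dir, seed: int, endpoint: str = "os",
                 horizon: float = 73.0, subsample_size: int | None = None,
                 n_replicates: int = 30) -> dict:
    out_dir = Path(out_dir)
    model_df = evaluation_frame(cohort_dir, out_dir, endpoint=endpoint)
    n = len(model_df)
    if subsample_size is None:
        subsample_size = 301 if n > 301 else max(2, (2 * n) // 3)
    cv = cv_prediction_error(standard_models(), model_df,
                             horizon=horizon, subsample_size=subsample_size,
                             n_replicates=n_replicates,
                             seed=child_seed(seed, 1))
    per_rep = cv.per_replicate_ibs
    p_values = {}
    for name in per_rep.columns:
        if name == "HM-metascore":
            continue
        p_values[f"HM-metascore_vs_{name}"] = compare_prediction_error(
            per_rep["HM-metascore"], per_rep[name], alternative="less")
    payload = {
        "endpoint": endpoint,
        "n_complete_cases": n,
        "ibs": {m: cv.curves[m].ibs for m in cv.curves},
        "p_values": p_values,
        "curves": {m: {"times": cv.curves[m].times.tolist(),
                       "brier": cv.curves[m].brier.tolist()}
                   for m in cv.curves},
        "metadata": cv.metadata,
        "n_dropped_replicates": cv.n_dropped,
    }
    (out_dir / "evaluation.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return payload


def run_reports(cohort_dir, out_dir, seed: int | None = None,
                metascore_config: MetascoreConfig | None = None) -> list[Path]:
    out_dir = Path(out_dir)
    metascore_config = metascore_config or MetascoreConfig()
    qc = pd.read_csv(out_dir / "qc.csv", index_col="sample_id")
    identity = pd.read_csv(out_dir / "identity.csv", index_col="sample_id")
    scores = pd.read_csv(out_dir / "scores.csv", index_col="sample_id")
    t414 = pd.read_csv(out_dir / "t414.csv", index_col="sample_id")
    staging = pd.read_csv(out_dir / "staging.csv", index_col="sample_id")
    meta = pd.read_csv(out_dir / "metascore.csv", index_col="sample_id")
    targets = pd.read_csv(out_dir / "targets.csv", index_col="sample_id")

    reports_dir = out_dir / "reports"
    reports_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for sid in qc.index:
        qrow = qc.loc[sid]
        metrics = {m: (None if pd.isna(qrow[m]) else float(qrow[m]))
                   for m in qc_mod.METRICS}
        statuses = {m: str(qrow[f"{m}_status"]) for m in qc_mod.METRICS}
        mismatched = []
        predicted, recorded, posteriors = {}, {}, {}
        for axis in IDENTITY_AXES:
            pred = str(identity.loc[sid, f"{axis}_predicted"])
            rec = identity.loc[sid, f"{axis}_recorded"]
            rec = None if pd.isna(rec) else str(rec)
            predicted[axis] = pred
            recorded[axis] = rec
            posteriors[axis] = {
                pred: float(identity.loc[sid, f"{axis}_posterior"])}
            if rec is not None and rec != pred:
                mismatched.append(axis)
        bundle = {
            "sample_id": str(sid),
            "identity": {
                "verdict": "mismatch" if mismatched else "confirmed",
                "predicted": predicted, "recorded": recorded,
                "posteriors": posteriors, "mismatched_axes": mismatched,
            },
            "qc": {
                "n_minor_warnings": int(qrow["n_minor_warnings"]),
                "excluded": bool(qrow["excluded"]),
                "metrics": metrics, "statuses": statuses,
            },
            "provenance": {
                "seed": seed,
                "config_hashes": {
                    "metascore": config_hash(metascore_config.to_yaml())},
                "versions": {"metascore": metascore_config.version,
                             **{k: s.version for k, s in SIGNATURES.items()}},
            },
        }
        if not bool(qrow["excluded"]):
            srow = scores.loc[sid]
            mrow = meta.loc[sid]
            trow = targets.loc[sid]
            strow = staging.loc[sid]
            bundle["risk"] = {
                "scores": {k: float(srow[f"{k}_score"]) for k in SIGNATURES},
                "strata": {k: str(srow[f"{k}_stratum"]) for k in SIGNATURES},
                "thresholds": {},
                "t4_14_call": str(t414.loc[sid, "call"]),
                "t4_14_posterior": float(t414.loc[sid, "posterior_positive"]),
                "iss": None if pd.isna(strow["iss"]) else str(strow["iss"]),
                "riss": None if pd.isna(strow["riss"]) else str(strow["riss"]),
                "riss_note": ("" if pd.isna(strow["riss_note"])
                              else str(strow["riss_note"])),
                "metascore_total": float(mrow["total"]),
                "metascore_stratum": str(mrow["stratum"]),
                "metascore_breakdown": {
                    c[len("pts_"):]: float(mrow[c])
                    for c in meta.columns if c.startswith("pts_")},
                "metascore_missing": (
                    [] if pd.isna(mrow["missing_factors"])
                    or not str(mrow["missing_factors"])
                    else str(mrow["missing_factors"]).split(";")),
                "metascore_version": str(mrow["version"]),
            }
            bundle["targets"] = {
                "calls": {g: str(trow[g]) for g in TARGETS},
                "evidence": {g: float(trow[f"{g}_evidence"])
                             for g in TARGETS},
                "method": {g: "mixture" for g in TARGETS},
            }
        path = reports_dir / f"{sid}.json"
        path.write_text(render_report(bundle, "json"))
        (reports_dir / f"{sid}.md").write_text(render_report(bundle, "markdown"))
        written.append(path)
    return written


def run_all(config: CohortConfig, base_dir, seed: int | None = None,
            n_replicates: int = 30) -> dict:
    """Simulate a cohort and chain every pipeline stage on it."""
    base_dir = Path(base_dir)
    if seed is not None:
        config = dataclasses.replace(config, seed=child_seed(seed, 0))
    else:
        seed = config.seed
    cohort_dir = base_dir / "cohort"
    out_dir = base_dir / "outputs"
    run_simulate(config, cohort_dir)
    run_qc(cohort_dir, out_dir)
    run_identity(cohort_dir, out_dir)
    run_scores(cohort_dir, out_dir)
    run_staging(cohort_dir, out_dir)
    run_metascore(cohort_dir, out_dir)
    evaluation = run_evaluate(cohort_dir, out_dir, seed=seed,
                              n_replicates=n_replicates)
    run_reports(cohort_dir, out_dir, seed=seed)
    return evaluation
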