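"""In-memory containers and on-disk formats for a profiled cohort.

A cohort directory holds three plain-text tables::

    expression.tsv   log2 expression, features as rows, first column ``feature``,
                     remaining columns one per sample
    features.tsv     feature annotations (``feature``, ``symbol``, ``role``)
    samples.csv      one row per sample: identity labels, clinical covariates,
                     cytogenetics flags and survival outcomes

Cytogenetics flags use the literal strings ``present`` / ``absent`` /
``unknown``; the unknown state is preserved through every round trip and is
never coerced to absent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CYTO_LESIONS = ("t_4_14", "t_14_16", "del17p13", "gain1q21")
CYTO_STATES = ("present", "absent", "unknown")


class CohortFormatError(ValueError):
    """A cohort table is malformed; the message names the offending part."""


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values (features x samples) with annotations.

    ``data`` is indexed by feature id with one column per sample id;
    ``annotations`` is indexed by feature id and carries at least ``symbol``
    and ``role`` columns (role tags: identity:*, spike:*, signature:*,
    target, noise).
    """

    data: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise CohortFormatError(f"duplicate feature id {dup!r}")
        if not self.data.index.equals(self.annotations.index):
            self.annotations = self.annotations.reindex(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    def to_frame(self) -> pd.DataFrame:
        """Samples x features orientation (sklearn convention)."""
        return self.data.T

    def features_with_role(self, role_prefix: str) -> list[str]:
        role = self.annotations["role"].astype(str)
        return list(self.annotations.index[role.str.startswith(role_prefix)])


@dataclass
class SampleRecord:
    """Identity labels, clinical covariates and outcomes for one patient."""

    sample_id: str
    sex: str = "unknown"  # male | female
    igh_type: str = "none"  # IgA | IgG | IgD | none
    igl_type: str = "unknown"  # kappa | lambda
    b2m: float = float("nan")  # beta2-microglobulin, mg/L
    albumin: float = float("nan")  # g/dL
    ldh: float = float("nan")  # U/L
    ldh_uln: float = float("nan")  # lab upper limit of normal, U/L
    cytogenetics: dict = field(default_factory=dict)  # lesion -> state
    pfs_months: float = float("nan")
    pfs_event: int = 0
    os_months: float = float("nan")
    os_event: int = 0
    true_risk_factors: dict = field(default_factory=dict)  # generator truth

    def __post_init__(self) -> None:
        for lesion, state in self.cytogenetics.items():
            if state not in CYTO_STATES:
                raise CohortFormatError(
                    f"sample {self.sample_id}: cytogenetics[{lesion!r}] = "
                    f"{state!r}, expected one of {CYTO_STATES}"
                )
        for name in ("pfs_months", "os_months"):
            t = getattr(self, name)
            if np.isfinite(t) and t < 0:
                raise CohortFormatError(f"sample {self.sample_id}: {name} < 0")
        for name in ("pfs_event", "os_event"):
            if getattr(self, name) not in (0, 1):
                raise CohortFormatError(
                    f"sample {self.sample_id}: {name} must be 0 or 1"
                )


def records_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Flatten records into the samples.csv layout."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        cyto = d.pop("cytogenetics")
        truths = d.pop("true_risk_factors")
        for lesion in CYTO_LESIONS:
            d[f"cyto_{lesion}"] = cyto.get(lesion, "unknown")
        for k, v in sorted(truths.items()):
            d[f"true_{k}"] = v
        rows.append(d)
    return pd.DataFrame(rows).set_index("sample_id")


def frame_to_records(frame: pd.DataFrame) -> list[SampleRecord]:
    records = []
    for sample_id, row in frame.iterrows():
        cyto = {}
        truths = {}
        plain = {}
        for col, val in row.items():
            if col.startswith("cyto_"):
                cyto[col[len("cyto_"):]] = str(val)
            elif col.startswith("true_"):
                truths[col[len("true_"):]] = val
            else:
                plain[col] = val
        try:
            records.append(
                SampleRecord(
                    sample_id=str(sample_id),
                    cytogenetics=cyto,
                    true_risk_factors=truths,
                    **{
                        k: (int(v) if k.endswith("_event") else v)
                        for k, v in plain.items()
                    },
                )
            )
        except (TypeError, ValueError) as exc:
            raise CohortFormatError(
                f"samples table row {sample_id!r}: {exc}"
            ) from exc
    return records


def write_cohort(matrix: ExpressionMatrix, records: list[SampleRecord],
                 directory: str | Path) -> Path:
    """Serialise a cohort; ``read_cohort(write_cohort(...))`` is the identity."""
    if not records:
        raise CohortFormatError("refusing to write a cohort with no samples")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    expr = matrix.data.copy()
    expr.index.name = "feature"
    expr.to_csv(directory / "expression.tsv", sep="\t")
    ann = matrix.annotations.copy()
    ann.index.name = "feature"
    ann.to_csv(directory / "features.tsv", sep="\t")
    records_to_frame(records).to_csv(directory / "samples.csv")
    # survival also written standalone for downstream tools; samples.csv
    # remains the authoritative copy on read
    survival_frame(records).to_csv(directory / "survival.csv")
    return directory


def read_cohort(directory: str | Path) -> tuple[ExpressionMatrix, list[SampleRecord]]:
    directory = Path(directory)
    try:
        expr = pd.read_csv(directory / "expression.tsv", sep="\t",
                           index_col="feature", float_precision="round_trip")
    except (FileNotFoundError, ValueError, KeyError) as exc:
        raise CohortFormatError(f"expression.tsv in {directory}: {exc}") from exc
    try:
        ann = pd.read_csv(directory / "features.tsv", sep="\t",
                          index_col="feature")
    except (FileNotFoundError, ValueError, KeyError) as exc:
        raise CohortFormatError(f"features.tsv in {directory}: {exc}") from exc
    samples = pd.read_csv(directory / "samples.csv", index_col="sample_id",
                          float_precision="round_trip")
    records = frame_to_records(samples)
    return ExpressionMatrix(expr, ann), records


def survival_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Survival table (time_months/event per endpoint), one row per sample."""
    return pd.DataFrame(
        {
            "pfs_months": [r.pfs_months for r in records],
            "pfs_event": [r.pfs_event for r in records],
            "os_months": [r.os_months for r in records],
            "os_event": [r.os_event for r in records],
        },
        index=pd.Index([r.sample_id for r in records], name="sample_id"),
    )
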