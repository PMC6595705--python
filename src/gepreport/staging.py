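"""Conventional staging (ISS, revised ISS) and the additive risk metascore.

ISS uses beta2-microglobulin (mg/L) and serum albumin (g/dL):

    stage I   iff b2m < 3.5 and albumin >= 3.5
    stage III iff b2m >= 5.5
    stage II  otherwise

rISS adds high-risk cytogenetics (del17p13, t(4;14), t(14;16) by iFISH) and
LDH relative to the lab's upper limit of normal:

    rISS I   iff ISS I, no high-risk aberration, LDH <= upper limit
    rISS III iff ISS III and (high-risk aberration or LDH > upper limit)
    rISS II  otherwise

The metascore adds configurable points per prognostic factor level (ISS
stage, adverse cytogenetics, expression-based risk strata, target-gene
calls) and assigns low / medium / high by two cut points. The shipped
default weight table is this package's own calibration; the published
weighting of the original clinical metascore is external to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

HIGH_RISK_LESIONS = ("del17p13", "t_4_14", "t_14_16")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def compute_iss(b2m: float, albumin: float) -> str | None:
    """ISS stage from beta2-microglobulin (mg/L) and albumin (g/dL).

    Returns ``None`` when either input is missing (unknown propagates).
    """
    if _missing(b2m) or _missing(albumin):
        return None
    if b2m <= 0 or albumin <= 0:
        raise ValueError("b2m and albumin must be positive")
    if b2m >= 5.5:
        return "III"
    if b2m < 3.5 and albumin >= 3.5:
        return "I"
    return "II"


@dataclass
class RissResult:
    stage: str | None
    note: str = ""


def _riss_given(iss: str, any_high_risk: bool, ldh_high: bool) -> str:
    if iss == "I" and not any_high_risk and not ldh_high:
        return "I"
    if iss == "III" and (any_high_risk or ldh_high):
        return "III"
    return "II"


def compute_riss(iss: str | None, cytogenetics: dict,
                 ldh: float, ldh_uln: float) -> RissResult:
    """Revised ISS from ISS stage, iFISH flags and LDH.

    Unknown cytogenetics are resolved both ways (as present and as absent);
    if the resulting stage differs, the stage is unknown with an
    explanation.
    """
    if iss is None:
        return RissResult(None, "ISS stage unknown")
    if iss not in ("I", "II", "III"):
        raise ValueError(f"invalid ISS stage {iss!r}")
    if _missing(ldh) or _missing(ldh_uln):
        return RissResult(None, "LDH or its upper limit of normal missing")
    states = [cytogenetics.get(lesion, "unknown")
              for lesion in HIGH_RISK_LESIONS]
    ldh_high = ldh > ldh_uln
    if "unknown" in states:
        known_present = any(s == "present" for s in states)
        lo = _riss_given(iss, known_present, ldh_high)   # unknowns absent
        hi = _riss_given(iss, True, ldh_high)            # unknowns present
        if lo != hi:
            unknown = [l for l, s in zip(HIGH_RISK_LESIONS, states)
                       if s == "unknown"]
            return RissResult(
                None, f"stage depends on unknown cytogenetics {unknown}: "
                      f"{lo} if absent, {hi} if present")
        return RissResult(lo, "unknown cytogenetics do not change the stage")
    return RissResult(_riss_given(iss, "present" in states, ldh_high), "")


# -- metascore -------------------------------------------------------------

class MetascoreConfigError(ValueError):
    pass


class MissingFactorError(KeyError):
    pass


def _default_weights() -> dict:
    return {
        "iss": {"I": 0.0, "II": 1.0, "III": 2.0},
        "del17p13": {"present": 1.0, "absent": 0.0},
        "t_4_14": {"present": 1.0, "absent": 0.0,
                   "positive": 1.0, "negative": 0.0},
        "gep70": {"high": 1.0, "low": 0.0},
        "ifm15": {"high": 1.0, "low": 0.0},
        "gpi": {"GPI_high": 1.0, "GPI_medium": 0.0, "GPI_low": 0.0},
        "aurka": {"expressed": 0.5, "absent": 0.0},
        "igf1r": {"expressed": 0.5, "absent": 0.0},
    }


@dataclass
class MetascoreConfig:
    """Additive weight table with low/medium/high cut points.

    ``low_max``/``high_min``: total <= low_max -> low, total >= high_min ->
    high, otherwise medium. Missing factors contribute ``neutral_value``
    (and are listed) unless ``strict`` is set, in which case they raise.
    """

    weights: dict = field(default_factory=_default_weights)
    low_max: float = 0.5
    high_min: float = 4.0
    neutral_value: float = 0.0
    strict: bool = False
    version: str = "hm-like-1.0"

    def validate(self) -> None:
        if not self.version:
            raise MetascoreConfigError("MetascoreConfig requires a version tag")
        if not self.low_max < self.high_min:
            raise MetascoreConfigError("low_max must be < high_min")
        for factor, table in self.weights.items():
            for level, w in table.items():
                if not np.isfinite(w):
                    raise MetascoreConfigError(
                        f"weight for {factor}={level} is not finite")

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "version": self.version,
            "weights": self.weights,
            "low_max": self.low_max,
            "high_min": self.high_min,
            "neutral_value": self.neutral_value,
            "strict": self.strict,
        }, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "MetascoreConfig":
        d = yaml.safe_load(text)
        if "version" not in d:
            raise MetascoreConfigError("metascore YAML lacks a version tag")
        cfg = cls(weights=d["weights"], low_max=float(d["low_max"]),
                  high_min=float(d["high_min"]),
                  neutral_value=float(d.get("neutral_value", 0.0)),
                  strict=bool(d.get("strict", False)),
                  version=str(d["version"]))
        cfg.validate()
        return cfg


@dataclass
class MetascoreResult:
    sample_id: str
    total: float
    stratum: str  # low | medium | high
    contributions: dict  # factor -> points
    missing_factors: list
    version: str


def compute_metascore(factors: dict, config: MetascoreConfig | None = None,
                      sample_id: str = "") -> MetascoreResult:
    """Sum per-factor points and assign the low/medium/high stratum.

    ``factors`` maps factor name -> level string (e.g. ``{"iss": "II",
    "gep70": "high"}``). Levels missing from the weight table raise a
    configuration error; absent or unknown factors contribute the neutral
    value and are listed (or raise in strict mode).
    """
    config = config or MetascoreConfig()
    config.validate()
    contributions = {}
    missing = []
    for factor, table in config.weights.items():
        level = factors.get(factor)
        if level is None or _missing(level) or level == "unknown":
            if config.strict:
                raise MissingFactorError(
                    f"factor {factor!r} missing in strict mode")
            contributions[factor] = config.neutral_value
            missing.append(factor)
            continue
        if level not in table:
            raise MetascoreConfigError(
                f"factor {factor!r} level {level!r} not in weight table "
                f"(known: {sorted(table)})")
        contributions[factor] = float(table[level])
    total = float(sum(contributions.values()))
    if total <= config.low_max:
        stratum = "low"
    elif total >= config.high_min:
        stratum = "high"
    else:
        stratum = "medium"
    return MetascoreResult(sample_id=sample_id, total=total, stratum=stratum,
                           contributions=contributions,
                           missing_factors=missing, version=config.version)
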