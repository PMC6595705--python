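"""Synthetic trial-cohort generator.

Emulates the statistical structure a prospective myeloma expression-report
pipeline consumes: class-separable identity markers (sex, IgH, IgL isotypes),
translocation spike genes, bimodal target-gene expression, a continuous
proliferation axis, high-risk signature genes, clinical covariates consistent
with ISS staging, and progression-free/overall survival drawn from a Weibull
proportional-hazards model with independent exponential right censoring.

All effect sizes are log2 expression shifts. For a fixed seed the generator
is deterministic (single ``numpy.random.default_rng`` stream).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CYTO_LESIONS, ExpressionMatrix, SampleRecord


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


def _default_prevalence() -> dict:
    # Binary risk/target factors. Translocation and target fractions follow
    # the prospective trial cohort this pipeline models; del17p13 and the
    # remaining lesions use typical newly-diagnosed myeloma frequencies.
    return {
        "t_4_14": 0.116,
        "t_14_16": 0.035,
        "del17p13": 0.13,
        "gain1q21": 0.36,
        "aurka_expressed": 0.432,
        "igf1r_expressed": 0.331,
        "fgfr3_expressed": 0.11,
        "gep70_high": 0.248,
        "ifm15_high": 0.232,
    }


def _default_log_hr(scale: float = 1.0) -> dict:
    return {k: v * scale for k, v in {
        "del17p13": 0.6,
        "t_4_14": 0.5,
        "t_14_16": 0.4,
        "gain1q21": 0.25,
        "gep70_high": 0.7,
        "ifm15_high": 0.5,
        "gpi_high": 0.6,
        "aurka_expressed": 0.3,
        "igf1r_expressed": 0.3,
        "iss_ii": 0.3,
        "iss_iii": 0.6,
    }.items()}


@dataclass
class HazardModel:
    """Weibull baseline with log-linear covariate effects (PH form).

    ``scale`` is the months at which the baseline cumulative hazard reaches 1
    for a cohort-average subject: the linear predictor is centred at its
    configured expectation before sampling, so ``scale``/``shape`` set the
    cohort-typical survival scale rather than that of an all-factors-absent
    subject.
    """

    shape: float = 1.2
    scale: float = 55.0
    log_hr: dict = field(default_factory=_default_log_hr)


@dataclass
class CohortConfig:
    n_samples: int = 456
    n_noise_features: int = 200
    prevalence: dict = field(default_factory=_default_prevalence)
    sex_frequencies: dict = field(
        default_factory=lambda: {"male": 0.59, "female": 0.41})
    igh_frequencies: dict = field(
        default_factory=lambda: {"IgA": 0.20, "IgG": 0.59, "IgD": 0.01,
                                 "none": 0.20})
    igl_frequencies: dict = field(
        default_factory=lambda: {"kappa": 0.675, "lambda": 0.325})
    iss_frequencies: tuple = (0.36, 0.30, 0.34)
    gpi_fractions: tuple = (0.502, 0.419, 0.079)  # low, medium, high
    marker_effect: float = 3.0
    spike_effect: float = 3.0
    target_effect: float = 3.0
    signature_effect: float = 2.0
    proliferation_loading: float = 1.2
    y_dropout: float = 0.05  # male samples losing Y-marker signal
    noise_sd: float = 0.6
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    ldh_uln: float = 250.0
    ldh_elevated_fraction: float = 0.15
    cyto_unknown_rate: float = 0.02
    hazards: dict = field(default_factory=lambda: {
        "pfs": HazardModel(shape=1.2, scale=55.0,
                           log_hr=_default_log_hr(1.0)),
        "os": HazardModel(shape=1.1, scale=140.0,
                          log_hr=_default_log_hr(1.1)),
    })
    censoring_rate: dict = field(
        default_factory=lambda: {"pfs": 0.25, "os": 0.45})
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if self.n_noise_features < 0:
            raise ConfigError("n_noise_features must be >= 0")
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd must be > 0")
        for name, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"prevalence[{name!r}] not in [0, 1]")
        for axis in ("sex_frequencies", "igh_frequencies", "igl_frequencies"):
            freqs = getattr(self, axis)
            if any(f < 0 for f in freqs.values()):
                raise ConfigError(f"{axis} has a negative frequency")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{axis} frequencies do not sum to 1")
        for name, val in (("iss_frequencies", self.iss_frequencies),
                          ("gpi_fractions", self.gpi_fractions)):
            if len(val) != 3 or abs(sum(val) - 1.0) > 1e-9 or min(val) < 0:
                raise ConfigError(f"{name} must be 3 nonnegative values summing to 1")
        for name in ("y_dropout", "cyto_unknown_rate", "ldh_elevated_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} not in [0, 1]")
        for ep, rate in self.censoring_rate.items():
            if not 0.0 <= rate < 1.0:
                raise ConfigError(f"censoring_rate[{ep!r}] not in [0, 1)")
        for ep, hz in self.hazards.items():
            if hz.shape <= 0 or hz.scale <= 0:
                raise ConfigError(f"hazards[{ep!r}] shape/scale must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "hazards" in d:
            d["hazards"] = {
                ep: hz if isinstance(hz, HazardModel) else HazardModel(**hz)
                for ep, hz in d["hazards"].items()
            }
        for key in ("iss_frequencies", "gpi_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# Synthetic feature panel: (feature id, role); identity markers are shifted
# up by marker_effect in their class, spike genes in t(4;14)-positives,
# signature genes by their latent risk factor, targets by expression state.
_SEX_MALE = [f"SEXM{i}" for i in range(1, 5)]      # Y-linked surrogates
_SEX_FEMALE = ["SEXF1", "SEXF2"]                   # XIST-like surrogates
_IGH = {"IgA": ["IGHA_M1", "IGHA_M2"], "IgG": ["IGHG_M1", "IGHG_M2"],
        "IgD": ["IGHD_M1", "IGHD_M2"]}
_IGL = {"kappa": ["IGKC_M1", "IGKC_M2"], "lambda": ["IGLC_M1", "IGLC_M2"]}
_SPIKE_T414 = [f"SPIKE_T414_{i}" for i in range(1, 4)]
GEP70_UP = [f"RS70_UP{i}" for i in range(1, 6)]
GEP70_DOWN = [f"RS70_DN{i}" for i in range(1, 4)]
IFM15_UP = [f"RS15_UP{i}" for i in range(1, 6)]
PROLIFERATION_GENES = [f"PROL{i}" for i in range(1, 11)]
TARGET_GENES = ("AURKA", "IGF1R", "FGFR3")


def _feature_table(config: CohortConfig) -> pd.DataFrame:
    rows = []
    for f in _SEX_MALE + _SEX_FEMALE:
        rows.append((f, "identity:sex"))
    for genes in _IGH.values():
        rows.extend((f, "identity:igh") for f in genes)
    for genes in _IGL.values():
        rows.extend((f, "identity:igl") for f in genes)
    rows.extend((f, "spike:t_4_14") for f in _SPIKE_T414)
    rows.extend((f, "signature:gep70") for f in GEP70_UP + GEP70_DOWN)
    rows.extend((f, "signature:ifm15") for f in IFM15_UP)
    rows.extend((f, "signature:gpi") for f in PROLIFERATION_GENES)
    rows.extend((f, "target") for f in TARGET_GENES)
    rows.extend((f"NOISE{i:04d}", "noise")
                for i in range(1, config.n_noise_features + 1))
    frame = pd.DataFrame(rows, columns=["feature", "role"])
    frame["symbol"] = frame["feature"]
    return frame.set_index("feature")


def _sample_categorical(rng, freqs: dict, n: int) -> np.ndarray:
    labels = list(freqs)
    return rng.choice(labels, size=n, p=[freqs[k] for k in labels])


def _solve_censoring_rate(event_times: np.ndarray, target: float) -> float:
    """Exponential rate lambda with E[fraction censored] = target.

    The expected censored fraction given the realised event times is
    mean(1 - exp(-lambda * T)); monotone in lambda, solved by bisection.
    """
    if target <= 0:
        return 0.0

    def frac(lam):
        return float(np.mean(1.0 - np.exp(-lam * event_times)))

    lo, hi = 1e-10, 1.0
    while frac(hi) < target:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - degenerate all-zero times
            return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _survival_endpoint(rng, hz: HazardModel, indicators: pd.DataFrame,
                       cens_rate: float) -> tuple[np.ndarray, np.ndarray]:
    eta = np.zeros(len(indicators))
    expected = 0.0
    for factor, beta in hz.log_hr.items():
        if factor not in indicators:
            raise ConfigError(f"hazard factor {factor!r} has no indicator")
        x = indicators[factor].to_numpy(float)
        eta += beta * x
        expected += beta * float(x.mean())
    eta -= expected  # centre at the cohort-average linear predictor
    u = rng.exponential(size=len(eta))
    t_event = hz.scale * (u / np.exp(eta)) ** (1.0 / hz.shape)
    if cens_rate <= 0:
        return t_event, np.ones(len(eta), dtype=int)
    lam = _solve_censoring_rate(t_event, cens_rate)
    c = rng.exponential(scale=1.0 / lam, size=len(eta))
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    return time, event


def _clinical_for_stage(rng, stage: int) -> tuple[float, float]:
    """(b2m mg/L, albumin g/dL) consistent with the given ISS stage (1-3)."""
    if stage == 1:
        return rng.uniform(1.2, 3.4), rng.uniform(3.5, 5.2)
    if stage == 3:
        return rng.uniform(5.5, 15.0), rng.uniform(2.2, 4.8)
    if rng.random() < 0.7:
        return rng.uniform(3.5, 5.4), rng.uniform(2.5, 5.2)
    return rng.uniform(1.2, 3.4), rng.uniform(2.2, 3.4)


def generate_cohort(config: CohortConfig) -> tuple[ExpressionMatrix, list[SampleRecord]]:
    """Draw a full synthetic cohort (expression matrix + sample records)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:05d}" for i in range(1, n + 1)]

    sex = _sample_categorical(rng, config.sex_frequencies, n)
    igh = _sample_categorical(rng, config.igh_frequencies, n)
    igl = _sample_categorical(rng, config.igl_frequencies, n)
    y_lost = (sex == "male") & (rng.random(n) < config.y_dropout)

    truth = {name: (rng.random(n) < p).astype(int)
             for name, p in config.prevalence.items()}

    # Proliferation axis: latent standard normal; GPI strata are fixed
    # quantile bands of the latent law so planted fractions are exact in
    # expectation.
    prolif = rng.normal(size=n)
    lo, med, hi = config.gpi_fractions
    cut_mh = stats.norm.ppf(1.0 - hi)          # medium/high boundary
    cut_lm = stats.norm.ppf(1.0 - hi - med)    # low/medium boundary
    gpi = np.where(prolif > cut_mh, "gpi_high",
                   np.where(prolif > cut_lm, "gpi_medium", "gpi_low"))
    truth["gpi_high"] = (gpi == "gpi_high").astype(int)

    iss = rng.choice([1, 2, 3], size=n, p=list(config.iss_frequencies))
    truth["iss_ii"] = (iss == 2).astype(int)
    truth["iss_iii"] = (iss == 3).astype(int)

    features = _feature_table(config)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=len(features))
    values = np.tile(baseline[:, None], (1, n))
    fidx = {f: i for i, f in enumerate(features.index)}

    def shift(genes, mask, effect):
        rows = [fidx[g] for g in genes]
        values[np.ix_(rows, np.flatnonzero(mask))] += effect

    shift(_SEX_MALE, (sex == "male") & ~y_lost, config.marker_effect)
    shift(_SEX_FEMALE, sex == "female", config.marker_effect)
    for cls, genes in _IGH.items():
        shift(genes, igh == cls, config.marker_effect)
    for cls, genes in _IGL.items():
        shift(genes, igl == cls, config.marker_effect)
    shift(_SPIKE_T414, truth["t_4_14"] == 1, config.spike_effect)
    shift(GEP70_UP, truth["gep70_high"] == 1, config.signature_effect)
    shift(GEP70_DOWN, truth["gep70_high"] == 1, -0.75 * config.signature_effect)
    shift(IFM15_UP, truth["ifm15_high"] == 1, config.signature_effect)
    prol_rows = [fidx[g] for g in PROLIFERATION_GENES]
    values[prol_rows, :] += config.proliferation_loading * prolif[None, :]
    for gene in TARGET_GENES:
        key = f"{gene.lower()}_expressed"
        shift([gene], truth[key] == 1, config.target_effect)

    values += rng.normal(0.0, config.noise_sd, size=values.shape)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=features.index, columns=sample_ids),
        features[["symbol", "role"]].copy(),
    )

    indicators = pd.DataFrame(truth, index=sample_ids)
    endpoint_data = {}
    for ep in ("pfs", "os"):
        endpoint_data[ep] = _survival_endpoint(
            rng, config.hazards[ep], indicators,
            config.censoring_rate.get(ep, 0.0))

    unknown = rng.random((n, len(CYTO_LESIONS))) < config.cyto_unknown_rate
    ldh_elev = rng.random(n) < config.ldh_elevated_fraction

    records = []
    for i, sid in enumerate(sample_ids):
        b2m, alb = _clinical_for_stage(rng, int(iss[i]))
        ldh = (rng.uniform(config.ldh_uln * 1.02, config.ldh_uln * 2.0)
               if ldh_elev[i]
               else rng.uniform(0.5 * config.ldh_uln, config.ldh_uln * 0.98))
        cyto = {}
        for j, lesion in enumerate(CYTO_LESIONS):
            if unknown[i, j]:
                cyto[lesion] = "unknown"
            else:
                cyto[lesion] = "present" if truth[lesion][i] else "absent"
        truths = {k: int(v[i]) for k, v in truth.items()}
        truths["gpi"] = str(gpi[i])
        truths["iss"] = int(iss[i])
        records.append(SampleRecord(
            sample_id=sid,
            sex=str(sex[i]),
            igh_type=str(igh[i]),
            igl_type=str(igl[i]),
            b2m=float(b2m),
            albumin=float(alb),
            ldh=float(ldh),
            ldh_uln=float(config.ldh_uln),
            cytogenetics=cyto,
            pfs_months=float(endpoint_data["pfs"][0][i]),
            pfs_event=int(endpoint_data["pfs"][1][i]),
            os_months=float(endpoint_data["os"][0][i]),
            os_event=int(endpoint_data["os"][1][i]),
            true_risk_factors=truths,
        ))
    return matrix, records
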