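"""Signature scoring, GPI strata, t(4;14) prediction, presence calls."""

import numpy as np
import pandas as pd
import pytest

from gepreport.cohort import ExpressionMatrix
from gepreport.signatures import (GEP70_LIKE, GPI_DEFAULT,
                                  GaussianPresenceCaller, SignatureDefinition,
                                  SignatureError, SignatureScorer,
                                  ThresholdSpec, call_presence, predict_t4_14,
                                  score_gpi, score_signature,
                                  signature_from_yaml, signature_to_yaml,
                                  train_t4_14_classifier)
from gepreport.simulate import CohortConfig, generate_cohort


def _matrix(values: dict, n: int) -> ExpressionMatrix:
    data = pd.DataFrame(values, index=[f"S{i}" for i in range(n)]).T
    ann = pd.DataFrame({"symbol": data.index, "role": "noise"},
                       index=data.index)
    ann.index.name = "feature"
    data.index.name = "feature"
    return ExpressionMatrix(data, ann)


def _sig(**kw):
    base = dict(name="toy", up_genes=("U1", "U2"), down_genes=("D1",),
                aggregation="mean-difference",
                thresholds=(ThresholdSpec("fixed", 1.0),))
    base.update(kw)
    return SignatureDefinition(**base)


def test_constant_up_down_gives_mean_difference():
    m = _matrix({"U1": [5.0] * 4, "U2": [5.0] * 4, "D1": [3.0] * 4}, 4)
    results = score_signature(m, _sig())
    assert all(r.score == pytest.approx(2.0) for r in results)
    assert all(r.stratum == "high" for r in results)


def test_constant_matrix_scores_zero():
    m = _matrix({"U1": [7.0] * 3, "U2": [7.0] * 3, "D1": [7.0] * 3}, 3)
    assert all(r.score == pytest.approx(0.0)
               for r in score_signature(m, _sig()))


def test_scores_match_brute_force_recomputation(rng):
    n, genes = 30, [f"G{i}" for i in range(20)]
    m = _matrix({g: rng.normal(7, 1, n) for g in genes}, n)
    sig = _sig(up_genes=tuple(genes[:6]), down_genes=tuple(genes[6:10]))
    results = score_signature(m, sig)
    for j, r in enumerate(results):
        col = m.data.iloc[:, j]
        expected = (np.mean([col[g] for g in genes[:6]])
                    - np.mean([col[g] for g in genes[6:10]]))
        assert r.score == pytest.approx(expected, abs=1e-12)


def test_missing_up_genes_error_missing_down_skipped(rng):
    m = _matrix({"U1": rng.normal(size=5), "D1": rng.normal(size=5)}, 5)
    with pytest.raises(SignatureError, match="no up-gene"):
        score_signature(m, _sig(up_genes=("NOPE",)))
    with pytest.warns(UserWarning, match="skipping"):
        results = score_signature(m, _sig(up_genes=("U1", "ALSO_MISSING")))
    assert len(results) == 5


def test_noise_features_do_not_change_scores(rng):
    n = 12
    cols = {"U1": rng.normal(size=n), "U2": rng.normal(size=n),
            "D1": rng.normal(size=n)}
    base = score_signature(_matrix(cols, n), _sig())
    noisy = score_signature(
        _matrix({**cols, **{f"N{i}": rng.normal(size=n) for i in range(30)}},
                n), _sig())
    np.testing.assert_allclose([r.score for r in base],
                               [r.score for r in noisy])


def test_strata_partition_every_sample(default_cohort):
    matrix, _ = default_cohort
    for sig in (GEP70_LIKE, GPI_DEFAULT):
        results = score_signature(matrix, sig)
        assert len(results) == len(matrix.samples)
        assert all(r.stratum in sig.strata for r in results)


def test_gpi_quantile_cuts_match_order_statistics(rng):
    """Cuts at the 49.8% / 92.1% quantiles of a continuous score yield
    n*(0.502, 0.419, 0.079) stratum counts up to integer rounding."""
    n = 1000
    m = _matrix({g: rng.normal(7, 1, n) for g in GPI_DEFAULT.up_genes}, n)
    results = score_gpi(m)
    counts = pd.Series([r.stratum for r in results]).value_counts()
    assert abs(counts["GPI_low"] - 0.498 * n) <= 1
    assert abs(counts["GPI_medium"] - (0.921 - 0.498) * n) <= 2
    assert abs(counts["GPI_high"] - (1 - 0.921) * n) <= 1


def test_gpi_monotone_raising_genes_never_lowers_stratum(rng):
    n = 50
    cols = {g: rng.normal(7, 1, n) for g in GPI_DEFAULT.up_genes}
    m = _matrix(cols, n)
    scorer = SignatureScorer(GPI_DEFAULT).fit(m.to_frame())
    order = {"GPI_low": 0, "GPI_medium": 1, "GPI_high": 2}
    frame = m.to_frame().copy()
    before = scorer.predict(frame)
    frame.iloc[0] += 2.0  # raise every proliferation gene of one sample
    after = scorer.predict(frame)
    assert order[after[0]] >= order[before[0]]
    np.testing.assert_array_equal(before[1:], after[1:])


def test_frozen_thresholds_reused_for_new_samples(rng):
    n = 200
    genes = list(GEP70_LIKE.up_genes) + list(GEP70_LIKE.down_genes)
    train = _matrix({g: rng.normal(7, 1, n) for g in genes}, n)
    scorer = SignatureScorer(GEP70_LIKE).fit(train.to_frame())
    frozen = scorer.thresholds_
    query = _matrix({g: rng.normal(9, 1, 10) for g in genes}, 10)
    results = scorer.score_results(query.to_frame())
    assert all(r.thresholds == frozen for r in results)


# -- t(4;14) ---------------------------------------------------------------

def test_t414_zero_noise_calls_equal_ground_truth(clean_cohort):
    matrix, records = clean_cohort
    truth = pd.Series({r.sample_id: ("positive" if
                                     r.true_risk_factors["t_4_14"]
                                     else "negative") for r in records})
    clf = train_t4_14_classifier(matrix, truth)
    calls, _ = predict_t4_14(clf, matrix)
    assert (calls["call"] == truth.loc[calls.index]).all()


def test_t414_planted_discrepancies_counted(clean_cohort):
    matrix, records = clean_cohort
    truth = pd.Series({r.sample_id: ("positive" if
                                     r.true_risk_factors["t_4_14"]
                                     else "negative") for r in records})
    ifish = truth.map({"positive": "present", "negative": "absent"})
    k = 4
    flipped = ifish.copy()
    flip = {"present": "absent", "absent": "present"}
    for sid in ifish.index[:k]:
        flipped[sid] = flip[ifish[sid]]
    clf = train_t4_14_classifier(matrix, truth)
    _, disc = predict_t4_14(clf, matrix, ifish=flipped)
    off = (disc.loc["positive", "absent"] + disc.loc["negative", "present"])
    assert off == k


def test_t414_posterior_threshold_half_equals_argmax(clean_cohort):
    matrix, records = clean_cohort
    truth = pd.Series({r.sample_id: ("positive" if
                                     r.true_risk_factors["t_4_14"]
                                     else "negative") for r in records})
    calls, _ = predict_t4_14(train_t4_14_classifier(matrix, truth), matrix)
    by_threshold = np.where(calls["posterior_positive"] > 0.5,
                            "positive", "negative")
    np.testing.assert_array_equal(calls["call"].to_numpy(), by_threshold)


# -- presence / absence ----------------------------------------------------

def test_fixed_threshold_all_below_is_zero_expressed(rng):
    m = _matrix({"AURKA": rng.uniform(4, 5, 20)}, 20)
    calls = call_presence(m, "AURKA", method="threshold",
                          params={"threshold": 6.0})
    assert all(c.call == "absent" for c in calls)


def test_mixture_recovers_planted_expressed_fraction():
    rng = np.random.default_rng(3)
    n, p = 5000, 0.432
    expressed = rng.random(n) < p
    values = rng.normal(6.0, 0.6, n) + 3.0 * expressed
    m = _matrix({"AURKA": values}, n)
    calls = call_presence(m, "AURKA")
    frac = np.mean([c.call == "expressed" for c in calls])
    se = np.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < 3 * se


def test_mixture_matches_midpoint_threshold_oracle():
    rng = np.random.default_rng(8)
    low = rng.normal(5.0, 0.3, 30)
    high = rng.normal(9.0, 0.3, 20)
    values = np.concatenate([low, high])
    m = _matrix({"G": values}, 50)
    calls = call_presence(m, "G")
    # brute-force oracle: best separating threshold between the two modes
    midpoint = (low.max() + high.min()) / 2
    expected = np.where(values > midpoint, "expressed", "absent")
    np.testing.assert_array_equal([c.call for c in calls], expected)


def test_mixture_label_stable_under_reordering_and_seed():
    rng = np.random.default_rng(12)
    values = np.concatenate([rng.normal(5, 0.4, 40), rng.normal(10, 0.4, 25)])
    base = GaussianPresenceCaller(random_state=0).fit(values).predict(values)
    perm = rng.permutation(len(values))
    shuffled = GaussianPresenceCaller(random_state=99).fit(
        values[perm]).predict(values[perm])
    np.testing.assert_array_equal(base[perm], shuffled)


def test_degenerate_mixture_falls_back_to_threshold(rng):
    values = rng.normal(7.0, 0.5, 100)  # single mode
    with pytest.warns(UserWarning, match="falling back"):
        caller = GaussianPresenceCaller().fit(values)
    assert caller.method_ == "threshold-fallback"
    calls = caller.predict(values)
    np.testing.assert_array_equal(
        calls, np.where(values > caller.threshold_, "expressed", "absent"))


def test_signature_yaml_roundtrip():
    text = signature_to_yaml(GEP70_LIKE)
    assert signature_from_yaml(text) == GEP70_LIKE
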