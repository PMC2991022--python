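"""Logistic prediction models: fitting, prediction, selection, validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import kneeoa as k

from conftest import make_cohort


def test_model_specs():
    assert k.MODEL_I.terms == ("n_risk_alleles",)
    assert k.MODEL_II.terms == ("n_risk_alleles", "gen", "age", "bmi")
    assert k.MODEL_III.terms == ("gen", "age", "bmi")


def test_fit_model_reproduces_published_per_allele_or(table5):
    cohort = k.cohort_from_distribution(table5)
    fit = k.fit_model(cohort, k.MODEL_I)
    assert round(np.exp(fit.coefficients["n_risk_alleles"]), 2) == 1.23


def test_fit_model_requires_both_groups(tiny_cohort):
    cases_only = tiny_cohort.subset(tiny_cohort.df["status"] == "case")
    with pytest.raises(k.DegenerateInputError):
        k.fit_model(cases_only, k.MODEL_I)


def test_fit_is_deterministic(synthetic_cohort):
    a = k.fit_model(synthetic_cohort, k.MODEL_II)
    b = k.fit_model(synthetic_cohort, k.MODEL_II)
    assert (a.coefficients == b.coefficients).all()
    assert a.log_likelihood <= 0


def test_null_labels_cover_zero():
    """On label-shuffled cohorts the slope CIs cover zero at roughly
    the nominal rate."""
    rng = np.random.default_rng(17)
    hits = total = 0
    base = k.generate_cohort(k.GeneratorParams(n_case=250, n_control=250, seed=1))
    for _ in range(60):
        df = base.df.copy()
        df["status"] = rng.permutation(df["status"].to_numpy())
        fit = k.fit_model(k.CohortTable(df), k.MODEL_II)
        ci = fit.wald_ci()
        for t in k.MODEL_II.terms:
            total += 1
            hits += ci.loc[t, "low"] <= 0 <= ci.loc[t, "high"]
    assert 0.88 <= hits / total <= 1.0


def test_predict_probability_zero_coefficients():
    assert k.predict_probability([0.0, 0.0], [3.0]) == pytest.approx(0.5)


def test_predict_probability_published_clinical_model():
    """Direct arithmetic on the published genetic+clinical formula at
    n=3, female, age 70, BMI 24."""
    beta = k.DEFAULT_COEFFICIENTS
    p = k.predict_probability(beta, [3, 2, 70, 24])
    eta = -8.395 + 0.200 * 3 + 0.302 * 2 + 0.045 * 70 + 0.162 * 24
    assert eta == pytest.approx(-0.153)
    assert p == pytest.approx(expit(-0.153), abs=1e-12)
    assert round(p, 3) == 0.462


def test_predict_probability_monotone_in_count():
    # genetic-only published formula (MLE sign for the intercept)
    probs = [k.predict_probability([-0.856, 0.205], [n]) for n in range(7)]
    assert all(a < b for a, b in zip(probs, probs[1:]))


def test_predicted_probabilities_consistent_with_fit(synthetic_cohort,
                                                     model2_fit):
    scores = k.scores_for(model2_fit, synthetic_cohort)
    frame = synthetic_cohort.with_columns(gen=synthetic_cohort.df["sex"])
    direct = k.predict_probability(
        model2_fit.coefficients, frame[list(k.MODEL_II.terms)])
    assert np.allclose(scores, direct)


# -- likelihood ratio --------------------------------------------------

def test_lrt_identical_specs(synthetic_cohort, model2_fit):
    stat, df, p = k.likelihood_ratio_compare(model2_fit, model2_fit)
    assert stat == 0.0 and p == 1.0


def test_lrt_closed_form_mapping(synthetic_cohort, model2_fit):
    reduced = k.fit_model(synthetic_cohort, k.MODEL_III)
    stat, df, p = k.likelihood_ratio_compare(reduced, model2_fit)
    assert stat == pytest.approx(
        2 * (model2_fit.log_likelihood - reduced.log_likelihood))
    assert df == 1
    assert p == pytest.approx(stats.chi2.sf(stat, 1))


def test_lrt_rejects_non_nested(synthetic_cohort, model2_fit):
    other = k.fit_model(synthetic_cohort, k.ModelSpec("x", ("height",)))
    with pytest.raises(k.ValidationError):
        k.likelihood_ratio_compare(other, model2_fit)


def test_lrt_power_genetic_term_at_study_size():
    """At the published effect size the genetic term is detected by the
    clinical-vs-full comparison in nearly every replicate."""
    hits = 0
    for seed in range(30):
        cohort = k.generate_cohort(k.GeneratorParams(seed=700 + seed))
        full = k.fit_model(cohort, k.MODEL_II)
        reduced = k.fit_model(cohort, k.MODEL_III)
        _, _, p = k.likelihood_ratio_compare(reduced, full)
        hits += p < 0.05
    assert hits >= 27


def test_lrt_invariant_to_covariate_rescaling(synthetic_cohort):
    df = synthetic_cohort.df.copy()
    df["age"] = df["age"] / 10.0
    rescaled = k.CohortTable(df)
    a = k.likelihood_ratio_compare(
        k.fit_model(synthetic_cohort, k.MODEL_III),
        k.fit_model(synthetic_cohort, k.MODEL_II))
    b = k.likelihood_ratio_compare(
        k.fit_model(rescaled, k.MODEL_III), k.fit_model(rescaled, k.MODEL_II))
    assert a[0] == pytest.approx(b[0], rel=1e-6)


# -- stepwise ----------------------------------------------------------

def _with_noise_columns(cohort, rng, names):
    df = cohort.df.copy()
    for name in names:
        df[name] = rng.standard_normal(len(df))
    return k.CohortTable(df)


def test_stepwise_selects_true_term():
    rng = np.random.default_rng(5)
    hits = 0
    for seed in range(20):
        cohort = k.generate_cohort(k.GeneratorParams(
            n_case=1000, n_control=1000, seed=800 + seed,
            coefficients=(-9.0, 0.4, 0.0, 0.045, 0.162)))
        aug = _with_noise_columns(cohort, rng, ["z1", "z2", "z3", "z4"])
        spec = k.stepwise_select(aug, ["n_risk_alleles", "z1", "z2", "z3", "z4"])
        hits += "n_risk_alleles" in spec.terms
    assert hits >= 18


def test_stepwise_all_noise_selects_nothing_typically():
    rng = np.random.default_rng(6)
    counts = []
    for seed in range(30):
        cohort = k.generate_cohort(k.GeneratorParams(
            n_case=300, n_control=300, seed=900 + seed,
            coefficients=(0.0, 0.0, 0.0, 0.0, 0.0)))
        aug = _with_noise_columns(cohort, rng, ["z1", "z2", "z3"])
        spec = k.stepwise_select(aug, ["z1", "z2", "z3"])
        counts.append(len(spec.terms))
    assert np.median(counts) == 0


def test_stepwise_single_informative_candidate():
    cohort = k.generate_cohort(k.GeneratorParams(seed=12))
    spec = k.stepwise_select(cohort, ["age"])
    assert spec.terms == ("age",)


# -- validation splits -------------------------------------------------

def test_split_validation_identical_halves(table5):
    cohort = k.cohort_from_distribution(table5)
    df = pd.concat([cohort.df, cohort.df.assign(
        subject_id=cohort.df["subject_id"] + "b")], ignore_index=True)
    doubled = k.CohortTable(df)
    mask = np.zeros(len(doubled), dtype=bool)
    mask[len(cohort):] = True  # holdout is a copy of the training half
    auc_train, auc_hold = k.split_validation(doubled, mask, k.MODEL_I)
    assert auc_train == pytest.approx(auc_hold)


def test_split_validation_null_labels():
    rng = np.random.default_rng(8)
    n = 4000
    cohort = make_cohort(rng.integers(0, 7, n), rng.integers(0, 2, n),
                         sex=rng.integers(1, 3, n),
                         age=rng.uniform(50, 90, n), bmi=rng.uniform(18, 35, n))
    mask = rng.random(n) < 0.33
    auc_train, auc_hold = k.split_validation(cohort, mask, k.MODEL_II)
    assert abs(auc_train - 0.5) < 0.05
    assert abs(auc_hold - 0.5) < 0.07


def test_split_validation_generalizes_on_model_data():
    gaps = []
    for seed in range(10):
        cohort = k.generate_cohort(k.GeneratorParams(seed=950 + seed))
        rng = np.random.default_rng(seed)
        mask = rng.random(len(cohort)) < 1 / 3
        auc_train, auc_hold = k.split_validation(cohort, mask, k.MODEL_II)
        gaps.append(auc_hold - auc_train)
    assert abs(np.mean(gaps)) < 0.05


def test_split_validation_single_class_split(tiny_cohort):
    mask = (tiny_cohort.df["status"] == "case").to_numpy()
    with pytest.raises(k.DegenerateInputError):
        k.split_validation(tiny_cohort, mask, k.MODEL_I)


def test_cross_validate_ceiling_floor_and_optimism():
    rng = np.random.default_rng(10)
    n = 600
    labels = rng.integers(0, 2, n)
    # near-perfect separation (a few flipped labels keep the fold fits
    # identified) -> AUC at the ceiling
    sep_scores = np.where(labels == 1, 6, 0)
    sep_labels = labels.copy()
    sep_labels[:12] = 1 - sep_labels[:12]
    sep = make_cohort(sep_scores, sep_labels)
    assert k.cross_validate(sep, k.MODEL_I, k=5, seed=0) > 0.9

    null = make_cohort(rng.integers(0, 7, n), labels,
                       age=rng.uniform(50, 90, n))
    assert abs(k.cross_validate(null, k.MODEL_I, k=5, seed=0) - 0.5) < 0.05

    diffs = []
    for seed in range(5):
        cohort = k.generate_cohort(k.GeneratorParams(seed=980 + seed))
        fit = k.fit_model(cohort, k.MODEL_II)
        in_sample = k.auc(k.scores_for(fit, cohort), cohort.is_case)
        diffs.append(k.cross_validate(cohort, k.MODEL_II, k=10, seed=seed)
                     - in_sample)
    assert np.mean(diffs) < 0.0  # out-of-fold AUC below apparent AUC
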