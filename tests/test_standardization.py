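"""Matched control resampling and liability-scale variance shares."""

import numpy as np
import pandas as pd
import pytest

import kneeoa as k
from kneeoa.standardization import _largest_remainder, sample_matched_controls

from conftest import make_cohort


def young_reference_table():
    """A reference population younger than the synthetic controls."""
    return k.DemographicTable(pd.DataFrame({
        "sex": [1, 2, 1, 2],
        "age_lo": [60, 60, 70, 70],
        "age_hi": [70, 70, 78, 78],
        "proportion": [0.20, 0.55, 0.05, 0.20]}))


def full_config(replicates=50, seed=4):
    return k.ResampleConfig(match_mode="full_age_distribution",
                            demographic=young_reference_table(),
                            replicates=replicates, seed=seed)


# -- quota sampling ----------------------------------------------------

def test_largest_remainder_quotas():
    w = np.array([0.107, 0.4, 0.493])
    q = _largest_remainder(w, 291)
    assert q.sum() == 291
    assert (np.abs(q - w * 291) < 1.0).all()


def test_single_stratum_reduces_to_simple_sampling(synthetic_cohort):
    demo = k.DemographicTable(pd.DataFrame({
        "sex": [2], "age_lo": [60], "age_hi": [95], "proportion": [1.0]}))
    cfg = k.ResampleConfig(match_mode="full_age_distribution",
                           demographic=demo, replicates=1, seed=0)
    idx = sample_matched_controls(synthetic_cohort, cfg,
                                  np.random.default_rng(0))
    total = cfg.n_control_male + cfg.n_control_female
    assert len(idx) == total
    sub = synthetic_cohort.df.iloc[idx]
    assert (sub["status"] == "control").all()
    assert (sub["sex"] == 2).all() and (sub["age"] >= 60).all()


def test_full_mode_composition_tracks_reference(synthetic_cohort):
    cfg = full_config()
    idx = sample_matched_controls(synthetic_cohort, cfg,
                                  np.random.default_rng(1))
    sub = synthetic_cohort.df.iloc[idx]
    demo = cfg.demographic
    total = len(idx)
    strat = demo.assign_stratum(sub["sex"].to_numpy(), sub["age"].to_numpy())
    realized = np.bincount(strat, minlength=len(demo.strata)) / total
    target = demo.strata["proportion"].to_numpy()
    assert np.abs(realized - target).max() <= 1.0 / total + 1e-12


def test_sampling_without_replacement(synthetic_cohort):
    idx = sample_matched_controls(synthetic_cohort, full_config(),
                                  np.random.default_rng(2))
    assert len(np.unique(idx)) == len(idx)


def test_request_exceeding_pool_names_stratum(synthetic_cohort):
    cfg = k.ResampleConfig(n_control_male=5000, n_control_female=100,
                           match_mode="sex_ratio_only", replicates=1)
    with pytest.raises(k.SamplingError, match="sex 1"):
        sample_matched_controls(synthetic_cohort, cfg,
                                np.random.default_rng(0))


# -- variance decomposition --------------------------------------------

def _manual_fit(terms, coefficients):
    names = ["const", *terms]
    return k.LogisticFit(
        spec=k.ModelSpec("manual", tuple(terms)),
        coefficients=pd.Series(coefficients, index=names),
        covariance=pd.DataFrame(np.eye(len(names)), index=names, columns=names),
        log_likelihood=-1.0, n_obs=4, converged=True)


def test_variance_decomposition_arithmetic_oracle():
    """var(G)=1, var(E)=3, cov=0 by construction -> genetic share 0.25."""
    n = np.array([1, 3, 1, 3])               # var 1 with beta_n = 1
    age = np.array([1, 1, 1 + 2 * np.sqrt(3), 1 + 2 * np.sqrt(3)])  # var 3
    cohort = make_cohort(n, [1, 0, 1, 0], age=age)
    fit = _manual_fit(("n_risk_alleles", "age"), [0.0, 1.0, 1.0])
    vs = k.variance_decomposition(fit, cohort)
    assert vs.var_genetic == pytest.approx(1.0)
    assert vs.var_clinical == pytest.approx(3.0)
    assert vs.covariance == pytest.approx(0.0, abs=1e-12)
    assert vs.genetic_share == pytest.approx(0.25)


def test_variance_decomposition_share_extremes():
    rng = np.random.default_rng(3)
    cohort = make_cohort(rng.integers(0, 7, 50), rng.integers(0, 2, 50),
                         age=rng.uniform(60, 90, 50))
    no_gene = _manual_fit(("n_risk_alleles", "age"), [0.0, 0.0, 0.05])
    assert k.variance_decomposition(no_gene, cohort).genetic_share == 0.0
    only_gene = _manual_fit(("n_risk_alleles", "age"), [0.0, 0.2, 0.0])
    assert k.variance_decomposition(only_gene, cohort).genetic_share == 1.0


def test_variance_decomposition_needs_both_components(synthetic_cohort):
    fit = k.fit_model(synthetic_cohort, k.MODEL_I)
    with pytest.raises(k.ValidationError):
        k.variance_decomposition(fit, synthetic_cohort)


def test_variance_components_add_up(synthetic_cohort, model2_fit):
    vs = k.variance_decomposition(model2_fit, synthetic_cohort)
    assert vs.var_total == pytest.approx(
        vs.var_genetic + vs.var_clinical + 2 * vs.covariance)
    assert 0.0 <= vs.genetic_share <= 1.0


# -- the resampling simulation ----------------------------------------

def test_simulation_reproducible_and_bounded(synthetic_cohort):
    a = k.adjusted_auc_simulation(synthetic_cohort, k.MODEL_II, full_config())
    b = k.adjusted_auc_simulation(synthetic_cohort, k.MODEL_II, full_config())
    assert np.array_equal(a.aucs, b.aucs)
    assert ((a.aucs >= 0) & (a.aucs <= 1)).all()
    assert a.aucs.min() <= a.mean_auc <= a.aucs.max()
    assert a.n_failed == 0


def test_single_replicate_matches_hand_trace(synthetic_cohort):
    cfg = full_config(replicates=1, seed=9)
    summary = k.adjusted_auc_simulation(synthetic_cohort, k.MODEL_II, cfg)
    # re-derive the one replicate with the same spawned stream
    child = np.random.SeedSequence([9, 101]).spawn(1)[0]
    rng = np.random.default_rng(child)
    ctrl_idx = sample_matched_controls(synthetic_cohort, cfg, rng)
    df = synthetic_cohort.df
    pool = np.flatnonzero(((df["status"] == "case")
                           & (df["age"] >= cfg.min_age)).to_numpy())
    case_idx = rng.choice(pool, size=cfg.n_case, replace=False)
    sub = k.CohortTable(df.iloc[np.concatenate([case_idx, ctrl_idx])])
    fit = k.fit_model(sub, k.MODEL_II)
    expected = k.auc(k.scores_for(fit, sub), sub.is_case)
    assert summary.aucs[0] == pytest.approx(expected, abs=1e-15)


def test_null_cohort_auc_near_half():
    cohort = k.generate_cohort(k.GeneratorParams(
        n_case=800, n_control=1200, seed=21,
        coefficients=(0.0, 0.0, 0.0, 0.0, 0.0)))
    cfg = k.ResampleConfig(match_mode="sex_ratio_only", n_control_male=80,
                           n_control_female=200, n_case=250,
                           replicates=60, seed=3)
    summary = k.adjusted_auc_simulation(cohort, k.MODEL_II, cfg)
    # in-replicate refits overfit slightly, so allow a small optimism margin
    assert abs(summary.mean_auc - 0.5) < 0.06


def test_age_standardization_shifts_auc(synthetic_cohort, model2_fit):
    """Cases run ~3 years older than controls under the default
    generator; matching controls to a younger reference population
    widens the age gap and moves the AUC by well over 0.01."""
    base_auc = k.auc(k.scores_for(model2_fit, synthetic_cohort),
                     synthetic_cohort.is_case)
    summary = k.adjusted_auc_simulation(synthetic_cohort, k.MODEL_II,
                                        full_config())
    assert abs(summary.mean_auc - base_auc) > 0.01


def test_sex_stratified_share_exceeds_mixed_on_average():
    """Single-sex refits drop the sex term, removing its clinical
    variance, so the genetic share rises on average — the direction
    reported for sex-stratified analyses.  A strong sex effect and
    balanced sexes make the mechanism dominate refit noise."""
    spec = k.ModelSpec("no_sex", ("n_risk_alleles", "age", "bmi"))
    mixed_shares, strat_shares = [], []
    for seed in range(6):
        cohort = k.generate_cohort(k.GeneratorParams(
            seed=2500 + seed, sex_female_fraction=0.5,
            coefficients=(-9.0, 0.2, 1.0, 0.045, 0.162)))
        fit = k.fit_model(cohort, k.MODEL_II)
        mixed_shares.append(
            k.variance_decomposition(fit, cohort).genetic_share)
        for sex in (1, 2):
            sub = cohort.subset(cohort.df["sex"] == sex)
            sub_fit = k.fit_model(sub, spec)
            strat_shares.append(
                k.variance_decomposition(sub_fit, sub).genetic_share)
    assert np.mean(strat_shares) > np.mean(mixed_shares)
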