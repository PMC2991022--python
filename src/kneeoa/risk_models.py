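"""Logistic prediction models for knee OA.

Three named model specifications are used throughout:

* MODEL I  — genetic only: case status ~ risk-allele count ``n``;
* MODEL II — genetic + clinical: ``n`` + sex code ``gen`` + age + BMI;
* MODEL III — clinical only: ``gen`` + age + BMI.

All fits are plain maximum-likelihood logistic regressions (no
regularization).  Fitted intercepts absorb the case-control sampling
fractions and are never interpreted as prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortTable
from .evaluation import auc
from .exceptions import (ConvergenceError, DegenerateInputError,
                         ValidationError)

#: model terms resolvable on a cohort frame
KNOWN_TERMS = ("n_risk_alleles", "gen", "age", "bmi", "height", "weight",
               "dosage_aspn", "dosage_gdf5", "dosage_dvwa")


@dataclass(frozen=True)
class ModelSpec:
    """Named ordered term list; ``gen`` is the 1=male / 2=female code."""

    name: str
    terms: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise ValidationError("duplicate model terms")


MODEL_I = ModelSpec("MODEL_I", ("n_risk_alleles",))
MODEL_II = ModelSpec("MODEL_II", ("n_risk_alleles", "gen", "age", "bmi"))
MODEL_III = ModelSpec("MODEL_III", ("gen", "age", "bmi"))


@dataclass
class LogisticFit:
    """Maximum-likelihood fit of a ModelSpec on a cohort."""

    spec: ModelSpec
    coefficients: pd.Series        # index: const + terms, log-odds scale
    covariance: pd.DataFrame
    log_likelihood: float
    n_obs: int
    converged: bool

    @property
    def params(self) -> np.ndarray:
        return self.coefficients.to_numpy()

    def standard_errors(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance.to_numpy())),
                         index=self.coefficients.index)

    def wald_ci(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        se = self.standard_errors()
        return pd.DataFrame({"low": self.coefficients - z * se,
                             "high": self.coefficients + z * se})


def design_matrix(cohort: CohortTable, terms: Sequence[str]) -> pd.DataFrame:
    frame = cohort.df.copy()
    frame["n_risk_alleles"] = cohort.n_risk_alleles
    frame["gen"] = frame["sex"]  # model coding: 1=male, 2=female
    for t in terms:
        if t not in frame.columns:
            raise ValidationError(f"unknown model term {t!r}")
        if frame[t].isna().any():
            raise ValidationError(f"term {t!r} has missing values")
    x = frame[list(terms)].astype(float)
    return sm.add_constant(x, has_constant="add")


def fit_model(cohort: CohortTable, spec: ModelSpec) -> LogisticFit:
    """Fit ``spec`` by maximum likelihood; deterministic given the data."""
    cohort.require_both_groups()
    x = design_matrix(cohort, spec.terms)
    y = cohort.is_case
    model = sm.Logit(y, x)
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # separation raises PerfectSeparationError
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge",
                               diagnostics=res.mle_retvals)
    return LogisticFit(
        spec=spec,
        coefficients=pd.Series(res.params, index=x.columns),
        covariance=pd.DataFrame(res.cov_params(), index=x.columns,
                                columns=x.columns),
        log_likelihood=float(res.llf),
        n_obs=int(res.nobs),
        converged=True)


def predict_probability(coefficients: pd.Series | Sequence[float],
                        covariates) -> np.ndarray | float:
    """logistic(beta0 + sum beta_k x_k).

    ``coefficients`` is const-first (as stored on LogisticFit);
    ``covariates`` is a mapping/frame/array of the term values in the
    same order, without the constant.
    """
    beta = np.asarray(coefficients, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        x = covariates.to_numpy(dtype=float)
    elif isinstance(covariates, dict):
        if isinstance(coefficients, pd.Series):
            order = [t for t in coefficients.index if t != "const"]
        else:
            order = list(covariates)
        x = np.asarray([covariates[t] for t in order], dtype=float).T
    else:
        x = np.asarray(covariates, dtype=float)
    eta = beta[0] + np.atleast_2d(x) @ beta[1:]
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(p[0]) if p.size == 1 and np.ndim(covariates) <= 1 else p


def scores_for(fit: LogisticFit, cohort: CohortTable) -> np.ndarray:
    """In-sample predicted probabilities of ``fit`` on ``cohort``."""
    x = design_matrix(cohort, fit.spec.terms)
    eta = x.to_numpy() @ fit.params
    return 1.0 / (1.0 + np.exp(-eta))


def likelihood_ratio_compare(reduced: LogisticFit, full: LogisticFit):
    """LRT of two nested fits on the same observations.

    Returns ``(statistic, df, p_value)`` with statistic
    2*(ll_full - ll_reduced) ~ chi2(df = added terms).
    """
    if not set(reduced.spec.terms) <= set(full.spec.terms):
        raise ValidationError("reduced model terms not nested in full model")
    if reduced.n_obs != full.n_obs:
        raise ValidationError("fits use different observation counts")
    df = len(full.spec.terms) - len(reduced.spec.terms)
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return float(stat), df, p


def stepwise_select(cohort: CohortTable, candidate_terms: Sequence[str],
                    alpha_enter: float = 0.05,
                    alpha_remove: float = 0.10) -> ModelSpec:
    """Forward-backward selection on likelihood-ratio entry and Wald
    removal tests; deterministic with ties broken by candidate order."""
    if not candidate_terms:
        raise ValidationError("need at least one candidate term")
    cohort.require_both_groups()
    selected: list[str] = []
    while True:
        changed = False
        # forward: best LR p among candidates not yet in the model
        current = fit_model(cohort, ModelSpec("step", tuple(selected)))
        best_term, best_p = None, alpha_enter
        for term in candidate_terms:
            if term in selected:
                continue
            trial = fit_model(cohort, ModelSpec("step", tuple(selected + [term])))
            _, _, p = likelihood_ratio_compare(current, trial)
            if p < best_p:  # strict: first candidate wins ties
                best_term, best_p = term, p
        if best_term is not None:
            selected.append(best_term)
            changed = True
        # backward: drop worst Wald p above the removal threshold
        if selected:
            fit = fit_model(cohort, ModelSpec("step", tuple(selected)))
            se = fit.standard_errors()
            wald_p = {
                t: 2 * stats.norm.sf(abs(fit.coefficients[t] / se[t]))
                for t in selected}
            worst = max(selected, key=lambda t: wald_p[t])
            if wald_p[worst] > alpha_remove and worst != best_term:
                selected.remove(worst)
                changed = True
        if not changed:
            break
    return ModelSpec("stepwise", tuple(selected))


def split_validation(cohort: CohortTable, holdout_mask,
                     spec: ModelSpec) -> tuple[float, float]:
    """Fit on the training split, score both splits.

    Returns ``(AUC_train, AUC_holdout)``; each split must contain both
    classes.
    """
    holdout_mask = np.asarray(holdout_mask, dtype=bool)
    train = cohort.subset(~holdout_mask, "train split")
    hold = cohort.subset(holdout_mask, "holdout split")
    for part in (train, hold):
        part.require_both_groups()
    fit = fit_model(train, spec)
    return (auc(scores_for(fit, train), train.is_case),
            auc(scores_for(fit, hold), hold.is_case))


def cross_validate(cohort: CohortTable, spec: ModelSpec, k: int = 10,
                   seed: int = 0) -> float:
    """Mean out-of-fold AUC over stratified k-fold CV; deterministic
    given ``seed``."""
    if k < 2:
        raise ValidationError("need at least 2 folds")
    cohort.require_both_groups()
    y = cohort.is_case
    if min(cohort.n_case, cohort.n_control) < k:
        raise DegenerateInputError("too few subjects per class for k folds")
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in folds.split(np.zeros(len(y)), y):
        mask = np.zeros(len(y), dtype=bool)
        mask[test_idx] = True
        _, holdout_auc = split_validation(cohort, mask, spec)
        aucs.append(holdout_auc)
    return float(np.mean(aucs))
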