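"""Demographic standardization of the control group by resampling.

A case-control sample recruited from clinics need not match the
age-sex structure of the population the model is meant to screen.
The remedy implemented here mirrors the study's simulation: restrict to
subjects at or above a minimum age, repeatedly draw a control subgroup
whose sex ratio (or full sex-by-age-stratum composition, against a
reference demographic table) matches the target population, draw a
random case subgroup, refit the prediction model and record its AUC —
summarizing over many replicates.

The same machinery reports a liability-scale variance decomposition of
each fitted linear predictor eta = G + E, with G the genetic term and E
the clinical terms; under no gene-environment interaction Cov(G, E) is
expected to vanish and the genetic share is Var(G)/Var(eta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, DemographicTable, FEMALE, MALE
from .evaluation import auc
from .exceptions import (ConvergenceError, DegenerateInputError,
                         SamplingError, ValidationError)
from .risk_models import LogisticFit, ModelSpec, fit_model, scores_for


@dataclass
class ResampleConfig:
    """Conditions of one standardization run.

    Defaults follow the study's full-age-distribution arm: age >= 60,
    128 male / 163 female controls and 291 cases per replicate.
    """

    min_age: float = 60.0
    n_control_male: int = 128
    n_control_female: int = 163
    n_case: int = 291
    match_mode: str = "sex_ratio_only"   # or "full_age_distribution"
    demographic: DemographicTable | None = None
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if min(self.n_control_male, self.n_control_female, self.n_case) <= 0:
            raise ValidationError("sample counts must be positive")
        if self.replicates < 1:
            raise ValidationError("need at least one replicate")
        if self.match_mode not in ("sex_ratio_only", "full_age_distribution"):
            raise ValidationError(f"unknown match_mode {self.match_mode!r}")
        if self.match_mode == "full_age_distribution" and self.demographic is None:
            raise ValidationError(
                "full_age_distribution matching needs a DemographicTable")


@dataclass
class VarianceShares:
    var_genetic: float
    var_clinical: float
    covariance: float
    var_total: float
    genetic_share: float
    clinical_share: float

    def __post_init__(self):
        implied = self.var_genetic + self.var_clinical + 2 * self.covariance
        if abs(self.var_total - implied) > 1e-9 * max(1.0, abs(self.var_total)):
            raise ValidationError("variance components do not add up")


@dataclass
class SimulationSummary:
    aucs: np.ndarray
    genetic_shares: np.ndarray
    mean_auc: float
    sd_auc: float
    mean_share: float
    n_failed: int


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer quotas summing to ``total`` with each quota within 1 of
    its exact share (largest-remainder / Hare rounding)."""
    exact = weights / weights.sum() * total
    base = np.floor(exact).astype(int)
    short = total - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:short]] += 1
    return base


def sample_matched_controls(cohort: CohortTable, config: ResampleConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """Row indices (into ``cohort.df``) of a demographically matched
    control subset, drawn without replacement.

    sex_ratio_only: simple random samples of the per-sex counts among
    controls aged >= min_age.  full_age_distribution: per-sex totals are
    split over the demographic table's sex-by-age strata by largest-
    remainder rounding of the table proportions, then sampled within
    each stratum.
    """
    df = cohort.df
    eligible = (df["status"] == "control") & (df["age"] >= config.min_age)
    if config.match_mode == "sex_ratio_only":
        out = []
        for sex, want in ((MALE, config.n_control_male),
                          (FEMALE, config.n_control_female)):
            pool = np.flatnonzero(eligible & (df["sex"] == sex))
            if len(pool) < want:
                raise SamplingError(
                    f"only {len(pool)} eligible controls of sex {sex}, "
                    f"need {want}")
            out.append(rng.choice(pool, size=want, replace=False))
        return np.concatenate(out)

    demo = config.demographic
    total = config.n_control_male + config.n_control_female
    quotas = _largest_remainder(demo.strata["proportion"].to_numpy(), total)
    stratum_of = demo.assign_stratum(df["sex"].to_numpy(), df["age"].to_numpy())
    out = []
    for s_idx, want in enumerate(quotas):
        if want == 0:
            continue
        pool = np.flatnonzero(eligible.to_numpy() & (stratum_of == s_idx))
        if len(pool) < want:
            row = demo.strata.iloc[s_idx]
            raise SamplingError(
                f"stratum sex={int(row['sex'])} age=[{row['age_lo']:g},"
                f"{row['age_hi']:g}): {len(pool)} eligible controls, "
                f"need {want}")
        out.append(rng.choice(pool, size=want, replace=False))
    return np.concatenate(out)


def variance_decomposition(fit: LogisticFit, cohort: CohortTable,
                           genetic_terms: tuple[str, ...] = ("n_risk_alleles",),
                           ) -> VarianceShares:
    """Split the fitted linear predictor into genetic and clinical parts
    and decompose its variance over the cohort's subjects."""
    gterms = [t for t in fit.spec.terms if t in genetic_terms]
    eterms = [t for t in fit.spec.terms if t not in genetic_terms]
    if not gterms or not eterms:
        raise ValidationError(
            "decomposition needs a genetic term and a clinical term in the fit")
    frame = cohort.df.copy()
    frame["n_risk_alleles"] = cohort.n_risk_alleles
    frame["gen"] = frame["sex"]
    g = sum(fit.coefficients[t] * frame[t].to_numpy(dtype=float)
            for t in gterms)
    e = sum(fit.coefficients[t] * frame[t].to_numpy(dtype=float)
            for t in eterms)
    var_g = float(np.var(g))
    var_e = float(np.var(e))
    cov = float(np.cov(g, e, ddof=0)[0, 1])
    total = var_g + var_e + 2 * cov
    if total <= 0:
        raise DegenerateInputError("zero total variance on the liability scale")
    return VarianceShares(var_genetic=var_g, var_clinical=var_e,
                          covariance=cov, var_total=total,
                          genetic_share=var_g / total,
                          clinical_share=var_e / total)


def adjusted_auc_simulation(cohort: CohortTable, spec: ModelSpec,
                            config: ResampleConfig) -> SimulationSummary:
    """The standardization simulation: per replicate, draw matched
    controls and random cases (age >= min_age), refit ``spec``, record
    the in-replicate AUC and genetic variance share.

    Replicate RNG streams are spawned from the master seed by counter,
    so the whole summary is reproducible and insensitive to failed
    replicates elsewhere.  More than 5% failed replicates abort the run.
    """
    df = cohort.df
    case_pool = np.flatnonzero(
        ((df["status"] == "case") & (df["age"] >= config.min_age)).to_numpy())
    if len(case_pool) < config.n_case:
        raise SamplingError(
            f"only {len(case_pool)} cases aged >= {config.min_age:g}, "
            f"need {config.n_case}")
    aucs, shares = [], []
    n_failed = 0
    root = np.random.SeedSequence([int(config.seed), 101])
    has_genetic = "n_risk_alleles" in spec.terms
    for rep, child in enumerate(root.spawn(config.replicates)):
        rng = np.random.default_rng(child)
        try:
            ctrl_idx = sample_matched_controls(cohort, config, rng)
            case_idx = rng.choice(case_pool, size=config.n_case, replace=False)
            sub = CohortTable(df.iloc[np.concatenate([case_idx, ctrl_idx])],
                              provenance=f"replicate {rep}")
            fit = fit_model(sub, spec)
            aucs.append(auc(scores_for(fit, sub), sub.is_case))
            if has_genetic and len(spec.terms) > 1:
                shares.append(
                    variance_decomposition(fit, sub).genetic_share)
        except (SamplingError, ConvergenceError, DegenerateInputError):
            n_failed += 1
    if n_failed > 0.05 * config.replicates:
        raise SamplingError(
            f"{n_failed}/{config.replicates} replicates failed")
    aucs = np.asarray(aucs)
    shares = np.asarray(shares) if shares else np.array([np.nan])
    return SimulationSummary(
        aucs=aucs, genetic_shares=shares,
        mean_auc=float(aucs.mean()), sd_auc=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        mean_share=float(np.nanmean(shares)), n_failed=n_failed)
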