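"""Population-attributable risk for multi-level exposures.

Case-control data give no direct disease risks, but the attributable
fraction can still be estimated from the case exposure distribution and
odds ratios (Bruzzi's estimator):

    PAR = 1 - sum_j rho_j / OR_j

where rho_j is the proportion of *cases* in exposure stratum j and OR_j
the (optionally covariate-adjusted) odds ratio of stratum j against the
reference stratum (OR_ref = 1).  Adjusted ORs come from a single
logistic fit with stratum indicator variables plus the adjustment
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .exceptions import DegenerateInputError, ValidationError
from .risk_models import ModelSpec, fit_model

BMI_CATEGORIES = ("normal_underweight", "overweight", "obese")


@dataclass
class PARResult:
    strata: tuple[str, ...]
    case_proportions: np.ndarray     # rho_j, sums to 1
    odds_ratios: np.ndarray          # OR_j, reference stratum first, OR=1
    par: float
    method: str
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self):
        self.case_proportions = np.asarray(self.case_proportions, float)
        self.odds_ratios = np.asarray(self.odds_ratios, float)
        if abs(self.case_proportions.sum() - 1.0) > 1e-9:
            raise ValidationError("case proportions must sum to 1")
        if self.odds_ratios[0] != 1.0:
            raise ValidationError("reference stratum OR must be exactly 1")


def par_multilevel(case_proportions: Sequence[float],
                   odds_ratios: Sequence[float]) -> float:
    """PAR = 1 - sum_j rho_j / OR_j over exposure strata.

    The first stratum is the reference (OR must be 1); returns 0 when
    every OR is 1 and approaches 1 as all non-reference ORs grow.
    """
    rho = np.asarray(case_proportions, dtype=float)
    ors = np.asarray(odds_ratios, dtype=float)
    if rho.shape != ors.shape:
        raise ValidationError("proportions and odds ratios differ in length")
    if (rho < 0).any():
        raise ValidationError("negative case proportion")
    if abs(rho.sum() - 1.0) > 1e-9:
        raise ValidationError(f"case proportions sum to {rho.sum()!r}, expected 1")
    if (ors <= 0).any():
        raise ValidationError("odds ratios must be positive")
    return float(1.0 - (rho / ors).sum())


def categorize_bmi(bmi: float) -> str:
    """WHO-style BMI bands: <25 normal/underweight, [25, 30) overweight,
    >=30 obese (the band edges 25-26 are closed half-open here)."""
    if not bmi > 0:
        raise ValidationError(f"bmi must be positive, got {bmi!r}")
    if bmi < 25:
        return "normal_underweight"
    if bmi < 30:
        return "overweight"
    return "obese"


#: built-in stratification rules: name -> (labels in reference-first order,
#: function CohortTable -> per-subject label array)
def _risk_allele_strata(cohort: CohortTable) -> np.ndarray:
    n = cohort.n_risk_alleles
    bins = np.array(["0-1", "2", "3", "4", "5-6"])
    idx = np.clip(n - 1, 0, 4)
    return bins[idx]


def _bmi_strata(cohort: CohortTable) -> np.ndarray:
    return np.array([categorize_bmi(b) for b in cohort.df["bmi"]])


EXPOSURE_RULES: dict[str, tuple[tuple[str, ...], Callable]] = {
    "risk_alleles": (("0-1", "2", "3", "4", "5-6"), _risk_allele_strata),
    "bmi_category": (BMI_CATEGORIES, _bmi_strata),
}


def par_from_cohort(cohort: CohortTable, exposure: str | tuple,
                    adjust: Sequence[str] = (),
                    bootstrap: int = 0, seed: int = 0) -> PARResult:
    """Bruzzi PAR from subject-level data.

    ``exposure`` names a built-in rule ("risk_alleles": counts binned
    0-1 / 2 / 3 / 4 / 5-6 with 0-1 as reference; "bmi_category") or is a
    ``(labels, rule)`` pair.  ``adjust`` lists covariate terms entering
    the logistic fit alongside the stratum indicators.  With
    ``bootstrap`` > 0, a subject-level bootstrap stratified by group
    yields a percentile 95% CI.
    """
    cohort.require_both_groups()
    if isinstance(exposure, str):
        try:
            labels, rule = EXPOSURE_RULES[exposure]
        except KeyError:
            raise ValidationError(f"unknown exposure rule {exposure!r}") from None
    else:
        labels, rule = exposure

    def compute(co: CohortTable) -> PARResult:
        strata = np.asarray(rule(co))
        present = [l for l in labels if (strata == l).any()]
        if len(present) < 2:
            raise DegenerateInputError(
                "exposure collapses to a single stratum")
        if (strata == labels[0]).sum() == 0:
            raise DegenerateInputError("empty reference stratum")
        is_case = co.is_case.astype(bool)
        for lab in present:
            m = strata == lab
            if not (is_case[m].any() and (~is_case[m]).any()):
                raise DegenerateInputError(
                    f"stratum {lab!r} lacks cases or controls")
        rho = np.array([(strata[is_case] == lab).mean() for lab in present])
        extra = co.df.copy()
        ind_cols = []
        for lab in present[1:]:
            col = f"_stratum_{lab}"
            extra[col] = (strata == lab).astype(float)
            ind_cols.append(col)
        aug = CohortTable(extra, co.provenance)
        fit = fit_model(aug, ModelSpec("par", tuple(ind_cols) + tuple(adjust)))
        ors = np.concatenate(
            [[1.0], np.exp(fit.coefficients[ind_cols].to_numpy())])
        return PARResult(
            strata=tuple(present), case_proportions=rho, odds_ratios=ors,
            par=par_multilevel(rho, ors),
            method="bruzzi" + (f"+adjusted({','.join(adjust)})" if adjust else ""))

    result = compute(cohort)
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        is_case = cohort.is_case.astype(bool)
        idx_case = np.flatnonzero(is_case)
        idx_ctrl = np.flatnonzero(~is_case)
        draws = []
        for _ in range(bootstrap):
            take = np.concatenate([
                rng.choice(idx_case, len(idx_case), replace=True),
                rng.choice(idx_ctrl, len(idx_ctrl), replace=True)])
            df = cohort.df.iloc[take].copy()
            df["subject_id"] = [f"b{i}" for i in range(len(df))]
            try:
                draws.append(compute(CohortTable(df, "bootstrap")).par)
            except DegenerateInputError:
                continue
        if draws:
            lo, hi = np.percentile(draws, [2.5, 97.5])
            result.ci_low, result.ci_high = float(lo), float(hi)
    return result
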