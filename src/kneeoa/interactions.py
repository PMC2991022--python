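"""Pairwise locus independence and interaction tests.

Two families: Pearson chi-square tests of independence on the 3x3
dosage-by-dosage table (case-only, or all subjects pooled), and nested
logistic-model likelihood-ratio tests where the interaction is the
product of the two terms (1 df).  Bonferroni families are always passed
explicitly by the caller — for the three gene pairs the family size is 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .exceptions import DegenerateInputError, ValidationError
from .risk_models import ModelSpec, fit_model, likelihood_ratio_compare


@dataclass
class InteractionTestResult:
    pair: tuple[str, str]
    design: str                  # case_only | pooled | nested_models
    statistic: float
    df: int
    p_value: float
    p_bonferroni: float

    def __post_init__(self):
        if self.p_bonferroni < self.p_value - 1e-12 or self.p_bonferroni > 1.0:
            raise ValidationError("Bonferroni p must lie in [p_value, 1]")


def _resolve(cohort: CohortTable, term: str) -> np.ndarray:
    frame = cohort.df
    if term in frame.columns:
        return frame[term].to_numpy()
    if term == "gen":
        return frame["sex"].to_numpy()
    if term == "n_risk_alleles":
        return cohort.n_risk_alleles
    raise ValidationError(f"unknown term {term!r}")


def genotype_independence_test(cohort: CohortTable, locus_a: str, locus_b: str,
                               design: str = "pooled",
                               bonferroni_m: int = 1) -> InteractionTestResult:
    """Pearson chi-square on the 3x3 dosage table of two loci.

    ``design="case_only"`` restricts to cases (sensitive to
    multiplicative interaction); ``"pooled"`` uses all subjects.
    All-zero rows/columns are collapsed with a warning and the degrees
    of freedom reduced accordingly.
    """
    if design not in ("case_only", "pooled"):
        raise ValidationError(f"unknown design {design!r}")
    sub = cohort.df if design == "pooled" else cohort.df[cohort.df["status"] == "case"]
    if len(sub) == 0:
        raise DegenerateInputError("no subjects in the selected design")
    da = sub[f"dosage_{locus_a}"].to_numpy()
    db = sub[f"dosage_{locus_b}"].to_numpy()
    table = np.zeros((3, 3))
    np.add.at(table, (da, db), 1)
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if (~keep_r).any() or (~keep_c).any():
        warnings.warn("collapsing all-zero dosage rows/columns; "
                      "degrees of freedom reduced", stacklevel=2)
    table = table[keep_r][:, keep_c]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateInputError("dosage table degenerate after collapse")
    if (stats.contingency.expected_freq(table) < 5).any():
        warnings.warn("expected cell count below 5; chi-square approximation "
                      "may be poor", stacklevel=2)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return InteractionTestResult(
        pair=(locus_a, locus_b), design=design, statistic=float(chi2),
        df=int(df), p_value=float(p),
        p_bonferroni=min(1.0, float(p) * bonferroni_m))


def interaction_lrt(cohort: CohortTable, term_a: str, term_b: str,
                    covariates: tuple[str, ...] = (),
                    bonferroni_m: int = 1,
                    categorical: bool = False) -> InteractionTestResult:
    """Likelihood-ratio test for an interaction between two terms.

    Compares logistic models with and without the interaction on top of
    the main effects plus ``covariates``.  Default coding is the product
    of the two terms (1 df); ``categorical=True`` instead adds the full
    set of dosage-by-dosage indicator products (4 df for two 0/1/2 loci).
    """
    va, vb = _resolve(cohort, term_a), _resolve(cohort, term_b)
    for name, v in ((term_a, va), (term_b, vb)):
        if len(np.unique(v)) < 2:
            raise ValidationError(f"term {name!r} is constant; "
                                  "interaction not identifiable")
    base_terms = [term_a, term_b, *covariates]

    extra = cohort.df.copy()
    if categorical:
        inter_cols = []
        for la in (1, 2):
            for lb in (1, 2):
                col = f"_{term_a}{la}_x_{term_b}{lb}"
                extra[col] = ((va == la) & (vb == lb)).astype(float)
                inter_cols.append(col)
    else:
        inter_cols = [f"_{term_a}_x_{term_b}"]
        extra[inter_cols[0]] = va * vb
    aug = CohortTable(extra, cohort.provenance)
    reduced = fit_model(aug, ModelSpec("reduced", tuple(base_terms)))
    full = fit_model(aug, ModelSpec("full", tuple(base_terms + inter_cols)))
    stat, df, p = likelihood_ratio_compare(reduced, full)
    return InteractionTestResult(
        pair=(term_a, term_b), design="nested_models", statistic=stat,
        df=df, p_value=p, p_bonferroni=min(1.0, p * bonferroni_m))


def gene_pair_scan(cohort: CohortTable,
                   covariates: tuple[str, ...] = ()) -> pd.DataFrame:
    """All three locus pairs through the nested-model LRT with the
    Bonferroni family m=3, tidy frame mirroring the published layout."""
    pairs = [("aspn", "gdf5"), ("gdf5", "dvwa"), ("dvwa", "aspn")]
    rows = []
    for a, b in pairs:
        pooled = genotype_independence_test(cohort, a, b, "pooled", bonferroni_m=3)
        case_only = genotype_independence_test(cohort, a, b, "case_only",
                                               bonferroni_m=3)
        lrt = interaction_lrt(cohort, f"dosage_{a}", f"dosage_{b}",
                              covariates=covariates, bonferroni_m=3)
        rows.append({"pair": f"{a.upper()} x {b.upper()}",
                     "p_case_control": pooled.p_value,
                     "p_case_only": case_only.p_value,
                     "p_two_models": lrt.p_value,
                     "p_two_models_bonferroni": lrt.p_bonferroni})
    return pd.DataFrame(rows)
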