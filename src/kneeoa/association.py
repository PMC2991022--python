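"""Single-locus association statistics and risk-allele-count analyses.

Allelic odds ratios treat the 2N chromosomes of a group as independent
observations (the standard allelic test for this design); confidence
intervals are Woolf (log-normal) intervals.  The burden analyses work on
the grouped risk-allele-count histogram, which is sufficient for the
count-only logistic model because its likelihood depends on the data
only through the per-count case/control totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cohort import RiskAlleleDistribution
from .exceptions import ConvergenceError, DegenerateInputError, ValidationError

Z95 = stats.norm.ppf(0.975)


@dataclass
class ORResult:
    """Odds ratio with Woolf 95% CI and a chi-square p-value."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or_se: float
    p_value: float
    method: str

    def __post_init__(self):
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValidationError("CI does not bracket the odds ratio")
        if min(self.odds_ratio, self.ci_low, self.ci_high, self.log_or_se) <= 0:
            raise ValidationError("odds ratio and CI must be positive")


@dataclass
class TrendResult:
    statistic: float
    p_value: float
    scores: tuple


def allele_frequency(homo: int, hetero: int, other: int) -> float:
    """Risk-allele frequency from genotype counts: (2*homo + hetero) / 2N."""
    if min(homo, hetero, other) < 0:
        raise ValidationError("negative genotype count")
    total = homo + hetero + other
    if total == 0:
        raise DegenerateInputError("no subjects")
    return (2 * homo + hetero) / (2 * total)


def _woolf_2x2(a: float, b: float, c: float, d: float, method: str) -> ORResult:
    """OR and Woolf CI for the 2x2 table [[a, b], [c, d]] with exposed
    cases a, exposed controls b, unexposed cases c, unexposed controls d."""
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
        method = method + "+haldane0.5"
    a_, b_, c_, d_ = cells
    log_or = np.log(a_ * d_ / (b_ * c_))
    se = float(np.sqrt((1.0 / cells).sum()))
    chi2, p, _, _ = stats.chi2_contingency(
        np.array([[a_, c_], [b_, d_]]), correction=False)
    return ORResult(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        log_or_se=se, p_value=float(p), method=method)


def allelic_odds_ratio(case_counts: Sequence[int],
                       control_counts: Sequence[int]) -> ORResult:
    """Allelic OR from (homo, hetero, other) genotype counts per group.

    Expands each group into risk vs non-risk allele counts
    (2*homo + hetero vs 2*other + hetero) and takes the cross-product
    ratio of the resulting 2x2 allele table.
    """
    ch, ce, co = case_counts
    kh, ke, ko = control_counts
    if min(ch, ce, co, kh, ke, ko) < 0:
        raise ValidationError("negative genotype count")
    if ch + ce + co == 0 or kh + ke + ko == 0:
        raise DegenerateInputError("empty group")
    return _woolf_2x2(2 * ch + ce, 2 * kh + ke, 2 * co + ce, 2 * ko + ke,
                      method="allelic-2x2-woolf")


def armitage_trend_test(dist: RiskAlleleDistribution,
                        scores: Sequence[float] | None = None) -> TrendResult:
    """Cochran-Armitage test for a linear trend in the case proportion
    across ordered risk-allele counts; invariant under affine rescaling
    of the scores (default 0..6)."""
    s = np.arange(7, dtype=float) if scores is None else np.asarray(scores, float)
    if s.shape != (7,):
        raise ValidationError("scores must match the 7 count bins")
    r = dist.case.astype(float)
    n = (dist.case + dist.control).astype(float)
    N, R = n.sum(), r.sum()
    if R == 0 or R == N:
        raise DegenerateInputError("all subjects in one group")
    num = N * (N * (s * r).sum() - R * (s * n).sum()) ** 2
    den = R * (N - R) * (N * (s * s * n).sum() - (s * n).sum() ** 2)
    if den == 0:
        raise DegenerateInputError("scores are constant over occupied bins")
    chi2 = num / den
    return TrendResult(statistic=float(chi2),
                       p_value=float(stats.chi2.sf(chi2, df=1)),
                       scores=tuple(s))


def permutation_trend_pvalue(dist: RiskAlleleDistribution,
                             n_permutations: int = 100_000,
                             seed: int = 0) -> float:
    """Monte-Carlo reference p for the trend test: redistributes case
    status over subjects at fixed margins (multivariate hypergeometric)
    and compares the statistic.  An oracle for the asymptotic p-value."""
    rng = np.random.default_rng(seed)
    observed = armitage_trend_test(dist).statistic
    n = dist.case + dist.control
    draws = rng.multivariate_hypergeometric(n, dist.n_case, size=n_permutations)
    s = np.arange(7, dtype=float)
    N, R = float(n.sum()), float(dist.n_case)
    num = N * (N * (draws * s).sum(axis=1) - R * float((s * n).sum())) ** 2
    den = R * (N - R) * (N * float((s * s * n).sum()) - float((s * n).sum()) ** 2)
    chi2 = num / den
    return float((np.count_nonzero(chi2 >= observed - 1e-12) + 1)
                 / (n_permutations + 1))


def grouped_odds_ratio(dist: RiskAlleleDistribution,
                       reference_bins: Sequence[int],
                       target_bins: Sequence[int]) -> ORResult:
    """OR of carrying a count in ``target_bins`` vs ``reference_bins``
    (e.g. 5-6 risk alleles vs the 0-1 reference group)."""
    ref, tgt = set(reference_bins), set(target_bins)
    if ref & tgt:
        raise ValidationError("reference and target bins overlap")
    idx_r, idx_t = sorted(ref), sorted(tgt)
    a = int(dist.case[idx_t].sum())
    b = int(dist.control[idx_t].sum())
    c = int(dist.case[idx_r].sum())
    d = int(dist.control[idx_r].sum())
    if (a + b == 0) or (c + d == 0):
        raise DegenerateInputError("empty collapsed group")
    return _woolf_2x2(a, b, c, d, method="grouped-2x2-woolf")


def control_bin_proportion(dist: RiskAlleleDistribution,
                           bins: Sequence[int]) -> float:
    """Fraction of the control group whose count falls in ``bins``."""
    total = dist.n_control
    if total == 0:
        raise DegenerateInputError("no controls")
    return float(dist.control[sorted(set(bins))].sum() / total)


def per_allele_or_from_distribution(dist: RiskAlleleDistribution) -> tuple[ORResult, tuple[float, float]]:
    """Per-allele OR from a grouped-likelihood logistic regression of
    case status on the risk-allele count.

    Fits intercept + slope by maximum likelihood on the binomial counts
    (equivalent to the subject-level fit) and returns
    ``(ORResult for exp(slope), (intercept, slope))``.
    """
    occupied = (dist.case + dist.control) > 0
    if int(np.count_nonzero(occupied)) < 2:
        raise DegenerateInputError("need at least two occupied count bins")
    x = sm.add_constant(np.arange(7, dtype=float)[occupied])
    endog = np.column_stack([dist.case[occupied], dist.control[occupied]])
    model = sm.GLM(endog, x, family=sm.families.Binomial())
    fit = model.fit()
    method = "grouped-logistic-wald"
    params = np.asarray(fit.params, dtype=float)
    bse = np.asarray(fit.bse, dtype=float)
    if not np.all(np.isfinite(bse)) or bse[1] > 1e3:
        # quasi-separation: the slope runs away and Wald intervals collapse
        method += "+separation-flagged"
    if not np.all(np.isfinite(params)):
        raise ConvergenceError("grouped logistic fit did not converge",
                               diagnostics=fit)
    intercept, slope = float(params[0]), float(params[1])
    se = float(bse[1]) if np.isfinite(bse[1]) else np.inf
    wald_z = slope / se if se > 0 else np.inf
    p = float(2 * stats.norm.sf(abs(wald_z)))
    orr = float(np.exp(slope))
    with np.errstate(over="ignore", under="ignore"):
        lo = float(np.exp(slope - Z95 * se)) if np.isfinite(se) else 0.0
        hi = float(np.exp(slope + Z95 * se)) if np.isfinite(se) else np.inf
    res = ORResult(
        odds_ratio=orr,
        ci_low=min(max(lo, 1e-300), orr),  # guard exp underflow at huge se
        ci_high=max(hi, orr),
        log_or_se=se if np.isfinite(se) else 1e12,
        p_value=p, method=method)
    return res, (intercept, slope)
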