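"""Synthetic case-control cohort generator.

Emulates the statistical structure the downstream analyses assume: a
large source population with Hardy-Weinberg genotypes at three
independent loci, sex-specific anthropometrics, truncated-normal ages,
and disease status drawn from a logistic model in the risk-allele count
``n``, sex code ``gen`` (1=male, 2=female), age and BMI.  A cohort is
then formed retrospectively by sampling exactly ``n_case`` cases and
``n_control`` controls without replacement, mirroring a case-control
design (so fitted intercepts carry the sampling-fraction offset and are
not population quantities; slope coefficients are recoverable).

Defaults reproduce the study's conditions: 933 cases / 1,225 controls,
control-group risk-allele frequencies (0.062, 0.747, 0.569) for ASPN /
GDF5 / DVWA, and the published clinical+genetic model coefficients
(-8.395, 0.200, 0.302, 0.045, 0.162).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FEMALE, LOCI, MALE, CohortTable, DemographicTable
from .exceptions import GenerationError, ValidationError

#: (beta0, beta_n, beta_gen, beta_age, beta_bmi) of the published model
DEFAULT_COEFFICIENTS = (-8.395, 0.200, 0.302, 0.045, 0.162)

#: control-group risk-allele frequencies, ASPN / GDF5 / DVWA
DEFAULT_ALLELE_FREQS = (0.062, 0.747, 0.569)

#: per-sex (height_mean, height_sd, weight_mean, weight_sd), cm / kg,
#: from the study's control-group clinical summary
DEFAULT_ANTHROPOMETRICS = {
    MALE: (162.9, 7.5, 63.8, 10.7),
    FEMALE: (149.9, 6.1, 51.5, 9.0),
}

COEFFICIENT_NAMES = ("const", "n_risk_alleles", "gen", "age", "bmi")


@dataclass
class GeneratorParams:
    """Tunable conditions of the synthetic cohort.

    ``age_distribution`` is either ``(mean, sd, lo, hi)`` for a truncated
    normal (default 70 +/- 9 on [40, 95]) or a DemographicTable, in which
    case sex and age stratum are drawn jointly from it and
    ``sex_female_fraction`` is ignored.  ``extra_linear_term`` is a hook
    adding a custom contribution (e.g. a gene-gene product term) to the
    linear predictor; the default model has none.
    """

    n_case: int = 933
    n_control: int = 1225
    allele_freqs: tuple[float, float, float] = DEFAULT_ALLELE_FREQS
    coefficients: tuple[float, float, float, float, float] = DEFAULT_COEFFICIENTS
    sex_female_fraction: float = 0.754
    age_distribution: object = (70.0, 9.0, 40.0, 95.0)
    anthropometrics: dict = field(
        default_factory=lambda: dict(DEFAULT_ANTHROPOMETRICS))
    height_weight_correlation: float = 0.4
    extra_linear_term: Callable[[pd.DataFrame], np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValidationError("group sizes must be positive")
        if not all(0.0 < q < 1.0 for q in self.allele_freqs):
            raise ValidationError("allele frequencies must lie in (0, 1)")
        if not 0.0 < self.sex_female_fraction < 1.0:
            raise ValidationError("sex_female_fraction must lie in (0, 1)")
        for sex, (hm, hs, wm, ws) in self.anthropometrics.items():
            if hs <= 0 or ws <= 0:
                raise ValidationError(f"non-positive sd for sex {sex}")
        if not isinstance(self.age_distribution, DemographicTable):
            mean, sd, lo, hi = self.age_distribution
            if sd <= 0 or hi <= lo:
                raise ValidationError("invalid truncated-normal age parameters")


def _draw_sex_age(params: GeneratorParams, size: int, rng: np.random.Generator):
    ad = params.age_distribution
    if isinstance(ad, DemographicTable):
        strata = ad.strata
        idx = rng.choice(len(strata), size=size, p=strata["proportion"].to_numpy())
        sex = strata["sex"].to_numpy()[idx]
        lo = strata["age_lo"].to_numpy()[idx]
        hi = strata["age_hi"].to_numpy()[idx]
        age = rng.uniform(lo, hi)
        return sex.astype(int), age
    sex = np.where(rng.random(size) < params.sex_female_fraction, FEMALE, MALE)
    mean, sd, lo, hi = ad
    a, b = (lo - mean) / sd, (hi - mean) / sd
    age = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    return sex, age


def simulate_population(params: GeneratorParams, size: int,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Source population before case-control sampling.

    Returns a frame with sex/age/height/weight/bmi, per-locus dosages
    (Binomial(2, q), i.e. Hardy-Weinberg, independent across loci),
    disease probability and realized status.
    """
    sex, age = _draw_sex_age(params, size, rng)
    height = np.empty(size)
    weight = np.empty(size)
    rho = params.height_weight_correlation
    for s, (hm, hs, wm, ws) in params.anthropometrics.items():
        m = sex == s
        z_h = rng.standard_normal(m.sum())
        z_w = rng.standard_normal(m.sum())
        height[m] = hm + hs * z_h
        # weight shares a latent factor with height
        weight[m] = wm + ws * (rho * z_h + np.sqrt(1 - rho ** 2) * z_w)
    height = np.clip(height, 120.0, 210.0)
    weight = np.clip(weight, 30.0, 150.0)
    bmi = weight / (height / 100.0) ** 2

    df = pd.DataFrame({"sex": sex, "age": age, "height": height,
                       "weight": weight, "bmi": bmi})
    for locus, q in zip(LOCI, params.allele_freqs):
        df[f"dosage_{locus}"] = rng.binomial(2, q, size=size)
    n_alleles = df[[f"dosage_{l}" for l in LOCI]].sum(axis=1).to_numpy()

    b0, b_n, b_gen, b_age, b_bmi = params.coefficients
    eta = b0 + b_n * n_alleles + b_gen * sex + b_age * age + b_bmi * bmi
    if params.extra_linear_term is not None:
        eta = eta + np.asarray(params.extra_linear_term(df), dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    df["p_disease"] = p
    df["status"] = np.where(rng.random(size) < p, "case", "control")
    return df


def _pilot_prevalence(params: GeneratorParams, rng: np.random.Generator,
                      pilot: int = 2000) -> float:
    pop = simulate_population(params, pilot, rng)
    return float(pop["p_disease"].mean())


def population_multiplier(params: GeneratorParams, margin: float = 1.5,
                          cap: int = 64) -> int:
    """Source-population size as a multiple of ``n_case + n_control``
    chosen so both expected group counts exceed ``margin`` times the
    requested sizes (estimated from a seeded pilot simulation; capped,
    so extreme parameters surface later as a generation error)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 11]))
    prev = _pilot_prevalence(params, rng)
    prev = min(max(prev, 1.0 / 2001), 1 - 1.0 / 2001)
    total = params.n_case + params.n_control
    need = margin * max(params.n_case / prev, params.n_control / (1.0 - prev))
    return int(np.clip(np.ceil(need / total), 2, cap))


def generate_cohort(params: GeneratorParams | None = None, *,
                    seed: int | None = None) -> CohortTable:
    """Simulate a source population and sample a case-control cohort.

    Deterministic given ``params.seed`` (overridable via ``seed``);
    raises GenerationError when the realized population cannot supply
    the requested group sizes.
    """
    params = params if params is not None else GeneratorParams()
    if seed is not None:
        params = GeneratorParams(**{**params.__dict__, "seed": seed})
    master = np.random.SeedSequence([int(params.seed), 7])
    rng = np.random.default_rng(master)
    size = population_multiplier(params) * (params.n_case + params.n_control)
    pop = simulate_population(params, size, rng)

    case_idx = np.flatnonzero((pop["status"] == "case").to_numpy())
    ctrl_idx = np.flatnonzero((pop["status"] == "control").to_numpy())
    if len(case_idx) < params.n_case or len(ctrl_idx) < params.n_control:
        raise GenerationError(
            f"simulated population of {size} yielded {len(case_idx)} cases / "
            f"{len(ctrl_idx)} controls, fewer than requested "
            f"({params.n_case}/{params.n_control}); increase the population "
            "multiplier cap or moderate the model coefficients")
    take = np.concatenate([
        rng.choice(case_idx, size=params.n_case, replace=False),
        rng.choice(ctrl_idx, size=params.n_control, replace=False)])
    sample = pop.iloc[take].reset_index(drop=True)
    sample.insert(0, "subject_id",
                  [f"sim{params.seed}-{i:06d}" for i in range(len(sample))])
    sample = sample.drop(columns=["p_disease"])
    sample["age"] = sample["age"].round(1)
    sample["height"] = sample["height"].round(1)
    sample["weight"] = sample["weight"].round(1)
    sample["bmi"] = sample["weight"] / (sample["height"] / 100.0) ** 2
    return CohortTable(sample, provenance=f"synthetic(seed={params.seed})")
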