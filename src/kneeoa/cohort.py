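"""Cohort data model and delimited-text I/O.

A cohort is a case-control table of subjects, each carrying disease
status, sex (coded 1=male, 2=female), age, anthropometrics and the
risk-allele dosage (0, 1 or 2 copies) at each of the three knee-OA
susceptibility loci: the ASPN aspartic-acid D-repeat risk allele,
GDF5 rs143383 and DVWA rs7639618.  The multiallelic ASPN microsatellite
is collapsed to the dosage of its named risk allele, so every locus is
a 0/1/2 column and the per-subject genetic score is simply the dosage
sum (0..6 risk alleles).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import DegenerateInputError, FormatError, ValidationError

LOCI = ("aspn", "gdf5", "dvwa")
DOSAGE_COLUMNS = tuple(f"dosage_{locus}" for locus in LOCI)

#: canonical column order of the cohort CSV/TSV schema
COHORT_COLUMNS = (
    "subject_id", "status", "sex", "age", "height", "weight", "bmi",
) + DOSAGE_COLUMNS

_SEX_ALIASES = {"m": 1, "male": 1, "1": 1, "f": 2, "female": 2, "2": 2}
_STATUS_ALIASES = {"case": "case", "control": "control", "1": "case", "0": "control"}

MALE, FEMALE = 1, 2


@dataclass(frozen=True)
class SubjectRecord:
    """One individual of the case-control cohort.

    ``sex`` follows the prediction-model coding (1=male, 2=female);
    ``dosage_*`` is the risk-allele count at the locus.
    """

    subject_id: str
    status: str                 # "case" | "control"
    sex: int                    # 1=male, 2=female
    age: float                  # years
    bmi: float                  # kg/m^2
    dosage_aspn: int
    dosage_gdf5: int
    dosage_dvwa: int
    height: float | None = None  # cm
    weight: float | None = None  # kg

    def __post_init__(self):
        problems = _record_problems(self)
        if problems:
            raise ValidationError(
                f"subject {self.subject_id!r}: " + "; ".join(problems))

    @property
    def n_risk_alleles(self) -> int:
        return count_risk_alleles(
            (self.dosage_aspn, self.dosage_gdf5, self.dosage_dvwa))


def _record_problems(rec) -> list[str]:
    problems = []
    if rec.status not in ("case", "control"):
        problems.append(f"status {rec.status!r} not in {{case, control}}")
    if rec.sex not in (MALE, FEMALE):
        problems.append(f"sex {rec.sex!r} not in {{1, 2}}")
    if not (rec.age >= 0):
        problems.append(f"age {rec.age!r} negative or missing")
    if not (rec.bmi > 0):
        problems.append(f"bmi {rec.bmi!r} must be positive")
    for col in DOSAGE_COLUMNS:
        d = getattr(rec, col)
        if d not in (0, 1, 2):
            problems.append(f"{col} = {d!r} outside {{0, 1, 2}}")
    h, w = rec.height, rec.weight
    if h is not None and not (h > 0):
        problems.append(f"height {h!r} must be positive")
    if w is not None and not (w > 0):
        problems.append(f"weight {w!r} must be positive")
    if h and w and rec.bmi > 0:
        implied = w / (h / 100.0) ** 2
        # tolerate rounding in transcribed sources
        if abs(implied - rec.bmi) > 0.5:
            problems.append(
                f"bmi {rec.bmi:.2f} inconsistent with height/weight "
                f"(implies {implied:.2f})")
    return problems


def count_risk_alleles(dosages: Iterable[int]) -> int:
    """Total risk alleles carried over the three loci (0..6)."""
    dosages = tuple(dosages)
    for d in dosages:
        if d not in (0, 1, 2):
            raise ValidationError(f"dosage {d!r} outside {{0, 1, 2}}")
    return int(sum(dosages))


class CohortTable:
    """An ordered collection of subjects backed by a DataFrame.

    The frame always carries the canonical columns (COHORT_COLUMNS) in
    order; ``height``/``weight`` may be NaN when only BMI is known.
    """

    def __init__(self, subjects: pd.DataFrame, provenance: str = ""):
        df = subjects.copy()
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        # canonical columns first; extra (derived) columns are preserved
        extra = [c for c in df.columns if c not in COHORT_COLUMNS]
        df = df.loc[:, list(COHORT_COLUMNS) + extra].reset_index(drop=True)
        df["subject_id"] = df["subject_id"].astype(str)
        errors = _frame_problems(df)
        if errors:
            raise ValidationError(
                "invalid cohort rows:\n  " + "\n  ".join(errors[:20])
                + ("" if len(errors) <= 20 else f"\n  ... {len(errors) - 20} more"))
        for col in ("sex",) + DOSAGE_COLUMNS:
            df[col] = df[col].astype(int)
        for col in ("age", "height", "weight", "bmi"):
            df[col] = df[col].astype(float)
        self.df = df
        self.provenance = provenance

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        # equality is over the canonical schema; derived columns don't count
        return (isinstance(other, CohortTable)
                and self.df[list(COHORT_COLUMNS)].equals(
                    other.df[list(COHORT_COLUMNS)]))

    def __repr__(self) -> str:
        return (f"CohortTable({self.n_case} cases, {self.n_control} controls"
                + (f", {self.provenance!r}" if self.provenance else "") + ")")

    def records(self) -> Iterator[SubjectRecord]:
        for row in self.df.itertuples(index=False):
            yield SubjectRecord(
                subject_id=row.subject_id, status=row.status, sex=int(row.sex),
                age=float(row.age), bmi=float(row.bmi),
                height=None if pd.isna(row.height) else float(row.height),
                weight=None if pd.isna(row.weight) else float(row.weight),
                dosage_aspn=int(row.dosage_aspn), dosage_gdf5=int(row.dosage_gdf5),
                dosage_dvwa=int(row.dosage_dvwa))

    # -- derived views -------------------------------------------------
    @property
    def n_case(self) -> int:
        return int((self.df["status"] == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.df["status"] == "control").sum())

    @property
    def is_case(self) -> np.ndarray:
        """0/1 outcome vector in row order."""
        return (self.df["status"] == "case").to_numpy(dtype=int)

    @property
    def n_risk_alleles(self) -> np.ndarray:
        """Per-subject total risk-allele count, 0..6."""
        return self.df[list(DOSAGE_COLUMNS)].to_numpy().sum(axis=1)

    def with_columns(self, **cols) -> pd.DataFrame:
        """Model frame: canonical columns plus derived ones."""
        out = self.df.copy()
        out["n_risk_alleles"] = self.n_risk_alleles
        for k, v in cols.items():
            out[k] = v
        return out

    def subset(self, mask, provenance: str | None = None) -> "CohortTable":
        return CohortTable(self.df.loc[mask],
                           provenance or self.provenance)

    def require_both_groups(self):
        if self.n_case == 0 or self.n_control == 0:
            raise DegenerateInputError(
                "operation requires at least one case and one control "
                f"(have {self.n_case} cases, {self.n_control} controls)")
        return self


def _frame_problems(df: pd.DataFrame) -> list[str]:
    errors = []
    dup = df["subject_id"][df["subject_id"].duplicated()]
    for i, sid in dup.items():
        errors.append(f"row {i}: duplicate subject_id {sid!r}")
    for i, row in enumerate(df.itertuples(index=False)):
        probs = []
        if row.status not in ("case", "control"):
            probs.append(f"status {row.status!r}")
        if row.sex not in (1, 2):
            probs.append(f"sex {row.sex!r}")
        if pd.isna(row.age) or row.age < 0:
            probs.append(f"age {row.age!r}")
        if pd.isna(row.bmi) or row.bmi <= 0:
            probs.append(f"bmi {row.bmi!r}")
        for col in DOSAGE_COLUMNS:
            d = getattr(row, col)
            if pd.isna(d) or d not in (0, 1, 2):
                probs.append(f"{col} = {d!r} outside {{0, 1, 2}}")
        h, w = row.height, row.weight
        if not pd.isna(h) and h <= 0:
            probs.append(f"height {h!r}")
        if not pd.isna(w) and w <= 0:
            probs.append(f"weight {w!r}")
        if (not pd.isna(h) and not pd.isna(w) and h > 0 and not pd.isna(row.bmi)
                and abs(w / (h / 100.0) ** 2 - row.bmi) > 0.5):
            probs.append(f"bmi {row.bmi} inconsistent with height/weight")
        if probs:
            errors.append(f"row {i} (subject {row.subject_id!r}): "
                          + ", ".join(probs))
    return errors


# ---------------------------------------------------------------------
# aggregate tables


@dataclass
class GenotypeCountTable:
    """Per-locus genotype counts by group.

    ``counts[(locus, group)] = (homo, hetero, other)`` where *homo* is the
    risk-allele homozygote count and *other* collects non-carriers.
    """

    counts: dict[tuple[str, str], tuple[int, int, int]]

    def __post_init__(self):
        sizes: dict[str, set[int]] = {}
        for (locus, group), (a, b, c) in self.counts.items():
            if min(a, b, c) < 0:
                raise ValidationError(f"negative count at {locus}/{group}")
            sizes.setdefault(group, set()).add(a + b + c)
        for group, totals in sizes.items():
            if len(totals) > 1:
                raise ValidationError(
                    f"group {group!r} totals differ across loci: {sorted(totals)}")

    def group_size(self, group: str) -> int:
        for (_, g), (a, b, c) in self.counts.items():
            if g == group:
                return a + b + c
        raise KeyError(group)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"locus": locus, "group": group, "homo": a, "hetero": b, "other": c}
            for (locus, group), (a, b, c) in self.counts.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class RiskAlleleDistribution:
    """Subjects per total risk-allele count 0..6, by group."""

    case: np.ndarray
    control: np.ndarray

    def __post_init__(self):
        self.case = np.asarray(self.case, dtype=int)
        self.control = np.asarray(self.control, dtype=int)
        for name, arr in (("case", self.case), ("control", self.control)):
            if arr.shape != (7,):
                raise ValidationError(f"{name} counts must have 7 bins (0..6)")
            if (arr < 0).any():
                raise ValidationError(f"negative {name} count")

    @property
    def n_case(self) -> int:
        return int(self.case.sum())

    @property
    def n_control(self) -> int:
        return int(self.control.sum())

    def expand(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject (risk-allele count, case indicator) arrays."""
        scores = np.concatenate([
            np.repeat(np.arange(7), self.case),
            np.repeat(np.arange(7), self.control)])
        labels = np.concatenate([
            np.ones(self.n_case, dtype=int),
            np.zeros(self.n_control, dtype=int)])
        return scores, labels


@dataclass
class DemographicTable:
    """Reference sex-by-age-stratum population proportions.

    Strata are half-open ``[age_lo, age_hi)`` and must not overlap within
    a sex; proportions cover the whole table and sum to 1.
    """

    strata: pd.DataFrame  # columns: sex, age_lo, age_hi, proportion

    def __post_init__(self):
        df = self.strata.copy().reset_index(drop=True)
        need = {"sex", "age_lo", "age_hi", "proportion"}
        if not need.issubset(df.columns):
            raise FormatError(f"demographic table needs columns {sorted(need)}")
        if (df["proportion"] < 0).any():
            raise ValidationError("negative proportion")
        if abs(df["proportion"].sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"proportions sum to {df['proportion'].sum()!r}, expected 1")
        for sex, grp in df.groupby("sex"):
            g = grp.sort_values("age_lo")
            if (g["age_hi"].to_numpy() <= g["age_lo"].to_numpy()).any():
                raise ValidationError(f"empty age stratum for sex {sex}")
            if (g["age_lo"].to_numpy()[1:] < g["age_hi"].to_numpy()[:-1]).any():
                raise ValidationError(f"overlapping age strata for sex {sex}")
        self.strata = df

    @classmethod
    def read_csv(cls, path) -> "DemographicTable":
        return cls(pd.read_csv(path, comment="#"))

    def assign_stratum(self, sex: np.ndarray, age: np.ndarray) -> np.ndarray:
        """Index of the stratum containing each (sex, age), -1 if none."""
        out = np.full(len(sex), -1, dtype=int)
        for idx, row in self.strata.iterrows():
            hit = (sex == row["sex"]) & (age >= row["age_lo"]) & (age < row["age_hi"])
            out[hit] = idx
        return out


# ---------------------------------------------------------------------
# aggregation


def aggregate_genotype_counts(cohort: CohortTable) -> GenotypeCountTable:
    """Collapse a cohort to per-locus homo/hetero/other counts by group."""
    if len(cohort) == 0:
        raise DegenerateInputError("empty cohort")
    counts = {}
    for locus in LOCI:
        col = f"dosage_{locus}"
        for group in ("case", "control"):
            d = cohort.df.loc[cohort.df["status"] == group, col]
            counts[(locus, group)] = (
                int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum()))
    return GenotypeCountTable(counts)


def risk_allele_distribution(cohort: CohortTable) -> RiskAlleleDistribution:
    """Histogram of the per-subject risk-allele count, by group."""
    if len(cohort) == 0:
        raise DegenerateInputError("empty cohort")
    n = cohort.n_risk_alleles
    is_case = cohort.is_case.astype(bool)
    return RiskAlleleDistribution(
        case=np.bincount(n[is_case], minlength=7),
        control=np.bincount(n[~is_case], minlength=7))


# ---------------------------------------------------------------------
# I/O


def _load_dialect(dialect) -> dict:
    """Dialect: optional column-name mapping {file column -> schema column},
    as a dict or a YAML file path with a ``columns:`` mapping."""
    if dialect is None:
        return {}
    if isinstance(dialect, Mapping):
        return dict(dialect.get("columns", dialect))
    with open(dialect) as fh:
        cfg = yaml.safe_load(fh) or {}
    return dict(cfg.get("columns", cfg))


def read_cohort(path, dialect=None, provenance: str | None = None) -> CohortTable:
    """Read a cohort from delimited text (comma or tab, autodetected).

    ``dialect`` optionally renames file columns onto the canonical schema
    and may be a mapping or a YAML file with a ``columns:`` section.
    Rows violating domain invariants are rejected with row-level
    diagnostics (ValidationError).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such cohort file: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - re-raise as format error
        raise FormatError(f"could not parse {path}: {exc}") from exc
    mapping = _load_dialect(dialect)
    if mapping:
        df = df.rename(columns=mapping)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in COHORT_COLUMNS
               if c not in df.columns and c not in ("height", "weight")]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}")
    for opt in ("height", "weight"):
        if opt not in df.columns:
            df[opt] = np.nan
    df["status"] = (df["status"].astype(str).str.strip().str.lower()
                    .map(_STATUS_ALIASES).fillna(df["status"]))
    df["sex"] = (df["sex"].astype(str).str.strip().str.lower()
                 .map(_SEX_ALIASES).fillna(df["sex"]))
    return CohortTable(df, provenance or str(path))


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the canonical CSV schema; inverse of :func:`read_cohort`."""
    cohort.df[list(COHORT_COLUMNS)].to_csv(path, index=False)
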