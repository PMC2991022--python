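"""Published aggregate tables of the knee-OA case-control study.

The study's individual-level data are not deposited; what is public are
the aggregate tables — clinical summaries, per-locus genotype counts and
the risk-allele-count histogram for 933 cases and 1,225 controls.  They
are transcribed here verbatim and exposed through :func:`load_fixture`,
together with helpers that expand an aggregate table back into a cohort
whose margins reproduce it (dosage assignment within a group is
arbitrary, so only per-locus margins, not joint genotypes, are faithful).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .cohort import (CohortTable, DemographicTable, GenotypeCountTable,
                     RiskAlleleDistribution)

#: Clinical summary (per sex within group): subject counts and
#: mean (sd) age, height, weight, BMI — stored exactly as printed.
TABLE1_CLINICAL = {
    ("case", "female"): {"n": 757, "age": (71.6, 7.5), "height": (150.2, 6.1),
                         "weight": (56.2, 8.9), "bmi": (24.9, 12.7)},
    ("case", "male"): {"n": 176, "age": (72.9, 8.7), "height": (161.5, 6.8),
                       "weight": (63.8, 11.1), "bmi": (24.4, 11.0)},
    ("control", "female"): {"n": 924, "age": (70.3, 8.7), "height": (149.9, 6.1),
                            "weight": (51.5, 9.0), "bmi": (22.9, 12.1)},
    ("control", "male"): {"n": 301, "age": (66.2, 10.2), "height": (162.9, 7.5),
                          "weight": (63.8, 10.7), "bmi": (23.9, 8.75)},
}

#: Genotype counts (risk-homozygote, heterozygote, other) per locus/group.
TABLE2_GENOTYPES = {
    ("aspn", "case"): (9, 127, 797),
    ("aspn", "control"): (3, 147, 1075),
    ("gdf5", "case"): (566, 313, 54),
    ("gdf5", "control"): (684, 461, 80),
    ("dvwa", "case"): (369, 428, 136),
    ("dvwa", "control"): (397, 600, 228),
}

#: Subjects per total risk-allele count 0..6.
TABLE5_RISK_ALLELES = {
    "case": (6, 61, 224, 357, 252, 30, 3),
    "control": (9, 121, 332, 485, 254, 24, 0),
}

N_CASE, N_CONTROL = 933, 1225


def load_fixture(name: str):
    """Return a packaged aggregate: ``table1`` (dict), ``table2``
    (GenotypeCountTable), ``table5`` (RiskAlleleDistribution) or
    ``demo_example`` (approximate DemographicTable for demos)."""
    if name == "table1":
        return {k: dict(v) for k, v in TABLE1_CLINICAL.items()}
    if name == "table2":
        return GenotypeCountTable(dict(TABLE2_GENOTYPES))
    if name == "table5":
        return RiskAlleleDistribution(case=TABLE5_RISK_ALLELES["case"],
                                      control=TABLE5_RISK_ALLELES["control"])
    if name == "demo_example":
        ref = resources.files("kneeoa.data") / "elderly_demographics_synthetic.csv"
        with resources.as_file(ref) as path:
            return DemographicTable.read_csv(path)
    raise KeyError(f"unknown fixture {name!r}; "
                   "choose from table1, table2, table5, demo_example")


def cohort_from_genotype_counts(table: GenotypeCountTable,
                                provenance: str = "genotype-count expansion",
                                ) -> CohortTable:
    """Cohort whose per-locus genotype margins reproduce ``table``.

    Within a group each locus column is filled independently
    (homo block, hetero block, other block), so joint genotypes are a
    deterministic artifact; only single-locus margins are meaningful.
    """
    frames = []
    for group in ("case", "control"):
        size = table.group_size(group)
        cols = {}
        for locus in ("aspn", "gdf5", "dvwa"):
            homo, het, _ = table.counts[(locus, group)]
            d = np.zeros(size, dtype=int)
            d[:homo] = 2
            d[homo:homo + het] = 1
            cols[f"dosage_{locus}"] = d
        frames.append(pd.DataFrame({
            "subject_id": [f"{group}{i:05d}" for i in range(size)],
            "status": group, "sex": 2, "age": 70.0,
            "height": np.nan, "weight": np.nan, "bmi": 23.0, **cols}))
    return CohortTable(pd.concat(frames, ignore_index=True), provenance)


def cohort_from_distribution(dist: RiskAlleleDistribution,
                             provenance: str = "risk-allele expansion",
                             ) -> CohortTable:
    """Minimal cohort carrying the per-subject risk-allele counts of
    ``dist`` (dosages packed greedily into the three 0..2 columns;
    clinical columns are constant placeholders)."""
    scores, labels = dist.expand()
    d1 = np.minimum(scores, 2)
    d2 = np.minimum(scores - d1, 2)
    d3 = scores - d1 - d2
    status = np.where(labels == 1, "case", "control")
    df = pd.DataFrame({
        "subject_id": [f"s{i:05d}" for i in range(len(scores))],
        "status": status, "sex": 2, "age": 70.0,
        "height": np.nan, "weight": np.nan, "bmi": 23.0,
        "dosage_aspn": d1, "dosage_gdf5": d2, "dosage_dvwa": d3})
    return CohortTable(df, provenance)
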