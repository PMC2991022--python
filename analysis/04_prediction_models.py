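"""Fit and compare the genetic / clinical / combined prediction models.

Runs on a synthetic cohort (the saved output of 01_simulate_cohort.py
when present, else regenerated): fits the genetic-only, combined and
clinical-only logistic models, reports in-sample AUCs, the nested
likelihood-ratio comparison of combined vs clinical, stepwise variable
selection, a one-third holdout validation and 10-fold cross-validation.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import kneeoa as k


def load_or_generate(path: Path, seed: int) -> k.CohortTable:
    if path.exists():
        return k.read_cohort(path)
    return k.generate_cohort(k.GeneratorParams(seed=seed))


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path,
                    default=Path("results/synthetic_cohort.csv"))
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", type=Path,
                    default=Path("results/prediction_models.json"))
    args = ap.parse_args()

    cohort = load_or_generate(args.cohort, args.seed)
    print(f"cohort: {cohort.n_case} cases / {cohort.n_control} controls "
          f"({cohort.provenance})")

    report = {}
    fits = {}
    for spec in (k.MODEL_I, k.MODEL_II, k.MODEL_III):
        fit = k.fit_model(cohort, spec)
        fits[spec.name] = fit
        auc = k.auc(k.scores_for(fit, cohort), cohort.is_case)
        report[spec.name] = {
            "terms": list(spec.terms),
            "coefficients": {t: round(v, 4)
                             for t, v in fit.coefficients.items()},
            "auc_in_sample": round(auc, 3),
        }
        print(f"{spec.name}: AUC {auc:.3f}  "
              + "  ".join(f"{t}={v:+.3f}"
                          for t, v in fit.coefficients.items()))

    stat, df, p = k.likelihood_ratio_compare(fits["MODEL_III"],
                                             fits["MODEL_II"])
    report["lrt_combined_vs_clinical"] = {"statistic": round(stat, 3),
                                          "df": df, "p": p}
    print(f"combined vs clinical LRT: chi2({df}) = {stat:.2f}, p = {p:.3g}")

    selected = k.stepwise_select(
        cohort, ["n_risk_alleles", "gen", "age", "bmi", "height", "weight"])
    report["stepwise_terms"] = list(selected.terms)
    print(f"stepwise selection kept: {', '.join(selected.terms)}")

    rng = np.random.default_rng(args.seed)
    mask = rng.random(len(cohort)) < 1 / 3
    auc_train, auc_hold = k.split_validation(cohort, mask, k.MODEL_II)
    report["validation"] = {"auc_train": round(auc_train, 3),
                            "auc_holdout": round(auc_hold, 3)}
    print(f"1/3 holdout: train AUC {auc_train:.3f}, "
          f"holdout AUC {auc_hold:.3f}")

    cv = k.cross_validate(cohort, k.MODEL_II, k=10, seed=args.seed)
    report["cv10_auc"] = round(cv, 3)
    print(f"10-fold CV AUC (combined model): {cv:.3f}")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(report, indent=2) + "\n")
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
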