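#!/usr/bin/env python
"""Desk checks against the published clinical cohort summaries.

From the shipped per-arm means of the 10-patient clinical CyberKnife cohort
(the study the synthetic phantoms emulate) this recomputes: the headline
percent reductions of the double plan (lung/heart/esophagus gEUD, lung
V5/V20), the homogeneity-index cells from mean Dmax / 50 Gy, the new
conformity index from mean CI and coverage, and the constraint audit of the
published OAR means.  Writes results/clinical_summary_checks.csv.
"""

from pathlib import Path

import pandas as pd

from sbrteval import (
    audit_metrics,
    homogeneity_index,
    load_clinical_summary,
    load_constraint_specs,
    n_failures,
    percent_reduction,
)


def mean(df, structure, metric, col):
    return float(df[(df.structure == structure) & (df.metric == metric)].iloc[0][col])


def main() -> None:
    eud = load_clinical_summary("eud")
    oar = load_clinical_summary("oar")
    ptv = load_clinical_summary("ptv")
    rows = []

    for df, structure, metric, label in [
        (eud, "lungs", "eud", "combined-lung gEUD"),
        (eud, "heart", "eud", "heart gEUD"),
        (eud, "esophagus", "eud", "esophagus gEUD"),
        (oar, "lungs", "v_pct@5", "lung V5"),
        (oar, "lungs", "v_pct@20", "lung V20"),
    ]:
        s = mean(df, structure, metric, "plan_s_mean")
        d = mean(df, structure, metric, "plan_d_mean")
        rows.append({"check": f"percent reduction, {label}",
                     "value": round(percent_reduction(s, d), 2)})

    for structure in ("ptv1", "ptv2", "ptv12"):
        for arm in ("plan_s_mean", "plan_d_mean"):
            hi = homogeneity_index(mean(ptv, structure, "d_max", arm), 50.0)
            rows.append({"check": f"HI from mean Dmax, {structure} {arm[5]}",
                         "value": round(hi, 2),
                         "published": mean(ptv, structure, "hi", arm)})

    ci = mean(ptv, "ptv1", "ci", "plan_s_mean")
    cov = mean(ptv, "ptv1", "coverage", "plan_s_mean")
    rows.append({"check": "nCI from mean CI / coverage, ptv1 s",
                 "value": round(ci / (cov / 100.0), 2),
                 "published": mean(ptv, "ptv1", "nci", "plan_s_mean")})

    specs = load_constraint_specs()
    for col, arm in (("plan_s_mean", "s"), ("plan_d_mean", "d")):
        metrics = {(r.structure, r.metric): float(getattr(r, col))
                   for r in oar.itertuples()}
        rows.append({"check": f"constraint violations on published OAR means, arm {arm}",
                     "value": n_failures(audit_metrics(metrics, specs))})

    df = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    df.to_csv("results/clinical_summary_checks.csv", index=False)
    print(df.to_string(index=False))
    print("wrote results/clinical_summary_checks.csv")


if __name__ == "__main__":
    main()
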