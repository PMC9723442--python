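"""Constraint auditing and paired Plan S vs Plan D cohort comparison.

A constraint is a (structure, metric-descriptor, comparator, threshold)
tuple.  Metric descriptors are resolved by the DVH and plan-quality modules:

    d_max | d_mean | d_min            voxel-exact dose statistics (Gy)
    v_pct@X                           % of volume receiving >= X Gy
    v_cc@X / v_below_cc@X             cc receiving >= X Gy / < X Gy
    d_cc@X                            min dose to the hottest X cc (Gy)
    coverage                          % of volume inside the prescription isodose
    pidl                              100 * PD / Dmax (%)
    eud                               gEUD (Gy), radiobio module

Comparators ``<  >  <=  >=`` are strict as written; ``~`` is a soft band
(pass within ``band`` of the threshold, default 10), used for the ~70 %
prescription-isodose-line objective.  A constraint whose structure or metric
is absent from the inputs yields a "not evaluable" result rather than a
failure or a crash.

The cohort comparison mirrors the clinical-study table layout: per metric,
mean +/- sample SD per arm, the percent reduction of means, and a two-sided
paired t-test (p < 0.05 flagged significant, no multiple-testing correction;
the report records how many tests were run).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import dvh as _dvh
from . import quality as _quality
from . import radiobio as _radiobio
from .grid import PlanDose, StructureSet

__all__ = [
    "ConstraintSpec",
    "ConstraintResult",
    "PairedTResult",
    "load_constraint_specs",
    "compute_metric",
    "evaluate_constraints",
    "audit_metrics",
    "n_failures",
    "paired_t_test",
    "cohort_report",
    "load_clinical_summary",
]

_PTV_ALIASES = ("ptv1", "ptv2", "ptv12")
_COMPARATORS = ("<", ">", "<=", ">=", "~")


@dataclass(frozen=True)
class ConstraintSpec:
    structure: str
    metric: str
    cmp: str
    threshold: float
    units: str = ""
    band: float = 10.0  # only used by the "~" comparator

    def __post_init__(self) -> None:
        if self.cmp not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.cmp!r}")
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def label(self) -> str:
        return f"{self.structure} {self.metric} {self.cmp} {self.threshold}{self.units}"


@dataclass(frozen=True)
class ConstraintResult:
    """Outcome of one constraint: ``passed`` is None when not evaluable."""

    spec: ConstraintSpec
    achieved: float | None
    passed: bool | None
    margin: float | None  # signed toward pass: positive = pass with room
    note: str = ""


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    n: int
    defined: bool = True
    note: str = ""


def load_constraint_specs(path=None) -> list[ConstraintSpec]:
    """Load the shipped clinical constraint table, or a user YAML file."""
    if path is None:
        text = resources.files("sbrteval").joinpath("data/constraints.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    entries = yaml.safe_load(text)
    return [
        ConstraintSpec(
            structure=e["structure"],
            metric=str(e["metric"]),
            cmp=e["cmp"],
            threshold=float(e["threshold"]),
            units=e.get("units", ""),
            band=float(e.get("band", 10.0)),
        )
        for e in entries
    ]


def _apply_comparator(
    cmp: str, achieved: float, threshold: float, band: float
) -> tuple[bool, float]:
    if cmp == "<":
        return achieved < threshold, threshold - achieved
    if cmp == "<=":
        return achieved <= threshold, threshold - achieved
    if cmp == ">":
        return achieved > threshold, achieved - threshold
    if cmp == ">=":
        return achieved >= threshold, achieved - threshold
    # "~": soft band around the objective
    return abs(achieved - threshold) <= band, band - abs(achieved - threshold)


def _parse_descriptor(descriptor: str) -> tuple[str, float | None]:
    if "@" in descriptor:
        base, _, arg = descriptor.partition("@")
        return base, float(arg)
    return descriptor, None


def compute_metric(
    plan: PlanDose,
    structures: StructureSet,
    structure: str,
    descriptor: str,
    eud_table: dict | None = None,
) -> float:
    """Resolve one metric descriptor for one structure on one plan dose."""
    mask = structures[structure]
    dose = plan.grid
    base, arg = _parse_descriptor(descriptor)
    if base in ("d_max", "d_mean", "d_min"):
        d_min, d_mean, d_max = _dvh.dose_stats(dose, mask)
        return {"d_min": d_min, "d_mean": d_mean, "d_max": d_max}[base]
    if base == "v_pct":
        return _dvh.v_dose_pct(dose, mask, arg)
    if base == "v_cc":
        return _dvh.v_dose_cc(dose, mask, arg)
    if base == "v_below_cc":
        return _dvh.v_below_cc(dose, mask, arg)
    if base == "d_cc":
        return _dvh.d_at_cc(dose, mask, arg)
    if base == "d_pct":
        return _dvh.d_at_pct(dose, mask, arg)
    if base == "coverage":
        return _dvh.coverage(dose, mask, plan.prescription_dose_gy)
    if base == "pidl":
        _, _, d_max = _dvh.dose_stats(dose, mask)
        return _quality.pidl(d_max, plan.prescription_dose_gy)
    if base == "eud":
        params = _radiobio.eud_params_for(
            structure, eud_table, n_fractions=plan.n_fractions
        )
        cdvh = _dvh.compute_cumulative_dvh(dose, mask)
        return _radiobio.geud(cdvh, params).eud_gy
    raise ValueError(f"unresolvable metric descriptor {descriptor!r}")


def _expand_structures(spec: ConstraintSpec, available) -> list[str]:
    if spec.structure == "ptv":
        return [s for s in _PTV_ALIASES if s in available]
    return [spec.structure] if spec.structure in available else []


def evaluate_constraints(
    plan: PlanDose,
    structures: StructureSet,
    specs: Sequence[ConstraintSpec],
    eud_table: dict | None = None,
) -> list[ConstraintResult]:
    """Audit one plan against a constraint table.

    The pseudo-structure ``ptv`` expands to each of ptv1/ptv2/ptv12 present.
    Missing structures yield per-constraint "not evaluable" results.
    """
    results: list[ConstraintResult] = []
    for spec in specs:
        targets = _expand_structures(spec, structures)
        if not targets:
            results.append(
                ConstraintResult(
                    spec, None, None, None, note=f"structure '{spec.structure}' absent"
                )
            )
            continue
        for structure in targets:
            achieved = compute_metric(plan, structures, structure, spec.metric, eud_table)
            passed, margin = _apply_comparator(
                spec.cmp, achieved, spec.threshold, spec.band
            )
            results.append(
                ConstraintResult(spec, achieved, passed, margin, note=structure)
            )
    return results


def audit_metrics(
    metrics: Mapping[tuple[str, str], float], specs: Sequence[ConstraintSpec]
) -> list[ConstraintResult]:
    """Audit a precomputed {(structure, descriptor): value} table.

    Used when only summary metrics are available (e.g. a published cohort
    table); constraints whose metric is not in the table are marked not
    evaluable.
    """
    available = {s for s, _ in metrics}
    results: list[ConstraintResult] = []
    for spec in specs:
        targets = _expand_structures(spec, available)
        evaluable = [(s, (s, spec.metric)) for s in targets if (s, spec.metric) in metrics]
        if not evaluable:
            results.append(
                ConstraintResult(spec, None, None, None, note="metric not available")
            )
            continue
        for structure, key in evaluable:
            achieved = float(metrics[key])
            passed, margin = _apply_comparator(
                spec.cmp, achieved, spec.threshold, spec.band
            )
            results.append(
                ConstraintResult(spec, achieved, passed, margin, note=structure)
            )
    return results


def n_failures(results: Sequence[ConstraintResult]) -> int:
    return sum(1 for r in results if r.passed is False)


def paired_t_test(pairs: Sequence[tuple[float, float]]) -> PairedTResult:
    """Two-sided paired t-test on differences (s - d).

    All-equal differences (zero variance) make t undefined; this is reported
    as a flagged result, never as +/-inf.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (plan_s, plan_d) pairs")
    n = arr.shape[0]
    diffs = arr[:, 0] - arr[:, 1]
    if float(np.std(diffs, ddof=1)) == 0.0:
        return PairedTResult(
            t=math.nan, df=n - 1, p=math.nan, n=n, defined=False,
            note="all differences equal; t undefined",
        )
    res = stats.ttest_rel(arr[:, 0], arr[:, 1])
    return PairedTResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue), n=n)


def cohort_report(
    metrics_s: Mapping[str, Mapping[tuple[str, str], float]],
    metrics_d: Mapping[str, Mapping[tuple[str, str], float]],
) -> pd.DataFrame:
    """Paired per-metric comparison of the two arms over a cohort.

    ``metrics_s``/``metrics_d`` map patient id -> {(structure, metric): value}.
    Returns a tidy frame (one row per structure/metric) with mean +/- sample
    SD per arm, percent reduction of means, t, df, p and a significance flag;
    ``df.attrs["n_tests"]`` records the number of t-tests performed.
    """
    missing = sorted(set(metrics_s) ^ set(metrics_d))
    if missing:
        raise ValueError(f"arms do not cover the same patients; mismatched: {missing}")
    patients = sorted(metrics_s)
    keys = list(dict.fromkeys(k for p in patients for k in metrics_s[p]))
    rows = []
    n_tests = 0
    for key in keys:
        vs = np.array([metrics_s[p][key] for p in patients], dtype=np.float64)
        vd = np.array([metrics_d[p][key] for p in patients], dtype=np.float64)
        mean_s, mean_d = float(vs.mean()), float(vd.mean())
        tres = paired_t_test(list(zip(vs, vd)))
        if tres.defined:
            n_tests += 1
        rows.append(
            {
                "structure": key[0],
                "metric": key[1],
                "mean_s": mean_s,
                "sd_s": float(vs.std(ddof=1)),
                "mean_d": mean_d,
                "sd_d": float(vd.std(ddof=1)),
                "pct_reduction": (
                    _radiobio.percent_reduction(mean_s, mean_d) if mean_s != 0 else math.nan
                ),
                "t": tres.t,
                "df": tres.df,
                "p": tres.p,
                "significant": bool(tres.defined and tres.p < 0.05),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_tests"] = n_tests
    return df


def format_report(df: pd.DataFrame) -> pd.DataFrame:
    """Side-by-side presentation: means/SDs at 2 dp, p at 3 dp."""
    out = pd.DataFrame(
        {
            "structure": df["structure"],
            "metric": df["metric"],
            "plan_s": [f"{m:.2f} ± {s:.2f}" for m, s in zip(df.mean_s, df.sd_s)],
            "plan_d": [f"{m:.2f} ± {s:.2f}" for m, s in zip(df.mean_d, df.sd_d)],
            "pct_reduction": df["pct_reduction"].round(2),
            "p": df["p"].round(3),
        }
    )
    return out


def load_clinical_summary(which: str) -> pd.DataFrame:
    """Shipped mean +/- SD summaries of the 10-patient clinical CyberKnife
    cohort (both arms) that the synthetic phantoms emulate.

    ``which`` is one of ``"ptv"``, ``"oar"``, ``"eud"``.
    """
    names = {
        "ptv": "clinical_ptv_summary.csv",
        "oar": "clinical_oar_summary.csv",
        "eud": "clinical_eud_summary.csv",
    }
    if which not in names:
        raise ValueError(f"unknown summary {which!r}; expected one of {sorted(names)}")
    text = (
        resources.files("sbrteval")
        .joinpath(f"data/reference/{names[which]}")
        .read_text()
    )
    return pd.read_csv(StringIO(text))
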