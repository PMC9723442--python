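"""End-to-end paired-plan study: generate/evaluate/compare, with reports.

``run_compare`` drives the whole pipeline on a synthetic cohort: for every
patient and arm it computes cumulative DVHs, the DVH metric families, the
conformity/homogeneity/gradient indices, gEUDs and the constraint audit,
then produces the paired cohort comparison.  Outputs are a tidy CSV and a
nested JSON report; every output embeds the configuration hash and master
seed, and a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    ConstraintResult,
    cohort_report,
    evaluate_constraints,
    load_constraint_specs,
    n_failures,
)
from .dvh import compute_cumulative_dvh, dose_stats
from .grid import PlanDose, StructureSet
from .phantom import DoseModelSpec, PatientCase, PhantomSpec, generate_cohort
from .quality import conformity_indices
from .radiobio import default_eud_params, eud_params_for, geud

__all__ = [
    "RunConfig",
    "PatientEvaluation",
    "CompareResult",
    "evaluate_plan",
    "run_compare",
    "PTV_METRICS",
    "OAR_METRICS",
    "EUD_STRUCTURES",
]

#: Metric descriptors reported per PTV (the target-table layout).
PTV_METRICS = ("coverage", "d_max", "d_min", "d_mean", "ci", "nci", "hi", "gi")

#: Metric descriptors reported per OAR (the OAR-table layout).
OAR_METRICS = {
    "lungs": ("d_mean", "v_pct@5", "v_pct@20", "v_below_cc@12.5", "v_below_cc@13.5"),
    "heart": ("d_mean", "d_cc@15"),
    "cord": ("d_mean", "d_cc@0.25", "d_cc@1.2"),
    "trachea": ("d_mean", "d_max"),
    "bronchus": ("d_mean", "d_max"),
    "trachea_bronchus": ("d_mean", "d_max", "d_cc@4"),
    "esophagus": ("d_mean", "d_max", "d_cc@5"),
}

#: Structures with validated gEUD parameters (trachea/bronchus excluded).
EUD_STRUCTURES = ("ptv1", "ptv2", "ptv12", "lungs", "heart", "cord", "esophagus")


@dataclass(frozen=True)
class RunConfig:
    n_patients: int = 10
    master_seed: int = 1
    prescription_dose_gy: float = 50.0
    n_fractions: int = 5
    out_dir: str = "results"
    dvh_bin_width_gy: float = 0.01
    constraint_file: str | None = None
    eud_param_file: str | None = None
    gradient_reference: str = "prescription"  # or "max"
    tumor_a_negative: bool = False

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PatientEvaluation:
    patient_id: str
    arm: str
    metrics: dict[tuple[str, str], float]
    constraints: list[ConstraintResult] = field(default_factory=list)

    @property
    def n_constraint_failures(self) -> int:
        return n_failures(self.constraints)


@dataclass
class CompareResult:
    config: RunConfig
    evaluations: list[PatientEvaluation]
    report: pd.DataFrame
    csv_path: Path | None = None
    json_path: Path | None = None

    @property
    def total_constraint_failures(self) -> int:
        return sum(e.n_constraint_failures for e in self.evaluations)


def evaluate_plan(
    plan: PlanDose,
    structures: StructureSet,
    eud_table: dict | None = None,
    gradient_reference: str = "prescription",
) -> dict[tuple[str, str], float]:
    """All reported metrics of one plan as {(structure, descriptor): value}."""
    from .cohort import compute_metric  # local import avoids a module cycle

    metrics: dict[tuple[str, str], float] = {}
    pd_gy = plan.prescription_dose_gy
    body = structures["body"]
    for name in ("ptv1", "ptv2", "ptv12"):
        if name not in structures:
            continue
        cs = conformity_indices(
            plan.grid, structures[name], body, pd_gy, half_of=gradient_reference
        )
        d_min, d_mean, d_max = dose_stats(plan.grid, structures[name])
        metrics[(name, "coverage")] = cs.coverage_pct
        metrics[(name, "d_max")] = d_max
        metrics[(name, "d_min")] = d_min
        metrics[(name, "d_mean")] = d_mean
        metrics[(name, "ci")] = cs.ci
        metrics[(name, "nci")] = cs.nci
        metrics[(name, "hi")] = cs.hi
        metrics[(name, "gi")] = cs.gi
        metrics[(name, "pidl")] = cs.pidl_pct
    for name, descriptors in OAR_METRICS.items():
        if name not in structures:
            continue
        for desc in descriptors:
            metrics[(name, desc)] = compute_metric(plan, structures, name, desc)
    for name in EUD_STRUCTURES:
        if name not in structures:
            continue
        params = eud_params_for(name, eud_table, n_fractions=plan.n_fractions)
        cdvh = compute_cumulative_dvh(plan.grid, structures[name])
        metrics[(name, "eud")] = geud(cdvh, params).eud_gy
    return metrics


def _json_safe(metrics: dict[tuple[str, str], float]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for (structure, metric), value in metrics.items():
        out.setdefault(structure, {})[metric] = value
    return out


def run_compare(config: RunConfig, write_files: bool = True) -> CompareResult:
    """Run the full synthetic paired-plan study defined by ``config``."""
    cohort = generate_cohort(
        n=config.n_patients,
        master_seed=config.master_seed,
        dose_spec=DoseModelSpec(
            prescription_dose_gy=config.prescription_dose_gy,
            n_fractions=config.n_fractions,
        ),
    )
    return compare_cohort(cohort, config, write_files=write_files)


def compare_cohort(
    cohort: list[PatientCase], config: RunConfig, write_files: bool = True
) -> CompareResult:
    """Evaluate both arms of an existing cohort and build the paired report."""
    specs = load_constraint_specs(config.constraint_file)
    eud_table = default_eud_params(
        n_fractions=config.n_fractions,
        tumor_a_negative=config.tumor_a_negative,
        path=config.eud_param_file,
    )
    evaluations: list[PatientEvaluation] = []
    metrics_s: dict[str, dict] = {}
    metrics_d: dict[str, dict] = {}
    for case in cohort:
        plans = {"S": case.plan_s, "D": case.plan_d}
        for arm, plan in plans.items():
            m = evaluate_plan(
                plan,
                case.phantom.structures,
                eud_table,
                gradient_reference=config.gradient_reference,
            )
            audit = evaluate_constraints(plan, case.phantom.structures, specs, eud_table)
            evaluations.append(PatientEvaluation(case.patient_id, arm, m, audit))
            (metrics_s if arm == "S" else metrics_d)[case.patient_id] = m
    report = cohort_report(metrics_s, metrics_d)
    result = CompareResult(config, evaluations, report)
    if write_files:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.csv_path = out_dir / "cohort_comparison.csv"
        report.to_csv(result.csv_path, index=False)
        result.json_path = out_dir / "cohort_comparison.json"
        payload = {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "config_hash": config.hash(),
            "master_seed": config.master_seed,
            "n_t_tests": report.attrs.get("n_tests", 0),
            "patients": [
                {
                    "patient_id": e.patient_id,
                    "arm": e.arm,
                    "metrics": _json_safe(e.metrics),
                    "constraint_failures": e.n_constraint_failures,
                    "constraints": [
                        {
                            "constraint": r.spec.label(),
                            "structure": r.note,
                            "achieved": r.achieved,
                            "passed": r.passed,
                            "margin": r.margin,
                        }
                        for r in e.constraints
                    ],
                }
                for e in evaluations
            ],
            "comparison": report.to_dict(orient="records"),
        }
        result.json_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return result
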