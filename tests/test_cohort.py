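"""Constraint auditing and the paired cohort comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from sbrteval import (
    ConstraintSpec,
    audit_metrics,
    cohort_report,
    load_constraint_specs,
    n_failures,
    paired_t_test,
)
from sbrteval.cohort import compute_metric, evaluate_constraints
from sbrteval.grid import PlanDose, StructureSet
from helpers import full_mask, make_grid, mask_on


class TestConstraintAudit:
    def test_lung_v20_passes_with_margin(self):
        spec = ConstraintSpec("lungs", "v_pct@20", "<", 25.0, "%")
        res = audit_metrics({("lungs", "v_pct@20"): 8.01}, [spec])[0]
        assert res.passed is True
        assert res.margin == pytest.approx(16.99)

    def test_strict_inequality_at_boundary_fails(self):
        spec = ConstraintSpec("cord", "d_max", "<", 27.0, "Gy")
        res = audit_metrics({("cord", "d_max"): 27.0}, [spec])[0]
        assert res.passed is False
        assert res.margin == 0.0

    def test_failed_constraint_has_negative_margin(self):
        spec = ConstraintSpec("heart", "d_mean", "<", 12.0, "Gy")
        res = audit_metrics({("heart", "d_mean"): 12.5}, [spec])[0]
        assert res.passed is False
        assert res.margin == pytest.approx(-0.5)

    def test_soft_band_comparator(self):
        spec = ConstraintSpec("ptv", "pidl", "~", 70.0, "%", band=10.0)
        assert audit_metrics({("ptv1", "pidl"): 66.0}, [spec])[0].passed is True
        assert audit_metrics({("ptv1", "pidl"): 81.0}, [spec])[0].passed is False

    def test_missing_metric_not_evaluable(self):
        spec = ConstraintSpec("heart", "v_cc@32", "<", 15.0, "cc")
        res = audit_metrics({("heart", "d_mean"): 3.0}, [spec])[0]
        assert res.passed is None and res.achieved is None
        assert n_failures([res]) == 0

    def test_shipped_table_loads_and_expands_ptv(self):
        specs = load_constraint_specs()
        assert any(s.structure == "ptv" and s.metric == "coverage" for s in specs)
        res = audit_metrics(
            {("ptv1", "coverage"): 96.0, ("ptv12", "coverage"): 97.0}, specs
        )
        evaluated = [r for r in res if r.achieved is not None]
        assert {r.note for r in evaluated} == {"ptv1", "ptv12"}

    def test_unresolvable_descriptor_names_it(self):
        g = make_grid(np.full((4, 4, 4), 10.0))
        ss = StructureSet({"body": full_mask(g, "body")})
        plan = PlanDose(g)
        with pytest.raises(ValueError, match="bogus@3"):
            evaluate_constraints(plan, ss, [ConstraintSpec("body", "bogus@3", "<", 1.0)])

    def test_missing_structure_is_not_a_crash(self):
        g = make_grid(np.full((4, 4, 4), 10.0))
        ss = StructureSet({"body": full_mask(g, "body")})
        res = evaluate_constraints(
            PlanDose(g), ss, [ConstraintSpec("heart", "d_max", "<", 38.0, "Gy")]
        )
        assert res[0].passed is None

    def test_compute_metric_descriptors_agree_with_direct_calls(self):
        rng = np.random.default_rng(2)
        g = make_grid(rng.uniform(0, 60, size=(8, 8, 8)), spacing=(5, 5, 5))
        ss = StructureSet({"body": full_mask(g, "body")})
        plan = PlanDose(g, prescription_dose_gy=50.0)
        member = g.values.ravel()
        assert compute_metric(plan, ss, "body", "d_max") == member.max()
        assert compute_metric(plan, ss, "body", "v_pct@20") == pytest.approx(
            100 * np.count_nonzero(member >= 20) / member.size
        )
        assert compute_metric(plan, ss, "body", "coverage") == pytest.approx(
            100 * np.count_nonzero(member >= 50) / member.size
        )
        assert compute_metric(plan, ss, "body", "pidl") == pytest.approx(
            100 * 50.0 / member.max()
        )


class TestPairedT:
    def test_antisymmetry(self):
        pairs = [(3.0, 1.0), (5.0, 2.5), (4.0, 4.5), (2.0, 1.0)]
        fwd = paired_t_test(pairs)
        rev = paired_t_test([(d, s) for s, d in pairs])
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)

    def test_shift_and_scale_invariance(self):
        pairs = [(3.0, 1.0), (5.0, 2.5), (2.0, 1.0)]
        base = paired_t_test(pairs)
        shifted = paired_t_test([(s + 10, d + 10) for s, d in pairs])
        scaled = paired_t_test([(3 * s, 3 * d) for s, d in pairs])
        assert shifted.t == pytest.approx(base.t, rel=1e-12)
        assert scaled.t == pytest.approx(base.t, rel=1e-12)

    def test_all_equal_differences_flagged_undefined(self):
        res = paired_t_test([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert not res.defined
        assert math.isnan(res.t) and math.isnan(res.p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([(1.0, 2.0)])


class TestCohortReport:
    def toy_metrics(self):
        s = {
            "p1": {("lungs", "d_mean"): 6.0, ("heart", "d_mean"): 4.0},
            "p2": {("lungs", "d_mean"): 8.0, ("heart", "d_mean"): 2.0},
        }
        d = {
            "p1": {("lungs", "d_mean"): 5.0, ("heart", "d_mean"): 3.5},
            "p2": {("lungs", "d_mean"): 7.0, ("heart", "d_mean"): 1.5},
        }
        return s, d

    def test_hand_computed_means_and_reduction(self):
        s, d = self.toy_metrics()
        df = cohort_report(s, d).set_index(["structure", "metric"])
        lungs = df.loc[("lungs", "d_mean")]
        assert lungs.mean_s == pytest.approx(7.0)
        assert lungs.sd_s == pytest.approx(np.std([6, 8], ddof=1))
        assert lungs.mean_d == pytest.approx(6.0)
        assert lungs.pct_reduction == pytest.approx(100 * (7 - 6) / 7)
        # differences are exactly [1, 1]: zero variance -> flagged, not inf
        assert not np.isfinite(lungs.t)

    def test_identical_arms_no_significance(self):
        s, _ = self.toy_metrics()
        df = cohort_report(s, s)
        assert (df["pct_reduction"] == 0).all()
        assert not df["significant"].any()

    def test_patient_mismatch_lists_missing(self):
        s, d = self.toy_metrics()
        del d["p2"]
        with pytest.raises(ValueError, match="p2"):
            cohort_report(s, d)

    def test_report_csv_roundtrip_identical(self, tmp_path):
        s, d = self.toy_metrics()
        df = cohort_report(s, d)
        path = tmp_path / "report.csv"
        df.to_csv(path, index=False)
        back = pd.read_csv(path)
        for col in ("mean_s", "sd_s", "mean_d", "sd_d", "pct_reduction"):
            np.testing.assert_array_equal(back[col].to_numpy(), df[col].to_numpy())
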