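"""DVH computation and metric extraction against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sbrteval import (
    compute_cumulative_dvh,
    coverage,
    d_at_cc,
    d_at_pct,
    dose_stats,
    v_below_cc,
    v_dose_cc,
    v_dose_pct,
)
from sbrteval.dvh import (
    EmptyStructureError,
    dvh_dose_at_cc,
    dvh_max_dose,
    dvh_mean_dose,
    dvh_volume_at,
)
from helpers import full_mask, make_grid, mask_on, random_dose_and_mask


class TestCumulativeDVH:
    def test_uniform_dose_is_step_function(self):
        # 1000 voxels of 0.1 cc: a uniform 10 Gy dose over 100 cc
        g = make_grid(np.full((10, 10, 10), 10.0), spacing=(10, 10, 1))
        mask = full_mask(g)
        dvh = compute_cumulative_dvh(g, mask, bin_width=0.5)
        total = mask.volume_cc
        assert total == pytest.approx(100.0)
        below = dvh.bin_edges <= 10.0
        np.testing.assert_allclose(dvh.volume_cc[below], total)
        np.testing.assert_allclose(dvh.volume_cc[~below], 0.0)

    def test_two_level_dose_steps(self):
        g = make_grid([4.0] * 5 + [8.0] * 5)
        mask = full_mask(g)
        dvh = compute_cumulative_dvh(g, mask, bin_width=1.0)
        total = mask.volume_cc
        vol_at = dict(zip(dvh.bin_edges, dvh.volume_cc))
        assert vol_at[0.0] == pytest.approx(total)
        assert vol_at[4.0] == pytest.approx(total)  # closed comparison at 4 Gy
        assert vol_at[5.0] == pytest.approx(total / 2)
        assert vol_at[8.0] == pytest.approx(total / 2)
        assert vol_at[9.0] == 0.0

    def test_first_entry_is_total_volume_and_monotone(self):
        rng = np.random.default_rng(11)
        g, mask = random_dose_and_mask(rng)
        dvh = compute_cumulative_dvh(g, mask)
        assert dvh.volume_cc[0] == pytest.approx(mask.volume_cc)
        assert np.all(np.diff(dvh.volume_cc) <= 1e-12)

    def test_empty_mask_names_structure(self):
        g = make_grid(np.zeros((3, 3, 3)))
        empty = mask_on(g, np.zeros(g.dims, bool), "cord")
        with pytest.raises(EmptyStructureError, match="cord"):
            compute_cumulative_dvh(g, empty)


class TestPointMetrics:
    def test_two_voxel_structure(self):
        g = make_grid([10.0, 20.0], spacing=(10, 10, 10))  # 1 cc voxels
        m = full_mask(g)
        assert d_at_cc(g, m, 1.0) == pytest.approx(20.0)
        assert v_dose_cc(g, m, 15.0) == pytest.approx(1.0)
        assert v_below_cc(g, m, 15.0) == pytest.approx(1.0)

    def test_uniform_50gy(self):
        g = make_grid(np.full((4, 4, 4), 50.0))
        m = full_mask(g)
        assert dose_stats(g, m) == (50.0, 50.0, 50.0)
        assert v_dose_pct(g, m, 50.0) == 100.0

    def test_coverage_examples(self):
        m = full_mask(make_grid(np.zeros((20, 1, 1))))
        covered = make_grid([50.0] * 19 + [49.0])
        assert coverage(covered, full_mask(covered), 50.0) == pytest.approx(95.0)
        uniform = make_grid(np.full((20, 1, 1), 50.0))
        assert coverage(uniform, m, 50.0) == 100.0
        half = make_grid([50.0] * 10 + [50.0 - 1e-9] * 10)
        assert coverage(half, m, 50.0) == pytest.approx(50.0)

    def test_query_validation(self):
        g = make_grid([10.0, 20.0])
        m = full_mask(g)
        with pytest.raises(ValueError, match="exceeds"):
            d_at_cc(g, m, 1.0)  # structure is only 0.002 cc
        with pytest.raises(ValueError):
            d_at_cc(g, m, -0.5)
        with pytest.raises(ValueError):
            d_at_pct(g, m, 120.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_field_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        g, mask = random_dose_and_mask(rng)
        member = g.values[mask.occupancy]
        vv = mask.voxel_volume_cc
        d_min, d_mean, d_max = dose_stats(g, mask)
        assert d_min == member.min() and d_max == member.max()
        assert d_mean == pytest.approx(member.mean(), rel=1e-12)
        for x in np.linspace(0, 65, 14):
            assert v_dose_pct(g, mask, x) == pytest.approx(
                100.0 * np.count_nonzero(member >= x) / member.size
            )
            assert v_dose_cc(g, mask, x) == pytest.approx(
                np.count_nonzero(member >= x) * vv
            )
        # d_at_cc is exact at voxel-volume multiples: k-th largest member dose
        desc = np.sort(member)[::-1]
        for k in (1, 2, member.size // 2, member.size):
            assert d_at_cc(g, mask, k * vv) == pytest.approx(desc[k - 1])

    @pytest.mark.parametrize("seed", [5, 6])
    def test_complementarity_identity(self, seed):
        rng = np.random.default_rng(seed)
        g, mask = random_dose_and_mask(rng)
        total = mask.volume_cc
        for x in np.linspace(0, 70, 9):
            assert v_dose_cc(g, mask, x) + v_below_cc(g, mask, x) == pytest.approx(total)

    def test_d_at_cc_non_increasing_in_volume(self):
        rng = np.random.default_rng(9)
        g, mask = random_dose_and_mask(rng)
        vols = np.linspace(0.01, mask.volume_cc, 20)
        doses = [d_at_cc(g, mask, v) for v in vols]
        assert np.all(np.diff(doses) <= 1e-12)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    doses=st.lists(st.floats(0, 80, allow_nan=False), min_size=2, max_size=40),
    x=st.floats(0, 85, allow_nan=False),
)
def test_v_metrics_are_complementary_and_bounded(doses, x):
    g = make_grid(doses)
    m = full_mask(g)
    v_pct = v_dose_pct(g, m, x)
    assert 0.0 <= v_pct <= 100.0
    assert v_dose_cc(g, m, x) + v_below_cc(g, m, x) == pytest.approx(m.volume_cc)


class TestCurveMetrics:
    """DVH-file-only metric extraction agrees with voxel metrics to one bin."""

    def test_curve_metrics_close_to_voxel_metrics(self):
        rng = np.random.default_rng(21)
        g, mask = random_dose_and_mask(rng)
        w = 0.01
        dvh = compute_cumulative_dvh(g, mask, bin_width=w)
        d_min, d_mean, d_max = dose_stats(g, mask)
        assert dvh_max_dose(dvh) == pytest.approx(d_max, abs=w)
        assert dvh_mean_dose(dvh) == pytest.approx(d_mean, abs=w)
        for x in (5.0, 20.0, 40.0):
            assert dvh_volume_at(dvh, x) == pytest.approx(
                v_dose_cc(g, mask, x), abs=2 * mask.voxel_volume_cc
            )
        for v in (0.05, 0.1):
            assert dvh_dose_at_cc(dvh, v) == pytest.approx(
                d_at_cc(g, mask, v), abs=0.25
            )
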