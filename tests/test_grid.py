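"""Voxel-grid model: superposition, resampling, mask algebra."""

import numpy as np
import pytest

from sbrteval import (
    DoseGrid,
    GeometryError,
    PlanDose,
    ROIMask,
    StructureSet,
    expand_margin,
    mask_volume_cc,
    resample_like,
    sum_doses,
    union_masks,
)
from helpers import full_mask, make_grid, mask_on, sphere_mask


def plan(values, **kw):
    return PlanDose(make_grid(values, **kw))


class TestSumDoses:
    def test_zero_grid_is_additive_identity(self):
        g = plan([[[1.0, 2.5], [3.0, 4.0]]])
        zero = PlanDose(g.grid.zeros_like())
        np.testing.assert_array_equal(sum_doses(zero, g).grid.values, g.grid.values)

    def test_voxelwise_addition(self):
        total = sum_doses(plan([1.0, 2.5]), plan([3.0, 4.0]))
        np.testing.assert_allclose(total.grid.values.ravel(), [4.0, 6.5])
        assert total.arm == "double"

    def test_origin_mismatch_raises_naming_field(self):
        a = plan([1.0, 2.0])
        b = plan([1.0, 2.0], origin=(0.75, 0.0, 0.0))
        with pytest.raises(GeometryError, match="origin"):
            sum_doses(a, b)

    def test_frame_mismatch_raises(self):
        with pytest.raises(GeometryError, match="frame_id"):
            sum_doses(plan([1.0]), plan([1.0], frame="other"))

    def test_fractionation_mismatch_raises(self):
        a = plan([1.0])
        b = PlanDose(make_grid([1.0]), n_fractions=3)
        with pytest.raises(ValueError, match="fraction"):
            sum_doses(a, b)

    def test_commutative_and_associative(self):
        rng = np.random.default_rng(7)
        grids = [plan(rng.uniform(0, 60, size=(4, 3, 2))) for _ in range(3)]
        a, b, c = grids
        np.testing.assert_array_equal(
            sum_doses(a, b).grid.values, sum_doses(b, a).grid.values
        )
        np.testing.assert_allclose(
            sum_doses(sum_doses(a, b), c).grid.values,
            sum_doses(a, sum_doses(b, c)).grid.values,
            rtol=1e-15,
        )


class TestResampleLike:
    def test_identity_resample(self):
        rng = np.random.default_rng(3)
        src = make_grid(rng.uniform(0, 50, size=(6, 5, 4)), spacing=(2, 2, 2))
        out = resample_like(src, src)
        np.testing.assert_allclose(out.values, src.values, atol=1e-12)

    def test_constant_field_interior(self):
        src = make_grid(np.full((8, 8, 8), 7.0), spacing=(2, 2, 2))
        target = DoseGrid((1.0, 1.0, 1.0), (1.5, 1.5, 1.5),
                          np.zeros((6, 6, 6)), src.frame_id)
        out = resample_like(src, target)
        np.testing.assert_allclose(out.values, 7.0, atol=1e-12)

    def test_affine_ramp_exact_at_half_spacing(self):
        # trilinear interpolation reproduces affine dose fields exactly
        def ramp(x, y, z):
            return 1.0 + 0.5 * x + 0.25 * y + 0.125 * z

        src_dims, spacing = (9, 9, 9), (2.0, 2.0, 2.0)
        ax = [np.arange(n) * s for n, s in zip(src_dims, spacing)]
        x, y, z = np.meshgrid(*ax, indexing="ij")
        src = make_grid(ramp(x, y, z), spacing=spacing)
        target = DoseGrid((2.0, 2.0, 2.0), (1.0, 1.0, 1.0),
                          np.zeros((12, 12, 12)), src.frame_id)
        out = resample_like(src, target)
        tx, ty, tz = np.meshgrid(*[target.axis_centers(a) for a in range(3)],
                                 indexing="ij")
        np.testing.assert_allclose(out.values, ramp(tx, ty, tz), rtol=1e-12)

    def test_outside_extent_is_zero(self):
        src = make_grid(np.full((4, 4, 4), 5.0))
        target = DoseGrid((100.0, 100.0, 100.0), (1, 1, 1),
                          np.zeros((3, 3, 3)), src.frame_id)
        assert resample_like(src, target).values.max() == 0.0


class TestMaskAlgebra:
    def test_disjoint_union_adds_volumes(self):
        g = make_grid(np.zeros((30, 10, 10)))  # 1 mm voxels: 1 voxel = 0.001 cc
        a = mask_on(g, np.arange(3000).reshape(g.dims) < 1000, "a")  # 1.0 cc
        b = mask_on(g, (np.arange(3000).reshape(g.dims) >= 1000)
                    & (np.arange(3000).reshape(g.dims) < 1500), "b")  # 0.5 cc
        u = union_masks(a, b)
        assert u.volume_cc == pytest.approx(a.volume_cc + b.volume_cc)

    def test_union_idempotent_and_empty_invariant(self):
        g = make_grid(np.zeros((5, 5, 5)))
        m = sphere_mask(g, (2, 2, 2), 1.6)
        assert np.array_equal(union_masks(m, m).occupancy, m.occupancy)
        empty = mask_on(g, np.zeros(g.dims, bool), "empty")
        assert union_masks(m, empty).volume_cc == m.volume_cc

    def test_union_monotone_under_superset(self):
        g = make_grid(np.zeros((8, 8, 8)))
        small = sphere_mask(g, (4, 4, 4), 1.5)
        big = sphere_mask(g, (4, 4, 4), 3.0)
        assert union_masks(small, big).volume_cc >= small.volume_cc

    def test_geometry_mismatch_raises(self):
        a = full_mask(make_grid(np.zeros((2, 2, 2))))
        b = full_mask(make_grid(np.zeros((2, 2, 2)), spacing=(2, 2, 2)))
        with pytest.raises(GeometryError, match="spacing"):
            union_masks(a, b)

    def test_empty_mask_volume_zero(self):
        g = make_grid(np.zeros((4, 4, 4)))
        assert mask_volume_cc(mask_on(g, np.zeros(g.dims, bool))) == 0.0

    def test_unit_conversion_thousand_voxels(self):
        g = make_grid(np.zeros((10, 10, 10)))  # 1x1x1 mm voxels
        assert mask_volume_cc(full_mask(g)) == pytest.approx(1.0)

    def test_digitized_sphere_volume_close_to_analytic(self):
        g = make_grid(np.zeros((31, 31, 31)))  # 1 mm spacing
        m = sphere_mask(g, (15, 15, 15), 12.0)
        analytic = 4.0 / 3.0 * np.pi * 1.2**3  # 7.238 cc
        assert mask_volume_cc(m) == pytest.approx(analytic, rel=0.02)


class TestExpandMargin:
    def test_zero_margin_is_identity(self):
        g = make_grid(np.zeros((12, 12, 12)))
        m = sphere_mask(g, (6, 6, 6), 3.0)
        assert np.array_equal(expand_margin(m, 0.0).occupancy, m.occupancy)

    def test_sphere_expands_toward_radius_plus_margin(self):
        g = make_grid(np.zeros((41, 41, 41)))  # 1 mm spacing
        m = sphere_mask(g, (20, 20, 20), 8.0)
        grown = expand_margin(m, 5.0)
        # centre-sampled dilation of a centre-sampled sphere is bracketed by
        # the digitized spheres of radius R+margin-h and R+margin
        inner = sphere_mask(g, (20, 20, 20), 11.0)
        outer = sphere_mask(g, (20, 20, 20), 13.0 + 1e-6)
        assert np.all(grown.occupancy[m.occupancy])
        assert np.all(grown.occupancy[inner.occupancy])
        assert np.all(outer.occupancy[grown.occupancy])
        analytic = 4.0 / 3.0 * np.pi * 1.3**3
        assert grown.volume_cc == pytest.approx(analytic, rel=0.10)

    def test_negative_margin_rejected(self):
        g = make_grid(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            expand_margin(full_mask(g), -1.0)


class TestStructureSet:
    def test_derives_unions(self):
        g = make_grid(np.zeros((10, 10, 10)))
        body = full_mask(g, "body")
        p1 = sphere_mask(g, (3, 5, 5), 2.0, "ptv1")
        p2 = sphere_mask(g, (7, 5, 5), 2.0, "ptv2")
        ss = StructureSet({"ptv1": p1, "ptv2": p2, "body": body})
        assert np.array_equal(
            ss["ptv12"].occupancy, p1.occupancy | p2.occupancy
        )

    def test_inconsistent_combined_mask_rejected(self):
        g = make_grid(np.zeros((10, 10, 10)))
        body = full_mask(g, "body")
        p1 = sphere_mask(g, (3, 5, 5), 2.0, "ptv1")
        p2 = sphere_mask(g, (7, 5, 5), 2.0, "ptv2")
        with pytest.raises(ValueError, match="ptv12"):
            StructureSet({"ptv1": p1, "ptv2": p2, "ptv12": p1, "body": body})

    def test_mask_outside_body_rejected(self):
        g = make_grid(np.zeros((10, 10, 10)))
        body = sphere_mask(g, (5, 5, 5), 3.0, "body")
        stray = sphere_mask(g, (1, 1, 1), 2.0, "heart")
        with pytest.raises(ValueError, match="heart"):
            StructureSet({"body": body, "heart": stray})


def test_dose_grid_rejects_bad_values():
    with pytest.raises(ValueError):
        make_grid([-1.0, 2.0])
    with pytest.raises(ValueError):
        make_grid([np.nan, 2.0])
    with pytest.raises(GeometryError):
        make_grid([1.0], spacing=(0.0, 1.0, 1.0))
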