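"""Trait operators: oracles, invariances and the outlier filter."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_face_count, digital_ellipsoid, rotation_matrix_zyx
from grainct import morpho, simgrain
from grainct.morpho import GrainLimitBounds


def rod_mask(n=50, w=3):
    mask = np.zeros((n, w, w), dtype=bool)
    mask[:] = True
    return mask


class TestPrincipalAxes:
    def test_axis_aligned_rod(self):
        axes, extents = morpho.principal_axes(rod_mask())
        assert abs(abs(axes[0][0]) - 1.0) < 1e-12  # major axis along z, up to sign
        assert extents[0] == pytest.approx(50.0)

    def test_rotated_rod_extent(self):
        # 30° in-plane rotation; oracle projects exact voxel centres
        pts = np.argwhere(rod_mask()).astype(float)
        theta = math.radians(30)
        rotm = rotation_matrix_zyx((theta, 0.0, 0.0))
        rotated = pts @ rotm.T
        _, extents = morpho.principal_axes(rotated)
        assert extents[0] == pytest.approx(50.0, abs=1.0)

    def test_digital_ellipsoid_extents(self):
        mask = digital_ellipsoid((40, 20, 10))
        _, extents = morpho.principal_axes(mask)
        for got, want in zip(extents, (80, 40, 20)):
            # the unit-cube convention adds one voxel, so the smallest axis
            # (20 voxels) sits exactly on the 5% boundary
            assert abs(got / want - 1) <= 0.05 + 1e-12

    def test_degenerate_sets_rejected(self):
        with pytest.raises(morpho.DegenerateGrainError):
            morpho.principal_axes(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]))
        plane = np.array([[0, y, x] for y in range(3) for x in range(3)])
        with pytest.raises(morpho.DegenerateGrainError):
            morpho.principal_axes(plane)


class TestLength:
    def test_single_voxel_convention(self):
        assert morpho.measure_length(np.array([[3, 3, 3]]), 68.8) == pytest.approx(68.8)

    def test_rod(self):
        assert morpho.measure_length(rod_mask(), 1.0) == pytest.approx(50.0)

    def test_ellipsoid(self):
        mask = digital_ellipsoid((40, 20, 10))
        assert abs(morpho.measure_length(mask, 1.0) / 80.0 - 1) < 0.05


class TestCrossSection:
    def test_rod_square_section(self):
        w, d = morpho.measure_cross_section(rod_mask(), 1.0)
        assert w == pytest.approx(3.0)
        assert d == pytest.approx(3.0)

    def test_ellipsoid_midpoint_section(self):
        # the midpoint section of an (a,b,c) ellipsoid is an ellipse with
        # semi-axes (b, c)
        mask = digital_ellipsoid((40, 20, 10))
        w, d = morpho.measure_cross_section(mask, 1.0)
        assert abs(w / 40.0 - 1) <= 0.05 + 1e-12
        assert abs(d / 20.0 - 1) <= 0.05 + 1e-12

    def test_rotation_invariance(self):
        rng = np.random.default_rng(123)
        rot = rotation_matrix_zyx(tuple(rng.uniform(0, 2 * math.pi, 3)))
        w0, d0 = morpho.measure_cross_section(digital_ellipsoid((40, 20, 10)), 1.0)
        w1, d1 = morpho.measure_cross_section(digital_ellipsoid((40, 20, 10), rot), 1.0)
        assert abs(w1 / w0 - 1) < 0.07
        assert abs(d1 / d0 - 1) < 0.07

    def test_degenerate_midpoint_section(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 1], [3, 1, 0], [4, 0, 0]])
        with pytest.raises(morpho.DegenerateGrainError, match="midpoint"):
            morpho.measure_cross_section(pts, 1.0)


class TestVolume:
    def test_cube_exact(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        assert morpho.measure_volume(mask, 1.0) == 1000.0

    def test_digital_sphere(self):
        mask = digital_ellipsoid((20, 20, 20))
        expected = 4.0 / 3.0 * math.pi * 20**3
        assert abs(morpho.measure_volume(mask, 1.0) / expected - 1) < 0.02

    def test_units_law(self):
        mask = digital_ellipsoid((8, 6, 5))
        assert morpho.measure_volume(mask, 2.0) == 8 * morpho.measure_volume(mask, 1.0)


class TestSurfaceArea:
    def test_single_voxel(self):
        assert morpho.measure_surface_area(np.array([[0, 0, 0]]), 1.0) == 6.0

    @pytest.mark.parametrize("n", [1, 5, 10, 25])
    def test_cube_6n2_exact(self, n):
        mask = np.ones((n, n, n), dtype=bool)
        assert morpho.measure_surface_area(mask, 1.0) == 6.0 * n**2

    def test_matches_brute_force_oracle_on_sphere(self):
        mask = digital_ellipsoid((12, 12, 12))
        assert morpho.measure_surface_area(mask, 1.0) == brute_force_face_count(mask)

    def test_scale_covariance(self):
        mask = digital_ellipsoid((8, 6, 5))
        assert morpho.measure_surface_area(mask, 3.0) == 9 * morpho.measure_surface_area(mask, 1.0)


class TestExtractTraits:
    def test_phantom_traits_match_analytic(self, small_phantom):
        spec, _, labels = small_phantom
        table = morpho.extract_traits(labels)
        assert len(table) == len(spec.grains)
        for row, grain in zip(table.itertuples(), spec.grains):
            a, b, c = grain.semi_axes
            assert abs(row.length_um / (2 * a) - 1) < 0.05
            assert abs(row.width_um / (2 * b) - 1) < 0.05
            assert abs(row.depth_um / (2 * c) - 1) < 0.07
            vol = 4 / 3 * math.pi * a * b * c
            assert abs(row.volume_um3 / vol - 1) < 0.05

    def test_record_invariants(self, small_phantom):
        _, _, labels = small_phantom
        table = morpho.extract_traits(labels)
        assert (table.length_um >= table.width_um).all()
        assert (table.width_um >= table.depth_um).all()
        np.testing.assert_allclose(
            table.sa_v_ratio_per_um, table.surface_area_um2 / table.volume_um3
        )

    def test_empty_label_volume(self):
        from grainct.volio import LabelVolume

        empty = LabelVolume(np.zeros((4, 4, 4), dtype=np.int32), 68.8)
        assert len(morpho.extract_traits(empty)) == 0

    def test_degenerate_grain_flagged_not_dropped(self):
        from grainct.volio import LabelVolume

        data = np.zeros((5, 5, 5), dtype=np.int32)
        data[1, 1, 1] = 1  # single voxel: no midpoint section
        data[3, 0:3, 0:3] = 2  # coplanar slab
        lab = LabelVolume(data, 68.8)
        table = morpho.extract_traits(lab)
        assert len(table) == 2
        assert (table.flag != "").all()
        assert table.length_um.isna().all()


def _filter_table(values):
    n = len(values)
    return pd.DataFrame(
        {
            "grain_id": range(n),
            "status": "wild",
            "taxon": "t",
            "length_um": np.asarray(values, dtype=float),
            "width_um": 1.0,
            "depth_um": 1.0,
            "volume_um3": 1.0,
            "surface_area_um2": 1.0,
        }
    )


class TestFilterOutliers:
    def test_order_statistics_oracle_950_survive(self):
        table = _filter_table(np.arange(1, 1001))
        out = morpho.filter_outliers(table)
        # oracle: type-7 quantiles of 1..1000 are 25.975 and 975.025
        values = np.sort(np.arange(1, 1001, dtype=float))
        lo = values[24] + 0.975 * (values[25] - values[24])
        hi = values[974] + 0.025 * (values[975] - values[974])
        survivors = ((values >= lo) & (values <= hi)).sum()
        assert survivors == 950
        assert len(out) == 950
        assert out.length_um.min() > 25.975 - 1e-9
        assert out.length_um.max() < 975.025 + 1e-9

    def test_identical_records_all_retained(self):
        table = _filter_table([5.0] * 10)
        assert len(morpho.filter_outliers(table)) == 10

    def test_grain_limit_bounds_removal(self):
        table = _filter_table([5.0] * 10)
        table["width_um"] = 2000.0
        table["depth_um"] = 1500.0
        table.loc[:, "length_um"] = 6000.0
        table.loc[3, "length_um"] = 40_000.0  # beyond plausible grain length
        out = morpho.filter_outliers(table, GrainLimitBounds())
        assert len(out) == 9
        assert 3 not in set(out.grain_id)

    def test_idempotent_on_degenerate_table(self):
        table = _filter_table([5.0] * 8)
        once = morpho.filter_outliers(table)
        twice = morpho.filter_outliers(once)
        pd.testing.assert_frame_equal(once, twice)
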