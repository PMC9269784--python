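import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import formfactors as ff
from formfactors import BoxDims, PhantomSpec, VoxelMask, make_phantom
from formfactors.errors import DomainError, EmptyROIError


def box_dims_strategy():
    sides = st.tuples(
        st.floats(0.1, 100.0), st.floats(0.1, 100.0), st.floats(0.1, 100.0)
    )
    return sides.map(lambda s: BoxDims(*sorted(s, reverse=True)))


class TestBoundingBox:
    def test_single_voxel_has_unit_box(self, single_voxel_mask):
        dims = ff.bounding_box_dims(single_voxel_mask)
        assert (dims.l, dims.b, dims.t) == (1, 1, 1)

    def test_solid_cuboid_exact(self, cuboid_mask):
        dims = ff.bounding_box_dims(cuboid_mask)
        assert (dims.l, dims.b, dims.t) == (20, 10, 5)

    def test_anisotropic_spacing_full_extents(self):
        grid = np.zeros((12, 12, 6))
        grid[1:11, 1:11, 1:5] = 1  # 10 x 10 x 4 voxels
        mask = VoxelMask(grid=grid, spacing=(1.37, 1.37, 3.27))
        dims = ff.bounding_box_dims(mask)
        assert (dims.l, dims.b, dims.t) == pytest.approx((13.7, 13.7, 13.08))

    def test_empty_mask_raises(self):
        mask = VoxelMask(grid=np.zeros((3, 3, 3)), spacing=(1, 1, 1))
        mask.grid[:] = 0
        with pytest.raises(EmptyROIError):
            ff.bounding_box_dims(mask)

    def test_invalid_dims_rejected(self):
        with pytest.raises(DomainError):
            BoxDims(l=1.0, b=2.0, t=0.5)  # violates l >= b
        with pytest.raises(DomainError):
            BoxDims(l=2.0, b=1.0, t=0.0)  # nonpositive


class TestFormFactorFormulas:
    """Hand-computed closed forms for the six bounding-box form factors."""

    @pytest.mark.parametrize(
        "dims, expected",
        [
            (BoxDims(1, 1, 1), (0.0, 0.0, 1.0)),
            (BoxDims(4, 2, 1), (2 / 7, 2 / 7, 3 / 7)),
        ],
    )
    def test_angelidakis(self, dims, expected):
        assert ff.angelidakis_indices(dims) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "dims, expected",
        [
            (BoxDims(1, 1, 1), (0.0, 0.0)),
            (BoxDims(4, 2, 1), (0.5, 0.5)),
            (BoxDims(2, 1, 0.5), (0.5, 0.5)),  # scale invariance vs (4,2,1)
        ],
    )
    def test_kong(self, dims, expected):
        assert ff.kong_indices(dims) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "dims, expected",
        [
            (BoxDims(1, 1, 1), 1.0),
            (BoxDims(4, 2, 1), 0.5),
            (BoxDims(2, 2, 1), 0.25 ** (1 / 3)),
        ],
    )
    def test_max_projection_sphericity(self, dims, expected):
        assert ff.max_projection_sphericity(dims) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=200)
    @given(dims=box_dims_strategy())
    def test_sum_to_one_and_ranges(self, dims):
        ael, afl, aco = ff.angelidakis_indices(dims)
        assert ael + afl + aco == pytest.approx(1.0, abs=1e-9)
        kel, kfl = ff.kong_indices(dims)
        mps = ff.max_projection_sphericity(dims)
        for v in (ael, afl, aco, kel, kfl, mps):
            assert -1e-12 <= v <= 1 + 1e-12

    @settings(derandomize=True, max_examples=100)
    @given(dims=box_dims_strategy(), k=st.floats(0.01, 100.0))
    def test_scale_invariance(self, dims, k):
        scaled = BoxDims(dims.l * k, dims.b * k, dims.t * k)
        assert ff.angelidakis_indices(scaled) == pytest.approx(
            ff.angelidakis_indices(dims), rel=1e-9
        )
        assert ff.kong_indices(scaled) == pytest.approx(
            ff.kong_indices(dims), rel=1e-9
        )
        assert ff.max_projection_sphericity(scaled) == pytest.approx(
            ff.max_projection_sphericity(dims), rel=1e-9
        )


class TestVolumeAndSurface:
    def test_voxel_volume_counting(self, single_voxel_mask, cuboid_mask):
        assert ff.voxel_volume(single_voxel_mask) == pytest.approx(1.0)
        assert ff.voxel_volume(cuboid_mask) == pytest.approx(1000.0)

    def test_voxel_volume_anisotropic(self):
        grid = np.zeros((12, 12, 12))
        grid[1:11, 1:11, 1:11] = 1
        mask = VoxelMask(grid=grid, spacing=(1.37, 1.37, 3.27))
        assert ff.voxel_volume(mask) == pytest.approx(1000 * 1.37 * 1.37 * 3.27)

    def test_ellipsoid_volume_closed_form(self, ellipsoid_mask):
        expected = 4 / 3 * np.pi * 10 * 5 * 2.5
        assert ff.voxel_volume(ellipsoid_mask) == pytest.approx(expected, rel=0.02)

    def test_sphere_surface_area(self, sphere_mask):
        assert ff.surface_area(sphere_mask) == pytest.approx(
            4 * np.pi * 100, rel=0.03
        )

    def test_surface_area_converges_with_resolution(self):
        truth = 4 * np.pi * 100
        errors = []
        for sp in (1.0, 0.5, 0.25):
            m = make_phantom(PhantomSpec(semi_axes=(10,) * 3, spacing=(sp,) * 3))
            errors.append(abs(ff.surface_area(m) - truth))
        assert errors[2] < errors[0]

    def test_voxel_face_area_single_voxel(self, single_voxel_mask):
        assert ff.surface_area(single_voxel_mask, method="voxel") == pytest.approx(6.0)

    def test_mesh_closes_at_grid_border(self):
        grid = np.ones((4, 4, 4))  # touches every border
        mask = VoxelMask(grid=grid, spacing=(1, 1, 1))
        verts, faces = ff.surface_mesh(mask)
        # closed mesh: every edge shared by exactly two triangles
        edges = np.vstack(
            [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert (counts == 2).all()


class TestDiameterAndDerived:
    def test_cuboid_diameter_near_box_diagonal(self, cuboid_mask):
        expected = np.sqrt(20**2 + 10**2 + 5**2)
        assert ff.max_3d_diameter(cuboid_mask) == pytest.approx(expected, rel=0.03)

    def test_sphere_diameter(self, sphere_mask):
        assert ff.max_3d_diameter(sphere_mask) == pytest.approx(20.0, rel=0.03)

    def test_diameter_at_least_box_length(self, ellipsoid_mask):
        dims = ff.bounding_box_dims(ellipsoid_mask)
        assert ff.max_3d_diameter(ellipsoid_mask) >= dims.l - 1e-9

    def test_sphericity_closed_forms(self):
        r = 7.3
        vol, area = 4 / 3 * np.pi * r**3, 4 * np.pi * r**2
        assert ff.sphericity(vol, area) == pytest.approx(1.0)
        assert ff.sphericity(1.0, 6.0) == pytest.approx(
            np.pi ** (1 / 3) * 6 ** (2 / 3) / 6
        )
        with pytest.raises(DomainError):
            ff.sphericity(-1.0, 6.0)

    def test_sphericity_clips_above_one_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            assert ff.sphericity(1e6, 1.0) == 1.0

    def test_volume_density(self, cuboid_mask, ellipsoid_mask):
        dims = ff.bounding_box_dims(cuboid_mask)
        assert ff.volume_density(ff.voxel_volume(cuboid_mask), dims) == pytest.approx(1.0)
        dims_e = ff.bounding_box_dims(ellipsoid_mask)
        vdn = ff.volume_density(ff.voxel_volume(ellipsoid_mask), dims_e)
        assert vdn == pytest.approx(np.pi / 6, rel=0.03)


class TestExtractAll:
    def test_ellipsoid_closed_forms(self, ellipsoid_mask):
        fv = ff.extract_all(ellipsoid_mask)
        assert fv.ael == pytest.approx(2 / 7, abs=0.02)
        assert fv.afl == pytest.approx(2 / 7, abs=0.02)
        assert fv.aco == pytest.approx(3 / 7, abs=0.02)
        assert fv.kel == pytest.approx(0.5, abs=0.02)
        assert fv.kfl == pytest.approx(0.5, abs=0.02)
        assert fv.mps == pytest.approx(0.5, abs=0.02)
        assert fv.vdn == pytest.approx(np.pi / 6, rel=0.03)
        assert fv.ael + fv.afl + fv.aco == pytest.approx(1.0, abs=1e-9)

    def test_sphere_is_equant(self, sphere_mask):
        fv = ff.extract_all(sphere_mask)
        assert fv.ael == pytest.approx(0.0, abs=0.01)
        assert fv.afl == pytest.approx(0.0, abs=0.01)
        assert fv.aco == pytest.approx(1.0, abs=0.01)
        assert fv.mps == pytest.approx(1.0, abs=0.01)
        assert fv.sphericity == pytest.approx(1.0, abs=0.05)

    def test_dimensionless_features_in_unit_interval(self, ellipsoid_mask):
        fv = ff.extract_all(ellipsoid_mask)
        for name in ff.shape_features.DIMENSIONLESS_FEATURES:
            assert 0.0 <= getattr(fv, name) <= 1.0

    def test_axis_permutation_invariance(self):
        m = make_phantom(PhantomSpec(semi_axes=(8, 5, 3), spacing=(0.5,) * 3))
        base = ff.extract_all(m).as_dict()
        permuted = VoxelMask(
            grid=np.transpose(m.grid, (2, 0, 1)),
            spacing=(m.spacing[2], m.spacing[0], m.spacing[1]),
        )
        perm = ff.extract_all(permuted).as_dict()
        for name, value in base.items():
            assert perm[name] == pytest.approx(value, rel=1e-6), name

    def test_spacing_scaling_covariance(self):
        m1 = make_phantom(PhantomSpec(semi_axes=(8, 5, 3), spacing=(0.5,) * 3))
        k = 2.0
        m2 = VoxelMask(grid=m1.grid, spacing=tuple(k * s for s in m1.spacing))
        f1, f2 = ff.extract_all(m1).as_dict(), ff.extract_all(m2).as_dict()
        # mesh vertices are float32, so covariance holds to single precision
        assert f2["max3ddiam"] == pytest.approx(k * f1["max3ddiam"], rel=1e-6)
        assert f2["surfarea"] == pytest.approx(k**2 * f1["surfarea"], rel=1e-6)
        assert f2["volume"] == pytest.approx(k**3 * f1["volume"], rel=1e-9)
        for name in ff.shape_features.DIMENSIONLESS_FEATURES:
            assert f2[name] == pytest.approx(f1[name], rel=1e-6), name

    def test_not_rotation_invariant(self):
        """An elongated ellipsoid rotated 45 deg changes its AEL: the box is
        axis-aligned by construction, and this is asserted behaviour."""
        theta = np.pi / 4
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        spec0 = PhantomSpec(semi_axes=(10, 3, 3), spacing=(0.5,) * 3)
        spec45 = PhantomSpec(semi_axes=(10, 3, 3), spacing=(0.5,) * 3, rotation=rot)
        ael0 = ff.extract_all(make_phantom(spec0)).ael
        ael45 = ff.extract_all(make_phantom(spec45)).ael
        assert abs(ael0 - ael45) > 0.05

    def test_single_slice_roi_is_defined(self):
        """A one-slice ROI gets thickness = one slice spacing; every feature
        stays finite and the ratios defined."""
        grid = np.zeros((10, 8, 1))
        grid[1:9, 1:7, 0] = 1
        fv = ff.extract_all(VoxelMask(grid=grid, spacing=(1.37, 1.37, 3.27)))
        assert np.isfinite(list(fv.as_dict().values())).all()
        assert fv.ael + fv.afl + fv.aco == pytest.approx(1.0, abs=1e-9)
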