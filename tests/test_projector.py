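import numpy as np
import pytest

from spectsip.core import ValidationError, Volume
from spectsip.io import load_projections, save_projections
from spectsip.projector import (
    AcquisitionGeometry,
    ForwardOperator,
    ProjectionSet,
    SystemModel,
    add_poisson_noise,
    back_project,
    forward_project,
    subsample_sparse,
)
from spectsip.sips import sip_index_plan


def ray_march_total(activity, mu, voxel_mm, src_idx):
    """Independent attenuated ray sum toward the +y detector at angle 0."""
    iz, iy, ix = src_idx
    n = activity.shape[1]
    path = 0.5 * mu[iz, iy, ix]
    for jy in range(iy + 1, n):
        path += mu[iz, jy, ix]
    return activity[iz, iy, ix] * np.exp(-voxel_mm * path)


class TestForwardModel:
    def test_zero_activity_projects_to_zero(self, small_attenuation, small_model):
        act = Volume(np.zeros((16, 16, 16)), 4.42, "activity")
        proj = forward_project(act, small_attenuation, small_model)
        assert proj.counts.shape == (8, 16, 16)
        np.testing.assert_array_equal(proj.counts, 0.0)

    def test_count_conservation_ideal_rays(self, rng, ideal_model):
        act = Volume(np.pad(rng.random((8, 8, 8)), 4), 4.42, "activity")
        mu = Volume(np.zeros((16, 16, 16)), 4.42, "attenuation")
        proj = forward_project(act, mu, ideal_model)
        totals = proj.counts.sum(axis=(1, 2))
        np.testing.assert_allclose(totals, act.values.sum(), rtol=1e-12)

    def test_single_voxel_attenuated_closed_form(self):
        n = 16
        mu0 = 0.0127
        geo = AcquisitionGeometry(n_angles=4, matrix_size=n, pixel_size_mm=4.42)
        model = SystemModel(geometry=geo, psf_sigma0_mm=0.0, psf_slope=0.0)
        mu = np.full((n, n, n), mu0)
        act = np.zeros((n, n, n))
        act[8, 10, 8] = 5.0
        proj = forward_project(
            Volume(act, 4.42, "activity"), Volume(mu, 4.42, "attenuation"), model
        )
        # depth to the detector: planes 11..15 plus half the emitting voxel
        expected = 5.0 * np.exp(-4.42 * mu0 * (5 + 0.5))
        assert proj.counts[0].sum() == pytest.approx(expected, rel=1e-7)
        # and against the independent ray-marching oracle (float32 transmission
        # cache in the operator limits agreement to single precision)
        oracle = ray_march_total(act, mu, 4.42, (8, 10, 8))
        assert proj.counts[0].sum() == pytest.approx(oracle, rel=1e-6)

    def test_forward_is_linear_in_activity(self, rng, small_attenuation, small_model):
        op = ForwardOperator(small_attenuation, small_model)
        pos = np.arange(8)
        x1 = rng.random((16, 16, 16))
        x2 = rng.random((16, 16, 16))
        lhs = op.project_positions(2.0 * x1 + 3.0 * x2, pos)
        rhs = 2.0 * op.project_positions(x1, pos) + 3.0 * op.project_positions(x2, pos)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_grid_mismatch_rejected(self, small_attenuation, small_model):
        act = Volume(np.zeros((8, 16, 16)), 4.42, "activity")
        with pytest.raises(ValidationError):
            forward_project(act, small_attenuation, small_model)


class TestAdjoint:
    def test_adjoint_identity_with_full_physics(self, rng, small_attenuation):
        geo = AcquisitionGeometry(n_angles=8, matrix_size=16, pixel_size_mm=4.42)
        model = SystemModel(geometry=geo, scatter_mode="kernel", scatter_fraction=0.2)
        op = ForwardOperator(small_attenuation, model)
        pos = np.arange(8)
        x = rng.random((16, 16, 16))
        y = rng.random((8, 16, 16))
        lhs = float(np.sum(op.project_positions(x, pos) * y))
        rhs = float(np.sum(x * op.backproject_positions(y, pos)))
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_backprojection_matches_explicit_matrix_transpose(self, rng):
        n = 6
        geo = AcquisitionGeometry(n_angles=4, matrix_size=n, pixel_size_mm=4.42)
        model = SystemModel(geometry=geo, psf_sigma0_mm=1.0, psf_slope=0.01)
        mu = Volume(np.full((n, n, n), 0.01), 4.42, "attenuation")
        op = ForwardOperator(mu, model)
        pos = np.arange(4)
        nvox = n**3
        nproj = 4 * n * n
        A = np.zeros((nproj, nvox))
        for j in range(nvox):
            e = np.zeros(nvox)
            e[j] = 1.0
            A[:, j] = op.project_positions(e.reshape(n, n, n), pos).ravel()
        y = rng.random((4, n, n))
        expected = A.T @ y.ravel()
        got = op.backproject_positions(y, pos).ravel()
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_zero_projections_backproject_to_zero(self, small_attenuation, small_model):
        proj = ProjectionSet(
            counts=np.zeros((8, 16, 16)),
            indices=np.arange(1, 9),
            angles_deg=small_model.geometry.angles_deg,
            pixel_size_mm=4.42,
        )
        vol = back_project(proj, small_attenuation, small_model)
        np.testing.assert_array_equal(vol.values, 0.0)

    def test_sensitivity_map_positive_in_fov(self, small_attenuation, small_model):
        proj = ProjectionSet(
            counts=np.ones((8, 16, 16)),
            indices=np.arange(1, 9),
            angles_deg=small_model.geometry.angles_deg,
            pixel_size_mm=4.42,
        )
        sens = back_project(proj, small_attenuation, small_model)
        # central region (inside every rotated frame) must be strictly positive
        assert (sens.values[:, 5:11, 5:11] > 0).all()


class TestPoissonNoise:
    def _flat_proj(self, mean, shape=(1, 100, 100)):
        counts = np.full(shape, float(mean))
        return ProjectionSet(
            counts=counts,
            indices=np.array([1]),
            angles_deg=np.array([0.0]),
            pixel_size_mm=4.42,
            count_scale=float(mean * shape[1] * shape[2]),  # scale factor 1
        )

    def test_zero_mean_stays_zero(self):
        proj = self._flat_proj(0.0)
        proj = ProjectionSet(
            counts=proj.counts, indices=proj.indices, angles_deg=proj.angles_deg,
            pixel_size_mm=4.42, count_scale=1e5,
        )
        noisy = add_poisson_noise(proj, seed=1)
        np.testing.assert_array_equal(noisy.counts, 0.0)

    def test_seed_reproducibility(self):
        proj = self._flat_proj(7.0)
        a = add_poisson_noise(proj, seed=42)
        b = add_poisson_noise(proj, seed=42)
        np.testing.assert_array_equal(a.counts, b.counts)
        c = add_poisson_noise(proj, seed=43)
        assert not np.array_equal(a.counts, c.counts)

    def test_sample_mean_within_three_sigma(self):
        # 10^4 independent Poisson(5) pixels: SEM = sqrt(5/10^4)
        proj = self._flat_proj(5.0)
        noisy = add_poisson_noise(proj, seed=7)
        assert noisy.counts.mean() == pytest.approx(5.0, abs=3 * np.sqrt(5 / 1e4))
        assert np.all(noisy.counts == np.round(noisy.counts))

    def test_mean_total_matches_count_scale(self, rng):
        counts = rng.random((4, 32, 32))
        proj = ProjectionSet(
            counts=counts, indices=np.arange(1, 5),
            angles_deg=np.arange(4) * 90.0, pixel_size_mm=4.42, count_scale=5e4,
        )
        noisy = add_poisson_noise(proj, seed=3)
        # law of large numbers at 5e4 counts/projection: within ~1.5%
        assert noisy.counts.sum() / 4 == pytest.approx(5e4, rel=0.015)


class TestSparseSubsampling:
    def _full(self, n_angles=120, side=8):
        geo = AcquisitionGeometry(n_angles=n_angles, matrix_size=side)
        return ProjectionSet(
            counts=np.arange(n_angles * side * side, dtype=float).reshape(
                n_angles, side, side
            ),
            indices=np.arange(1, n_angles + 1),
            angles_deg=geo.angles_deg,
            pixel_size_mm=4.42,
        )

    def test_every_fourth_retained(self):
        sparse = subsample_sparse(self._full())
        assert sparse.indices[0] == 1
        assert list(sparse.indices[:3]) == [1, 5, 9]
        assert sparse.indices[-1] == 117
        assert len(sparse) == 120 // 4
        np.testing.assert_array_equal(sparse.counts, self._full().counts[::4])

    def test_partition_with_sip_sets_tiles_orbit(self):
        sparse = subsample_sparse(self._full())
        plan = sip_index_plan(120)
        sets = [sparse.indices, *plan.sip_sets]
        union = np.concatenate(sets)
        assert len(np.unique(union)) == 120
        np.testing.assert_array_equal(np.sort(union), np.arange(1, 121))

    def test_partial_input_rejected(self):
        sparse = subsample_sparse(self._full())
        with pytest.raises(ValidationError):
            subsample_sparse(sparse)


def test_hdf5_roundtrip_bit_exact(tmp_path, rng):
    counts = rng.random((12, 16, 16))
    proj = ProjectionSet(
        counts=counts,
        indices=np.arange(1, 13),
        angles_deg=np.arange(12) * 30.0,
        pixel_size_mm=4.42,
        count_scale=2.5e4,
    )
    path = tmp_path / "proj.h5"
    save_projections(path, proj)
    back = load_projections(path)
    np.testing.assert_array_equal(back.counts, proj.counts)
    np.testing.assert_array_equal(back.indices, proj.indices)
    np.testing.assert_array_equal(back.angles_deg, proj.angles_deg)
    assert back.pixel_size_mm == proj.pixel_size_mm
    assert back.count_scale == proj.count_scale
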