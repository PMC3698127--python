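"""ISRA, TV-regularized ISRA, TV functional and filtered back projection."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import nnls

from sparsect.geometry import (
    ProjectionData,
    VolumeImage,
    forward_project,
    make_geometry,
    subsample_views,
)
from sparsect.phantom import simulate_projections
from sparsect.reconstruct import (
    DegenerateDataError,
    ReconConfig,
    fbp,
    isra,
    isra_system,
    isra_tv,
    stop_metric,
    tv_energy,
    tv_gradient,
)


class TestTvEnergy:
    def test_constant_image_equals_n_delta(self):
        x = np.full((7, 5), 3.2)
        assert tv_energy(x, 1e-3) == pytest.approx(35 * 1e-3)

    def test_unit_step_1d_approaches_one(self):
        x = np.array([[0.0, 0.0, 1.0, 1.0]])
        assert tv_energy(x, 1e-9) == pytest.approx(1.0, rel=1e-6)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.random((9, 9))
        assert tv_energy(x, 1e-4) == pytest.approx(tv_energy(x + 5.0, 1e-4))

    def test_delta_must_be_positive(self):
        with pytest.raises(ValueError):
            tv_energy(np.zeros((2, 2)), 0.0)


class TestTvGradient:
    def test_constant_image_has_zero_gradient(self):
        g = tv_gradient(np.full((6, 6), 2.0), 1e-3)
        assert np.allclose(g, 0.0)

    @pytest.mark.parametrize("shape", [(8, 8), (5, 4, 3)])
    def test_matches_central_finite_differences(self, shape):
        rng = np.random.default_rng(11)
        x = rng.random(shape)
        delta = 1e-2
        g = tv_gradient(x, delta)
        eps = 1e-6
        for idx in [(0,) * len(shape), tuple(s - 1 for s in shape),
                    tuple(s // 2 for s in shape), (1,) * len(shape)]:
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            fd = (tv_energy(xp, delta) - tv_energy(xm, delta)) / (2 * eps)
            assert g[idx] == pytest.approx(fd, abs=1e-5)

    def test_gradient_sums_to_zero(self):
        rng = np.random.default_rng(3)
        g = tv_gradient(rng.random((12, 12)), 1e-3)
        assert g.sum() == pytest.approx(0.0, abs=1e-10)


class TestStopMetric:
    def test_identical_images_give_zero(self):
        x = np.random.default_rng(0).random((4, 4))
        assert stop_metric(x, x) == 0.0

    def test_uniform_relative_change(self):
        x = np.full((5, 5), 1.0)
        assert stop_metric(x, 1.01 * x) == pytest.approx(100 * 0.01 / 1.01)

    def test_invariant_to_global_scaling(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((6, 6)), rng.random((6, 6))
        assert stop_metric(a, b) == pytest.approx(stop_metric(7 * a, 7 * b))

    def test_zero_current_image_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            stop_metric(np.ones((3, 3)), np.zeros((3, 3)))


class TestIsraSystem:
    def test_identity_system_converges_in_one_iteration(self):
        m = np.array([1.0, 0.0, 2.0, 3.0, 0.5])
        x, trace = isra_system(np.eye(5), m, x0=np.full(5, 2.0),
                               cfg=ReconConfig(max_iterations=1,
                                               stop_threshold=1e-15))
        assert np.array_equal(x, m)

    def test_matched_system_reaches_nnls_solution(self):
        rng = np.random.default_rng(3)
        A = rng.random((12, 8))
        x_true = rng.random(8)
        m = np.maximum(A @ x_true + 0.05 * rng.standard_normal(12), 0.0)
        x, trace = isra_system(A, m, cfg=ReconConfig(max_iterations=50_000,
                                                     stop_threshold=1e-9))
        _, res = nnls(A, m)
        obj = np.sum((A @ x - m) ** 2)
        assert obj <= res ** 2 * (1 + 1e-3) + 1e-12

    def test_matched_objective_is_monotone(self):
        rng = np.random.default_rng(7)
        A = rng.random((12, 8))
        m = np.maximum(A @ rng.random(8) + 0.1 * rng.standard_normal(12), 0)
        _, trace = isra_system(A, m, cfg=ReconConfig(max_iterations=500,
                                                     stop_threshold=1e-12))
        diffs = np.diff(trace.objective)
        assert np.all(diffs <= 1e-9 * np.abs(trace.objective[0]))

    def test_zero_backprojection_voxel_stays_zero(self):
        # a voxel unseen by the data (column of zeros) is driven to zero
        A = np.array([[1.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        m = np.array([1.0, 1.0, 2.0])
        x, _ = isra_system(A, m, x0=np.array([0.5, 0.5]),
                           cfg=ReconConfig(max_iterations=50,
                                           stop_threshold=1e-12))
        assert x[1] == 0.0
        assert x[0] == pytest.approx(1.0, rel=1e-3)

    def test_all_zero_data_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            isra_system(np.eye(3), np.zeros(3))

    def test_nonpositive_start_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            isra_system(np.eye(3), np.ones(3), x0=np.array([1.0, 0.0, 1.0]))


@pytest.fixture(scope="module")
def noisy_sparse_projection(small_phantom):
    geom = make_geometry(32, detector_count=96)
    return simulate_projections(small_phantom, geom, 1e4, seed=1)


@pytest.fixture(scope="module")
def x0_64():
    return VolumeImage(np.full((64, 64), 0.02), 0.1)


class TestIsraGeometry:
    def test_iterates_are_nonnegative(self, noisy_sparse_projection, x0_64):
        vol, _ = isra(noisy_sparse_projection, x0=x0_64,
                      cfg=ReconConfig(max_iterations=20, stop_threshold=1e-9))
        assert vol.values.min() >= 0.0

    def test_lambda_zero_reproduces_isra_bit_for_bit(
            self, noisy_sparse_projection, x0_64):
        cfg = ReconConfig(regularization_weight=0.0, max_iterations=15,
                          stop_threshold=1e-9)
        a, _ = isra(noisy_sparse_projection, x0=x0_64, cfg=cfg)
        b, _ = isra_tv(noisy_sparse_projection, x0=x0_64, cfg=cfg)
        assert np.array_equal(a.values, b.values)

    def test_tv_regularization_lowers_tv_energy(
            self, noisy_sparse_projection, x0_64):
        cfg = ReconConfig(max_iterations=150, stop_threshold=1e-9)
        plain, _ = isra(noisy_sparse_projection, x0=x0_64, cfg=cfg)
        reg, trace = isra_tv(noisy_sparse_projection, x0=x0_64, cfg=cfg)
        assert trace.n_iterations == 150
        assert reg.values.min() >= 0.0
        assert tv_energy(reg, cfg.tv_delta) < tv_energy(plain, cfg.tv_delta)

    def test_tv_energy_decreases_with_regularization_strength(
            self, noisy_sparse_projection, x0_64):
        # within the stable OSL window: no penalty > weak penalty > default
        # penalty in TV energy; far beyond the default the denominator
        # loses positivity and the clamped iteration stops being a
        # faithful TV limit, so no flat-image limit is asserted
        cfg = ReconConfig(max_iterations=150, stop_threshold=1e-9)
        plain, _ = isra(noisy_sparse_projection, x0=x0_64, cfg=cfg)
        weak_cfg = dataclasses.replace(cfg, regularization_weight=1e-4)
        weak, _ = isra_tv(noisy_sparse_projection, x0=x0_64, cfg=weak_cfg)
        default_cfg = dataclasses.replace(cfg, regularization_weight=1e-3)
        strong, trace = isra_tv(noisy_sparse_projection, x0=x0_64,
                                cfg=default_cfg)
        u_plain = tv_energy(plain, cfg.tv_delta)
        u_weak = tv_energy(weak, cfg.tv_delta)
        u_strong = tv_energy(strong, cfg.tv_delta)
        assert u_strong < 0.5 * u_plain
        assert u_strong < u_weak < u_plain
        assert sum(trace.clamped_denominators) == 0

    def test_sinogram_is_read_exactly_once(self, noisy_sparse_projection, x0_64):
        class CountingProjection(ProjectionData):
            reads = 0

            def __getattribute__(self, name):
                if name == "values":
                    CountingProjection.reads += 1
                return super().__getattribute__(name)

        proj = noisy_sparse_projection
        counting = CountingProjection.__new__(CountingProjection)
        for f, v in vars(proj).items():
            object.__setattr__(counting, f, v)
        CountingProjection.reads = 0
        isra(counting, x0=x0_64,
             cfg=ReconConfig(max_iterations=10, stop_threshold=1e-9))
        assert CountingProjection.reads == 1

    def test_default_start_image_reconstructs_on_fov_grid(
            self, noisy_sparse_projection):
        vol, trace = isra(noisy_sparse_projection,
                          cfg=ReconConfig(max_iterations=5,
                                          stop_threshold=1e-9))
        # default grid covers the detector FOV at 0.1 mm pitch
        assert vol.values.shape == (96, 96)
        assert vol.values.min() >= 0.0

    def test_zero_sinogram_is_degenerate(self):
        from sparsect.reconstruct import DegenerateDataError
        geom = make_geometry(8, detector_count=16)
        proj = ProjectionData(np.zeros((8, 16)), geom)
        with pytest.raises(DegenerateDataError):
            isra(proj)

    def test_trace_records_every_iteration(self, noisy_sparse_projection, x0_64):
        _, trace = isra(noisy_sparse_projection, x0=x0_64,
                        cfg=ReconConfig(max_iterations=12, stop_threshold=1e-9))
        assert trace.n_iterations == 12
        assert len(trace.objective) == 12
        assert len(trace.tv_energy) == 12
        assert not trace.converged

    def test_stopping_rule_halts_early(self, noisy_sparse_projection, x0_64):
        _, trace = isra(noisy_sparse_projection, x0=x0_64,
                        cfg=ReconConfig(max_iterations=500, stop_threshold=5.0))
        assert trace.converged
        assert trace.n_iterations < 500
        assert trace.stop_metric[-1] <= 5.0


@pytest.fixture(scope="module")
def disc_setup():
    geom = make_geometry(512, detector_count=288)
    n, pitch = 192, 0.1
    c = (np.arange(n) + 0.5) * pitch - n * pitch / 2
    x0, x1 = np.meshgrid(c, c, indexing="ij")
    r = np.hypot(x0, x1)
    disc = np.where(r <= 5.0, 0.03, 0.0)
    proj = forward_project(VolumeImage(disc, pitch), geom)
    template = VolumeImage(np.zeros((n, n)), pitch)
    return proj, template, disc, r


class TestFbp:
    def test_zero_sinogram_gives_zero_volume(self):
        geom = make_geometry(16, detector_count=32)
        proj = ProjectionData(np.zeros((16, 32)), geom)
        vol = fbp(proj, vol_template=VolumeImage(np.zeros((24, 24)), 0.1))
        assert np.allclose(vol.values, 0.0)

    def test_single_view_rejected(self):
        geom = make_geometry(1, detector_count=8)
        proj = ProjectionData(np.zeros((1, 8)), geom)
        with pytest.raises(ValueError, match="two views"):
            fbp(proj)

    def test_noiseless_disc_rmse_below_5_percent(self, disc_setup):
        proj, template, disc, r = disc_setup
        rec = fbp(proj, vol_template=template, window="ramp")
        fov = r <= 9.0
        rmse = np.sqrt(np.mean((rec.values[fov] - disc[fov]) ** 2))
        assert rmse <= 0.05 * 0.03

    def test_streak_variance_grows_with_subsampling(self, disc_setup):
        proj, template, disc, r = disc_setup
        out_region = (r > 6.0) & (r < 9.0)
        variances = []
        for factor in (1, 4, 8, 16):
            rec = fbp(subsample_views(proj, factor), vol_template=template,
                      window="hann")
            variances.append(np.var(rec.values[out_region]))
        assert all(b > a for a, b in zip(variances, variances[1:]))

    def test_linear_in_data(self):
        geom = make_geometry(32, detector_count=48)
        rng = np.random.default_rng(2)
        s1 = rng.random((32, 48))
        s2 = rng.random((32, 48))
        tmpl = VolumeImage(np.zeros((32, 32)), 0.1)
        lhs = fbp(ProjectionData(3 * s1 - s2, geom,
                                 negative_tolerance=np.inf),
                  vol_template=tmpl).values
        rhs = (3 * fbp(ProjectionData(s1, geom), vol_template=tmpl).values
               - fbp(ProjectionData(s2, geom), vol_template=tmpl).values)
        assert np.allclose(lhs, rhs, atol=1e-10)
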