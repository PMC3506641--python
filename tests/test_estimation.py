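"""Estimation pipeline: robust one-tensor least squares, initialization
geometry, the fascicle-matched spatial gradient, the MAP objective, the
F-test, and field fitting."""

import numpy as np
import pytest
from scipy import stats

from cuspmfm.estimation import (
    FitConfig,
    MFMField,
    UnderDeterminedError,
    estimate_sigma,
    fit_field,
    fit_single_tensor_ls,
    fit_voxel,
    ftest_select,
    initialize_mfm,
    map_objective,
    n_free_parameters,
    spatial_gradient_multitensor,
)
from cuspmfm.forward_model import MFMVoxel, add_rician_noise, predict_signal, predict_values, sigma_for_snr_db
from cuspmfm.gradients import GradientScheme, SchemeEntry, build_scheme
from cuspmfm.phantoms import crossing_grid_phantom
from cuspmfm.tensor_math import (
    axial_angle_deg,
    cylindrical_from_fa_trace,
    cylindrical_tensor,
    matrix_log_spd,
    principal_axis,
)


@pytest.fixture()
def single_tensor_signal(cusp35):
    l1, l2, _ = cylindrical_from_fa_trace(0.8, 2.1e-3)
    d = cylindrical_tensor([1.0, 0.4, -0.3], l1, l2)
    vox = MFMVoxel(s0=400.0, f_iso=0.0, fascicles=[(1.0, d)])
    return predict_values(vox, cusp35), d


class TestSingleTensorLS:
    def test_noise_free_recovery(self, cusp35, single_tensor_signal):
        y, d_true = single_tensor_signal
        d, s0 = fit_single_tensor_ls(y, cusp35)
        assert np.max(np.abs(d - d_true)) / np.max(np.abs(d_true)) < 1e-8
        assert s0 == pytest.approx(400.0, rel=1e-8)

    def test_robust_reweighting_noop_on_noise_free(self, cusp35, single_tensor_signal):
        y, _ = single_tensor_signal
        d0, _ = fit_single_tensor_ls(y, cusp35, n_robust_iter=0)
        d3, _ = fit_single_tensor_ls(y, cusp35, n_robust_iter=3)
        assert np.array_equal(d0, d3)

    def test_b0_only_scheme_underdetermined(self):
        scheme = GradientScheme([SchemeEntry((0, 0, 0), 0.0, "b0")] * 7, 1000.0)
        with pytest.raises(UnderDeterminedError):
            fit_single_tensor_ls(np.full(7, 100.0), scheme)

    def test_all_zero_signal_rejected(self, cusp35):
        with pytest.raises(ValueError):
            fit_single_tensor_ls(np.zeros(35), cusp35)


class TestInitialization:
    def _angle_between_first_two(self, ratio, config):
        lam = np.array([1.0, ratio, ratio * 0.5]) * 1e-3
        vox = initialize_mfm(np.diag(lam), 100.0, 2, config, 0)
        a1, a2 = (principal_axis(d) for d in vox.tensors)
        return axial_angle_deg(a1, a2)

    def test_prolate_gives_almost_parallel(self):
        # lambda2/lambda1 = 0.1 -> two tensors 2 x 4.5 = 9 degrees apart
        cfg = FitConfig(alpha=0.0, n_sweeps=0)
        assert self._angle_between_first_two(0.1, cfg) == pytest.approx(9.0, abs=1e-6)

    def test_oblate_gives_perpendicular(self):
        cfg = FitConfig(alpha=0.0, n_sweeps=0)
        assert self._angle_between_first_two(1.0, cfg) == pytest.approx(90.0, abs=1e-6)

    def test_third_tensor_seeded(self):
        cfg = FitConfig(alpha=0.0, n_sweeps=0, max_fascicles=3)
        a = initialize_mfm(np.diag([1.7, 0.4, 0.2]) * 1e-3, 100.0, 3, cfg, 5)
        b = initialize_mfm(np.diag([1.7, 0.4, 0.2]) * 1e-3, 100.0, 3, cfg, 5)
        assert np.array_equal(a.tensors[2], b.tensors[2])

    def test_fractions_initialized_per_config(self):
        cfg = FitConfig(alpha=0.0, n_sweeps=0, init_f_iso=0.15)
        vox = initialize_mfm(np.diag([1.7, 0.4, 0.2]) * 1e-3, 100.0, 2, cfg, 0)
        assert vox.f_iso == pytest.approx(0.15)
        assert [f for f, _ in vox.fascicles] == pytest.approx([0.425, 0.425])


def _uniform_log_field(shape, tensors_per_voxel):
    grid = np.empty(shape, dtype=object)
    for idx in np.ndindex(*shape):
        grid[idx] = [matrix_log_spd(t) for t in tensors_per_voxel]
    return grid


class TestSpatialGradient:
    def test_uniform_field_zero_gradient(self):
        t = [np.diag([1.7, 0.2, 0.2]) * 1e-3, np.diag([0.2, 1.7, 0.2]) * 1e-3]
        lf = _uniform_log_field((3, 3, 1), t)
        mask = np.ones((3, 3, 1), bool)
        for j in range(2):
            for axis in range(3):
                assert spatial_gradient_multitensor(lf, mask, (1, 1, 0), j, axis) == 0.0

    def test_most_similar_neighbor_pairing(self):
        # center {A, B}; both neighbors also carry A plus a distant tensor C:
        # fascicle A pairs with A on both sides, so its derivative vanishes
        # even though the naive same-index pairing would be non-zero
        a = matrix_log_spd(np.diag([1.7, 0.2, 0.2]) * 1e-3)
        b = matrix_log_spd(np.diag([0.2, 1.7, 0.2]) * 1e-3)
        b_near = matrix_log_spd(np.diag([0.21, 1.68, 0.2]) * 1e-3)
        c = matrix_log_spd(np.diag([5.0, 5.0, 5.0]) * 1e-3)
        lf = np.empty((3, 1, 1), dtype=object)
        lf[0, 0, 0] = [c, a]
        lf[1, 0, 0] = [a, b]
        lf[2, 0, 0] = [a, c]
        mask = np.ones((3, 1, 1), bool)
        # brute force over all pairings: min-distance partner of A is A itself
        assert spatial_gradient_multitensor(lf, mask, (1, 0, 0), 0, 0) == pytest.approx(0.0)
        # fascicle B has no similar neighbor: its matched partners are the
        # A tensors, giving the same (zero) central difference
        lf[0, 0, 0] = [c, b_near]
        expect = 0.5 * np.linalg.norm(a - b_near)
        assert spatial_gradient_multitensor(lf, mask, (1, 0, 0), 1, 0) == \
            pytest.approx(expect)

    def test_softmax_large_gamma_matches_exact_min(self, rng):
        tensors = [1e-3 * (m @ m.T + 3 * np.eye(3))
                   for m in rng.standard_normal((2, 3, 3))]
        lf = np.empty((3, 1, 1), dtype=object)
        for i in range(3):
            ms = rng.standard_normal((2, 3, 3))
            lf[i, 0, 0] = [matrix_log_spd(1e-3 * (m @ m.T + 3 * np.eye(3))) for m in ms]
        mask = np.ones((3, 1, 1), bool)
        for j in range(2):
            exact = spatial_gradient_multitensor(lf, mask, (1, 0, 0), j, 0, "exact-min")
            soft = spatial_gradient_multitensor(lf, mask, (1, 0, 0), j, 0, 1e6)
            assert soft == pytest.approx(exact, abs=1e-6)

    def test_one_sided_at_boundary_and_empty_neighborhood(self):
        t = [np.diag([1.0, 1.0, 1.0]) * 1e-3]
        lf = _uniform_log_field((2, 1, 1), t)
        mask = np.ones((2, 1, 1), bool)
        assert spatial_gradient_multitensor(lf, mask, (0, 0, 0), 0, 0) == 0.0
        assert spatial_gradient_multitensor(lf, mask, (0, 0, 0), 0, 1) == 0.0


class TestMapObjective:
    def _toy_field(self, scheme):
        phantom = crossing_grid_phantom(n_models=4, seed=8)
        grid = np.empty((2, 2, 1), dtype=object)
        for k, (_, vox) in enumerate(phantom.field.voxels()):
            grid[k // 2, k % 2, 0] = vox
        return MFMField(grid, np.ones((2, 2, 1), bool))

    def test_zero_residual_beta_zero_is_zero(self, cusp35):
        fld = self._toy_field(cusp35)
        data = np.zeros((2, 2, 1, 35))
        for idx, vox in fld.voxels():
            data[idx] = predict_values(vox, cusp35)
        cfg = FitConfig(alpha=1.0, K=1.0, n_sweeps=0)
        assert map_objective(fld, data, cusp35, cfg, beta=0.0) == pytest.approx(0.0)

    def test_prior_never_decreases_objective(self, cusp35):
        fld = self._toy_field(cusp35)
        data = np.zeros((2, 2, 1, 35))
        for idx, vox in fld.voxels():
            data[idx] = predict_values(vox, cusp35)
        cfg = FitConfig(alpha=1.0, K=1.0, n_sweeps=0)
        assert map_objective(fld, data, cusp35, cfg, 1.0) >= \
            map_objective(fld, data, cusp35, cfg, 0.0)

    def test_matches_brute_force_summation(self, cusp35):
        from cuspmfm.estimation import _phi, _spatial_derivative
        fld = self._toy_field(cusp35)
        rng = np.random.default_rng(0)
        data = np.zeros((2, 2, 1, 35))
        for idx, vox in fld.voxels():
            data[idx] = predict_values(vox, cusp35) + rng.normal(0, 5, 35)
        cfg = FitConfig(alpha=0.7, K=0.9, n_sweeps=0)
        beta = 0.6
        # independent term-by-term accumulation
        expect = 0.0
        lf = fld.log_tensors()
        for idx, vox in fld.voxels():
            r = predict_values(vox, cusp35) - data[idx]
            expect += float(r @ r)
            for j in range(vox.n_fascicles):
                g2 = sum(np.sum(_spatial_derivative(lf, fld.mask, idx, j, ax,
                                                    "exact-min") ** 2)
                         for ax in range(3))
                expect += beta * cfg.alpha * _phi(np.sqrt(g2) / cfg.K)
        assert map_objective(fld, data, cusp35, cfg, beta) == pytest.approx(
            expect, rel=1e-12)

    def test_misaligned_data_rejected(self, cusp35):
        fld = self._toy_field(cusp35)
        with pytest.raises(ValueError):
            map_objective(fld, np.zeros((2, 2, 1, 10)), cusp35,
                          FitConfig(alpha=0, n_sweeps=0), 0.0)


class TestFtest:
    def test_equal_rss_keeps_lower_order(self):
        assert ftest_select([10.0, 10.0], [10, 15], 35) == 1

    def test_hand_computed_toy(self):
        # F = ((10 - 2)/4) / (2/20) = 20 on F(4, 20)
        f = 20.0
        p = stats.f.sf(f, 4, 20)
        sel = ftest_select([10.0, 2.0], [4, 8], 28, alpha=p * 1.01)
        assert sel == 2
        sel = ftest_select([10.0, 2.0], [4, 8], 28, alpha=p * 0.99)
        assert sel == 1

    def test_selects_order_one_on_single_tensor_data(self, cusp35, fast_config):
        """Single-tensor data at 30 dB keeps model order 1 in >= 90% of
        seeded noise replicates."""
        l1, l2, _ = cylindrical_from_fa_trace(0.8, 2.1e-3)
        vox = MFMVoxel(s0=400.0, f_iso=0.1,
                       fascicles=[(0.9, cylindrical_tensor([1, 0.5, 0.3], l1, l2))])
        sigma = sigma_for_snr_db(400.0, 30.0)
        rng = np.random.default_rng(21)
        cfg = FitConfig(**{**fast_config.__dict__, "model_selection": True,
                           "max_fascicles": 2})
        wins = 0
        n_rep = 25
        for _ in range(n_rep):
            y = add_rician_noise(predict_signal(vox, cusp35), sigma, rng).values
            fld = fit_field(y[None, None, None, :], cusp35, cfg)
            wins += fld.grid[0, 0, 0].n_fascicles == 1
        assert wins / n_rep >= 0.9

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            ftest_select([5.0, 4.0], [8, 8], 35)


class TestFreeParameters:
    def test_cylindrical_tensor_has_four_parameters(self):
        # 4 per tensor + N fraction parameters
        assert n_free_parameters(1) == 5
        assert n_free_parameters(2) == 10
        assert n_free_parameters(3) == 15

    def test_unconstrained_tensor_has_six(self):
        assert n_free_parameters(2, cylindrical=False) == 14


class TestFitVoxelAndField:
    def test_fitted_voxel_is_valid_simplex_and_spd(self, cusp35, fast_config, rng):
        phantom = crossing_grid_phantom(n_models=1, seed=10)
        y = add_rician_noise(
            predict_signal(phantom.field.grid[0, 0, 0], cusp35), 12.0, rng).values
        vox, rss = fit_voxel(y, cusp35, 2, fast_config, 3)
        vox.validate()
        assert rss >= 0

    def test_no_b0_scheme_rejected(self, fast_config):
        entries = [SchemeEntry((1.0, 0.0, 0.0), 1000.0, "inner")] * 8
        scheme = GradientScheme(entries, 1000.0)
        with pytest.raises(ValueError):
            fit_field(np.full((1, 1, 1, 8), 50.0), scheme, fast_config)

    def test_single_shell_warning_logged(self, hardi35, fast_config, caplog):
        phantom = crossing_grid_phantom(n_models=1, scheme=hardi35, seed=10)
        data = phantom.signals(seed=2)
        import logging
        with caplog.at_level(logging.WARNING, logger="cuspmfm"):
            fit_field(data, hardi35, fast_config)
        assert any("single-shell" in r.message for r in caplog.records)

    def test_regularized_sweep_never_increases_local_objective(self, cusp35):
        phantom = crossing_grid_phantom(n_models=4, scheme=cusp35, seed=12)
        grid = np.empty((2, 2, 1), dtype=object)
        for k, (_, vox) in enumerate(phantom.field.voxels()):
            grid[k // 2, k % 2, 0] = vox
        truth = MFMField(grid, np.ones((2, 2, 1), bool))
        rng = np.random.default_rng(3)
        data = np.zeros((2, 2, 1, 35))
        for idx, vox in truth.voxels():
            data[idx] = add_rician_noise(predict_signal(vox, cusp35), 12.0, rng).values
        cfg_plain = FitConfig(alpha=0.0, n_sweeps=0, n_restarts=2, max_polish=2,
                              stage_maxfev=(200, 300, 400), seed=7)
        cfg_reg = FitConfig(alpha=1.0, n_sweeps=2, n_restarts=2, max_polish=2,
                            stage_maxfev=(200, 300, 400), seed=7)
        plain = fit_field(data, cusp35, cfg_plain)
        reg = fit_field(data, cusp35, cfg_reg)
        # at beta = 1 the regularized solution cannot lose to the plain one
        # on the regularized criterion it optimized
        k = cfg_reg.K or 1.0
        cfg_eval = FitConfig(alpha=1.0, K=k, n_sweeps=0)
        assert map_objective(reg, data, cusp35, cfg_eval, 1.0) <= \
            map_objective(plain, data, cusp35, cfg_eval, 1.0) + 1e-6


class TestSigmaEstimate:
    def test_recovers_simulated_noise_scale(self, cusp35):
        phantom = crossing_grid_phantom(n_models=40, scheme=cusp35, snr_db=30, seed=13)
        data = phantom.signals(seed=3)
        est = estimate_sigma(data, cusp35, phantom.field.mask)
        assert est == pytest.approx(phantom.sigma, rel=0.25)

    def test_needs_replicate_b0(self):
        scheme = GradientScheme([SchemeEntry((0, 0, 0), 0.0, "b0"),
                                 SchemeEntry((1, 0, 0), 1000.0, "inner")], 1000.0)
        with pytest.raises(ValueError):
            estimate_sigma(np.ones((1, 1, 1, 2)), scheme)
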