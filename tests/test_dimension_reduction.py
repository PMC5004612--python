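import numpy as np
import pytest

from respiro import (ConvolutionOperator, ImpulseResponse, PartitionPlan,
                     ProjectionSpec, SingularSystemError, TimeSeries,
                     add_noise, dr_solve_averaged, dr_solve_regularized,
                     dr_solve_sequential, dr_solve_single, eliminate_delay,
                     forward_convolve, pearson_correlation, sweep_m)
from respiro.dimension_reduction import (averaged_reconstruction_matrix,
                                         build_projection,
                                         reconstruction_matrix, shift_matrix)
from respiro.simulator import NoiseConfig


class TestProjection:
    def test_m1_is_identity(self):
        proj = build_projection(5, 1)
        np.testing.assert_array_equal(proj.L, np.eye(5))
        assert proj.pad == 0

    def test_m2_block_indicator(self):
        proj = build_projection(4, 2)
        np.testing.assert_array_equal(proj.L[:, 0], [1, 1, 0, 0])
        np.testing.assert_array_equal(proj.L[:, 1], [0, 0, 1, 1])

    @pytest.mark.parametrize("n_samples,m", [(12, 3), (20, 4), (17, 5)])
    def test_columns_orthogonal_with_squared_norm_m(self, n_samples, m):
        proj = build_projection(n_samples, m)
        np.testing.assert_allclose(proj.L.T @ proj.L, m * np.eye(proj.n))

    def test_padding_recorded(self):
        proj = build_projection(17, 5)
        assert proj.pad == 3 and proj.n_padded == 20 and proj.n == 4


class TestShiftMatrix:
    def test_shift_down_then_transpose_up(self, rng):
        x = rng.normal(size=8)
        S = shift_matrix(8, 2)
        np.testing.assert_array_equal(S @ x, np.r_[0, 0, x[:-2]])
        np.testing.assert_array_equal(S.T @ x, np.r_[x[2:], 0, 0])


class TestSingleSolve:
    def test_m1_invertible_noiseless_is_exact(self, rng, exp_kernel):
        n = 60
        u = rng.normal(size=n)
        y = TimeSeries(0.1, np.convolve(u, exp_kernel.h)[:n])
        sol = dr_solve_single(y, exp_kernel, ProjectionSpec(m=1))
        np.testing.assert_allclose(sol.u_hat.values, u, atol=1e-10)

    def test_window_aligned_input_recovered_exactly(self, rng, exp_kernel):
        n, m = 64, 4
        u = np.repeat(rng.normal(size=n // m), m)  # truth lies in the subspace
        y = TimeSeries(0.1, np.convolve(u, exp_kernel.h)[:n])
        sol = dr_solve_single(y, exp_kernel, ProjectionSpec(m=m))
        np.testing.assert_allclose(sol.u_hat.values, u, atol=1e-8)

    def test_matches_explicit_dense_assembly(self, rng, exp_kernel):
        n, m = 24, 3
        y = TimeSeries(0.1, rng.normal(size=n))
        sol = dr_solve_single(y, exp_kernel, ProjectionSpec(m=m))
        M = reconstruction_matrix(exp_kernel, n, m)
        np.testing.assert_allclose(sol.u_hat.values, M @ y.values, atol=1e-10)

    def test_singular_system_names_both_remedies(self, rng, delayed_kernel):
        y = TimeSeries(0.1, rng.normal(size=60))
        with pytest.raises(SingularSystemError, match="eliminate_delay"):
            dr_solve_single(y, delayed_kernel, ProjectionSpec(m=2))


class TestAveragedSolve:
    def test_m1_identical_to_single(self, rng, exp_kernel):
        y = TimeSeries(0.1, rng.normal(size=40))
        single = dr_solve_single(y, exp_kernel, ProjectionSpec(m=1))
        avg = dr_solve_averaged(y, exp_kernel, ProjectionSpec(m=1))
        np.testing.assert_array_equal(avg.u_hat.values, single.u_hat.values)

    def test_three_way_oracle_agreement(self, rng):
        # explicit M_bar assembly vs literal shift-solve-average loop vs
        # production implementation
        n, m = 60, 5
        hvals = rng.uniform(0.1, 1.0, 8)
        h = ImpulseResponse(0.1, hvals / hvals.sum())
        y = TimeSeries(0.1, np.convolve(rng.normal(size=n), h.h)[:n])

        explicit = averaged_reconstruction_matrix(h, n, m) @ y.values
        M = reconstruction_matrix(h, n, m)
        loop = np.mean([shift_matrix(n, k).T @ (M @ (shift_matrix(n, k)
                                                     @ y.values))
                        for k in range(m)], axis=0)
        prod = dr_solve_averaged(y, h, ProjectionSpec(m=m)).u_hat.values
        np.testing.assert_allclose(explicit, loop, atol=1e-10)
        np.testing.assert_allclose(prod, explicit, atol=1e-10)

    def test_recovers_noiseless_pulse_train(self, exp_kernel):
        from respiro import PulseTrainConfig, synth_pulse_train

        # windows (m=2) well inside the 2.5 s pulse width
        u = synth_pulse_train(PulseTrainConfig(frequency=0.2, n_pulses=3,
                                               start_time=5.0), 2000, 0.1)
        y = forward_convolve(u, exp_kernel)
        sol = dr_solve_averaged(y, exp_kernel, ProjectionSpec(m=2))
        ok = ~sol.diagnostics["low_confidence"]
        assert pearson_correlation(sol.u_hat.values[ok], u.values[ok]) >= 0.99

    def test_averaging_reduces_total_variation(self, exp_kernel):
        # input violating the piecewise-constant assumption (pulse edges
        # misaligned with the windows): the sliding average removes the
        # spurious jumps at window edges
        from respiro import PulseTrainConfig, synth_pulse_train

        u = synth_pulse_train(PulseTrainConfig(frequency=0.2, n_pulses=3,
                                               start_time=5.3), 600, 0.1)
        y = forward_convolve(u, exp_kernel)
        spec = ProjectionSpec(m=10)
        single = dr_solve_single(y, exp_kernel, spec)
        avg = dr_solve_averaged(y, exp_kernel, spec)
        ok = ~avg.diagnostics["low_confidence"]
        tv = lambda x: np.sum(np.abs(np.diff(x)))
        assert tv(avg.u_hat.values[ok]) <= tv(single.u_hat.values[ok])


class TestEliminateDelay:
    def test_trims_delay_and_records_offset(self, delayed_kernel, rng):
        y = TimeSeries(0.1, rng.normal(size=100))
        y_t, h_t, offset = eliminate_delay(y, delayed_kernel)
        assert offset == 10
        assert h_t.support_len == delayed_kernel.support_len - 10
        assert h_t.n0_delay == 0
        assert len(y_t) == 90
        np.testing.assert_array_equal(y_t.values, y.values[10:])

    def test_no_delay_is_a_noop_with_notice(self, exp_kernel, rng):
        y = TimeSeries(0.1, rng.normal(size=50))
        with pytest.warns(UserWarning, match="nothing to trim"):
            y2, h2, offset = eliminate_delay(y, exp_kernel)
        assert offset == 0 and y2 is y and h2 is exp_kernel

    def test_trimmed_solution_equals_ridge_limit(self, rng):
        # the trim removes the singularity without changing the solution:
        # compare against the gamma -> 0 ridge-stabilized untrimmed solve
        h = np.concatenate([np.zeros(4), np.exp(-np.arange(12) / 3.0)])
        ker = ImpulseResponse(0.1, h / h.sum(), n0_delay=4)
        n, m = 60, 2
        u = np.repeat(rng.normal(size=n // m), m)
        y = TimeSeries(0.1, np.convolve(u, ker.h)[:n])
        y_t, h_t, off = eliminate_delay(y, ker)
        trimmed = dr_solve_single(y_t, h_t, ProjectionSpec(m=m))
        ridge = dr_solve_regularized(
            y, ker, ProjectionSpec(m=m, use_averaging=False, gamma=1e-12,
                                   reg_kind="identity"))
        common = n - 2 * off  # windows observed by both systems
        np.testing.assert_allclose(trimmed.u_hat.values[:common],
                                   ridge.u_hat.values[:common], atol=1e-6)


class TestRegularizedSolve:
    def test_gamma_zero_rejected(self, exp_kernel, rng):
        y = TimeSeries(0.1, rng.normal(size=30))
        with pytest.raises(ValueError, match="dr_solve_single"):
            dr_solve_regularized(y, exp_kernel, ProjectionSpec(m=3))

    def test_vanishing_penalty_converges_to_plain_solve(self, rng, exp_kernel):
        n, m = 48, 4
        y = TimeSeries(0.1, rng.normal(size=n))
        plain = dr_solve_single(y, exp_kernel, ProjectionSpec(m=m))
        A_scale = np.linalg.norm(
            ConvolutionOperator(exp_kernel, n).dense(), 2) ** 2
        ridge = dr_solve_regularized(
            y, exp_kernel, ProjectionSpec(m=m, use_averaging=False,
                                          gamma=1e-12 * A_scale))
        np.testing.assert_allclose(ridge.u_hat.values, plain.u_hat.values,
                                   atol=1e-6)

    def test_penalty_dominated_limit_shrinks_solution(self, rng, exp_kernel):
        y = TimeSeries(0.1, rng.normal(size=48))
        sol = dr_solve_regularized(
            y, exp_kernel, ProjectionSpec(m=4, gamma=1e12,
                                          reg_kind="identity"))
        assert np.linalg.norm(sol.u_hat.values) < 1e-6 * np.linalg.norm(y.values)

    def test_moderate_ridge_survives_singular_instance(self, rng,
                                                       delayed_kernel):
        y = TimeSeries(0.1, rng.normal(size=60))
        spec0 = ProjectionSpec(m=2)
        with pytest.raises(SingularSystemError):
            dr_solve_single(y, delayed_kernel, spec0)
        sol = dr_solve_regularized(
            y, delayed_kernel, ProjectionSpec(m=2, gamma=1e-6))
        assert np.all(np.isfinite(sol.u_hat.values))


class TestSequentialSolve:
    def test_single_block_plan_equals_full_averaged(self, exp_kernel,
                                                    pulse_record):
        _, y = pulse_record
        spec = ProjectionSpec(m=4)
        full = dr_solve_averaged(y, exp_kernel, spec)
        seq = dr_solve_sequential(y, exp_kernel, spec,
                                  PartitionPlan(n=len(y), n_overlap=60))
        np.testing.assert_array_equal(seq.u_hat.values, full.u_hat.values)

    def test_agrees_with_single_shot_on_interior(self, exp_kernel):
        from respiro import PulseTrainConfig, synth_pulse_train

        u = synth_pulse_train(PulseTrainConfig(frequency=0.5), 3000, 0.1)
        y = forward_convolve(u, exp_kernel)
        spec = ProjectionSpec(m=4)
        full = dr_solve_averaged(y, exp_kernel, spec)
        seq = dr_solve_sequential(y, exp_kernel, spec,
                                  PartitionPlan(n=780, n_overlap=720))
        ok = ~seq.diagnostics["low_confidence"]
        rel = (np.linalg.norm((seq.u_hat.values - full.u_hat.values)[ok])
               / np.linalg.norm(full.u_hat.values[ok]))
        assert rel <= 0.02

    def test_noisy_correlation_close_to_single_shot(self, exp_kernel):
        from respiro import PulseTrainConfig, synth_pulse_train

        u = synth_pulse_train(PulseTrainConfig(frequency=0.5), 3000, 0.1)
        y = add_noise(forward_convolve(u, exp_kernel),
                      NoiseConfig(level=1.0, seed=8))
        spec = ProjectionSpec(m=8)
        full = dr_solve_averaged(y, exp_kernel, spec)
        seq = dr_solve_sequential(y, exp_kernel, spec,
                                  PartitionPlan(n=780, n_overlap=720))
        ok = ~seq.diagnostics["low_confidence"]
        r_full = pearson_correlation(full.u_hat.values[ok], u.values[ok])
        r_seq = pearson_correlation(seq.u_hat.values[ok], u.values[ok])
        assert abs(r_full - r_seq) <= 0.01


class TestMSweep:
    def test_single_value_grid_returns_it(self, exp_kernel, pulse_record):
        u, y = pulse_record
        res = sweep_m(y, u, exp_kernel, ms=(4,))
        assert res.best_m == 4

    def test_noise_pushes_best_m_up(self, exp_kernel, pulse_record):
        u, y = pulse_record
        ms = (1, 2, 4, 8, 16, 32)
        plan = PartitionPlan(n=400, n_overlap=100)
        clean = sweep_m(y, u, exp_kernel, ms=ms, plan=plan)
        noisy_y = add_noise(y, NoiseConfig(level=5.0, seed=4))
        noisy = sweep_m(noisy_y, u, exp_kernel, ms=ms, plan=plan)
        assert clean.best_m <= 2  # noiseless favors the finest windows
        assert noisy.best_m > clean.best_m
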