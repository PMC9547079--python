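import numpy as np
import pytest

import qubode as qb


def forward_euler(system, grid, y0):
    y = np.asarray(y0, dtype=float)
    out = [y.copy()]
    x = grid.start
    for _ in range(grid.n_steps):
        y = y + grid.dx * np.asarray(system.rhs(x, y))
        out.append(y.copy())
        x += grid.dx
    return np.array(out)


class TestLinearize:
    def test_linear_system_is_reproduced_exactly(self, harmonic_system):
        f0, jac = qb.linearize(harmonic_system, 0.0, np.array([0.3, -0.8]))
        for y in ([1.0, 0.0], [-2.0, 5.0], [0.25, 0.25]):
            y = np.array(y)
            exact = harmonic_system.rhs(0.0, y)
            assert np.allclose(f0 + jac @ (y - [0.3, -0.8]), exact, atol=1e-12)

    def test_morse_force_tangent_matches_analytic_derivative(self, morse_params, morse_system):
        r0 = 1.3
        f0, jac = qb.linearize(morse_system, 0.0, np.array([r0, 0.0]))
        f_exact = qb.morse_force(r0, morse_params)
        fprime = qb.morse_force_derivative(r0, morse_params)
        for dr in (-0.01, 0.004):
            lin = f0[1] + jac[1, 0] * dr
            ana = f_exact + fprime * dr
            assert lin == pytest.approx(ana, rel=1e-6)

    def test_constant_rhs_has_zero_linear_part(self):
        sys_const = qb.ODESystemSpec(n=1, rhs=lambda x, y: np.array([2.5]))
        f0, jac = qb.linearize(sys_const, 0.0, np.array([1.0]))
        assert f0 == pytest.approx([2.5])
        assert np.allclose(jac, [[0.0]], atol=1e-9)

    def test_finite_difference_jacobian_matches_analytic(self, morse_params):
        sys_nojac = qb.ODESystemSpec(
            n=2,
            rhs=lambda x, y: np.array(
                [y[1] / morse_params.mu, qb.morse_force(y[0], morse_params)]
            ),
        )
        _, jac_fd = qb.linearize(sys_nojac, 0.0, np.array([1.2, 0.5]))
        expect = np.array(
            [
                [0.0, 1.0 / morse_params.mu],
                [qb.morse_force_derivative(1.2, morse_params), 0.0],
            ]
        )
        assert np.allclose(jac_fd, expect, rtol=1e-5, atol=1e-9)

    def test_rhs_failure_carries_context(self):
        def bad(x, y):
            raise ValueError("boom")

        sys_bad = qb.ODESystemSpec(n=1, rhs=bad)
        with pytest.raises(RuntimeError, match="right-hand side"):
            qb.linearize(sys_bad, 0.0, np.array([1.0]))


class TestPropagateQP:
    def test_single_step_runs_reduce_to_forward_euler(self, morse_system):
        grid = qb.TimeGrid.from_total_time(40.0, 100)
        traj = qb.propagate(
            morse_system, grid, [1.3, 0.0], qb.PropagationConfig(solver="qp")
        )
        euler = forward_euler(morse_system, grid, [1.3, 0.0])
        assert np.abs(traj.values - euler).max() <= 1e-12

    def test_first_point_equals_initial_conditions_exactly(self, morse_system):
        grid = qb.TimeGrid.from_total_time(4.0, 10)
        traj = qb.propagate(
            morse_system, grid, [1.3, 0.0], qb.PropagationConfig(solver="qp")
        )
        assert traj.values[0].tolist() == [1.3, 0.0]

    def test_harmonic_error_shrinks_with_step(self, harmonic_system, harmonic_reference):
        errs = []
        for steps in (100, 400):
            grid = qb.TimeGrid.from_total_time(2 * np.pi, steps)
            traj = qb.propagate(
                harmonic_system, grid, [1.0, 0.0], qb.PropagationConfig(solver="qp")
            )
            ref = harmonic_reference(grid.times)
            errs.append(np.abs(traj.values[:, 0] - ref[:, 0]).max())
        assert errs[1] < errs[0] / 2

    def test_sequential_and_coupled_agree_at_single_step_runs(self, morse_system):
        grid = qb.TimeGrid.from_total_time(40.0, 100)
        seq = qb.propagate(
            morse_system, grid, [1.3, 0.0],
            qb.PropagationConfig(solver="qp", mode="sequential"),
        )
        cou = qb.propagate(
            morse_system, grid, [1.3, 0.0],
            qb.PropagationConfig(solver="qp", mode="coupled"),
        )
        assert np.abs(seq.values - cou.values).max() <= 1e-10

    def test_multi_step_runs_cover_grid_and_stay_consistent(self, harmonic_system,
                                                            harmonic_reference):
        grid = qb.TimeGrid.from_total_time(2 * np.pi, 100)
        traj = qb.propagate(
            harmonic_system, grid, [1.0, 0.0],
            qb.PropagationConfig(solver="qp", mode="coupled", m_per_run=4),
        )
        assert traj.values.shape == (101, 2)
        ref = harmonic_reference(grid.times)
        # first-order in dt: comparable to the one-step-per-run error level
        assert np.abs(traj.values[:, 0] - ref[:, 0]).max() < 0.3

    def test_gauss_seidel_variant_runs(self, morse_system):
        grid = qb.TimeGrid.from_total_time(4.0, 10)
        cfg = qb.PropagationConfig(solver="qp", mode="sequential", gauss_seidel=True)
        traj = qb.propagate(morse_system, grid, [1.3, 0.0], cfg)
        assert np.isfinite(traj.values).all()


class TestPropagateBinary:
    def test_exhaustive_backend_matches_qp_within_quantization(
        self, harmonic_system
    ):
        grid = qb.TimeGrid.from_total_time(np.pi, 50)
        scheme = qb.FixedPointScheme(6, 15)
        exh = qb.propagate(
            harmonic_system, grid, [1.0, 0.0],
            qb.PropagationConfig(solver="exhaustive", scheme=scheme),
        )
        ref = qb.propagate(
            harmonic_system, grid, [1.0, 0.0], qb.PropagationConfig(solver="qp")
        )
        bound = grid.n_steps * scheme.max_rounding_error * 10  # growth allowance
        assert np.abs(exh.values - ref.values).max() <= bound

    def test_saturation_aborts_with_step_index(self, morse_params):
        sys_spec = qb.make_system(morse_params)
        grid = qb.TimeGrid(0.0, 20.0, 2000)
        cfg = qb.PropagationConfig(
            solver="exhaustive", scheme=qb.FixedPointScheme(3, 4)
        )
        with pytest.raises(qb.SaturationError) as exc:
            qb.propagate(sys_spec, grid, [0.7, 0.0], cfg)
        assert 0 < exc.value.step <= 2000

    def test_out_of_range_initial_state_rejected(self, harmonic_system):
        cfg = qb.PropagationConfig(
            solver="exhaustive", scheme=qb.FixedPointScheme(2, 4)
        )
        grid = qb.TimeGrid.from_total_time(1.0, 10)
        with pytest.raises(qb.SaturationError):
            qb.propagate(harmonic_system, grid, [50.0, 0.0], cfg)


class TestScaling:
    def test_unit_factors_change_nothing(self, morse_system):
        grid = qb.TimeGrid.from_total_time(40.0, 50)
        scaled = qb.apply_scaling(morse_system, [1.0, 1.0])
        a = qb.propagate(morse_system, grid, [1.3, 0.0], qb.PropagationConfig())
        b = qb.propagate(scaled, grid, [1.3, 0.0], qb.PropagationConfig())
        assert np.abs(a.values - b.values).max() <= 1e-12

    def test_momentum_rescale_round_trip(self, morse_params, morse_system):
        s = np.array([1.0, qb.momentum_scale(morse_params)])
        scaled = qb.apply_scaling(morse_system, s)
        grid = qb.TimeGrid.from_total_time(400.0, 200)
        plain = qb.propagate(
            morse_system, grid, [1.3, 0.0], qb.PropagationConfig(solver="qp")
        )
        tilde = qb.propagate(
            scaled, grid, np.array([1.3, 0.0]) / s, qb.PropagationConfig(solver="qp")
        )
        assert np.abs(tilde.values * s - plain.values).max() <= 1e-9

    def test_harmonic_rescale_equalizes_residual_scales(self):
        # with s_p = mu*omega the two scaled equations have identical
        # coefficient magnitude: d r~/dt = omega p~, d p~/dt = -omega r~
        mu, k = 4.0, 9.0
        omega = np.sqrt(k / mu)
        sys_h = qb.ODESystemSpec(
            n=2,
            rhs=lambda x, y: np.array([y[1] / mu, -k * y[0]]),
            jac=lambda x, y: np.array([[0.0, 1.0 / mu], [-k, 0.0]]),
        )
        scaled = qb.apply_scaling(sys_h, [1.0, mu * omega])
        jac = scaled.jac(0.0, np.array([0.0, 0.0]))
        assert abs(jac[0, 1]) == pytest.approx(abs(jac[1, 0]), rel=1e-12)
        assert abs(jac[0, 1]) == pytest.approx(omega, rel=1e-12)

    def test_non_positive_factors_rejected(self, morse_system):
        with pytest.raises(ValueError):
            qb.apply_scaling(morse_system, [1.0, 0.0])


class TestGridAndConfig:
    @pytest.mark.parametrize("dx,n", [(-0.1, 10), (0.0, 10), (0.1, 0)])
    def test_invalid_grid_rejected(self, dx, n):
        with pytest.raises(ValueError):
            qb.TimeGrid(0.0, dx, n)

    def test_grid_from_total_time(self):
        grid = qb.TimeGrid.from_total_time(400.0, 1000)
        assert grid.dx == pytest.approx(0.4)
        assert grid.times[-1] == pytest.approx(400.0)
        assert len(grid.times) == 1001

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            qb.PropagationConfig(solver="quantum")
        with pytest.raises(ValueError):
            qb.PropagationConfig(mode="parallel")

    def test_trajectory_csv_round_trip(self, tmp_path, morse_system):
        import pandas as pd

        grid = qb.TimeGrid.from_total_time(4.0, 10)
        traj = qb.propagate(morse_system, grid, [1.3, 0.0], qb.PropagationConfig())
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time", "r_bohr", "p_au"]
        assert np.allclose(df["r_bohr"], traj.values[:, 0])
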