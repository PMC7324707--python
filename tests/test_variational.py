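import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medfuse.errors import ValidationError
from medfuse.structure_tensor import discrete_gradient
from medfuse.variational import (
    SolverConfig,
    discrete_divergence,
    fusion_energy,
    primal_dual_solve,
    project_dual,
)

from _oracles import naive_energy, subgradient_solve


class TestDivergence:
    def test_zero_field_zero_divergence(self):
        np.testing.assert_array_equal(
            discrete_divergence(np.zeros((2, 5, 5))), np.zeros((5, 5))
        )

    def test_adjoint_identity(self, rng):
        for _ in range(20):
            u = rng.random((16, 16))
            p = rng.standard_normal((2, 16, 16))
            lhs = float(np.sum(discrete_gradient(u) * p))
            rhs = -float(np.sum(u * discrete_divergence(p)))
            assert abs(lhs - rhs) < 1e-10

    def test_constant_horizontal_field_boundary_columns(self):
        c = 0.7
        p = np.zeros((2, 4, 6))
        p[0] = c
        div = discrete_divergence(p)
        np.testing.assert_allclose(div[:, 0], c)
        np.testing.assert_allclose(div[:, -1], -c)
        np.testing.assert_allclose(div[:, 1:-1], 0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_adjointness_property(self, seed):
        rng = np.random.default_rng(seed)
        h, w = int(rng.integers(2, 12)), int(rng.integers(2, 12))
        u = rng.random((h, w))
        p = rng.standard_normal((2, h, w))
        lhs = float(np.sum(discrete_gradient(u) * p))
        rhs = -float(np.sum(u * discrete_divergence(p)))
        assert abs(lhs - rhs) < 1e-10


class TestFusionEnergy:
    def test_global_minimum_is_zero(self, rng):
        u = rng.random((8, 8))
        assert fusion_energy(u, u, u, alpha_fid=5.0) == 0.0

    def test_vanishing_fidelity_leaves_regularizer(self, rng):
        f0, mr = rng.random((8, 8)), rng.random((8, 8))
        diff = discrete_gradient(f0) - discrete_gradient(mr)
        expected = float(np.sum(np.sqrt(diff[0] ** 2 + diff[1] ** 2)))
        assert fusion_energy(f0, f0, mr, alpha_fid=3.0) == pytest.approx(expected)

    def test_matches_naive_recomputation(self, rng):
        u, f0, mr = rng.random((4, 4)), rng.random((4, 4)), rng.random((4, 4))
        assert fusion_energy(u, f0, mr, alpha_fid=2.5) == pytest.approx(
            naive_energy(u, f0, mr, 2.5), abs=1e-12
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            fusion_energy(np.zeros((4, 4)), np.zeros((5, 4)), np.zeros((4, 4)), 1.0)


class TestProjectDual:
    def test_interior_point_unchanged(self):
        p = np.zeros((2, 1, 1))
        p[0, 0, 0], p[1, 0, 0] = 0.3, 0.4
        np.testing.assert_allclose(project_dual(p), p)

    def test_exterior_point_radially_projected(self):
        p = np.zeros((2, 1, 1))
        p[0, 0, 0], p[1, 0, 0] = 3.0, 4.0
        out = project_dual(p)
        np.testing.assert_allclose(out[:, 0, 0], [0.6, 0.8])

    def test_projection_idempotent(self, rng):
        p = rng.standard_normal((2, 8, 8)) * 3
        once = project_dual(p)
        np.testing.assert_allclose(project_dual(once), once, atol=1e-15)


class TestPrimalDualSolve:
    def test_identical_inputs_fixed_point(self, rng):
        img = rng.random((16, 16))
        u, trace = primal_dual_solve(img, img)
        np.testing.assert_allclose(u, img, atol=1e-12)
        assert trace.iterations_run == 1  # first tolerance check stops
        assert trace.energies[0] == pytest.approx(0.0, abs=1e-12)

    def test_fidelity_limit_pins_to_initializer(self, rng):
        f0, mr = rng.random((16, 16)), rng.random((16, 16))
        cfg = SolverConfig(alpha_fid=1e6, max_iter=200, tol=0.0)
        u, _ = primal_dual_solve(f0, mr, cfg)
        assert np.abs(u - f0).max() < 1e-3

    def test_final_energy_beats_subgradient_oracle(self, rng):
        cfg = SolverConfig(alpha_fid=8.0, max_iter=2000, tol=0.0)
        for _ in range(3):
            f0, mr = rng.random((8, 8)), rng.random((8, 8))
            u, trace = primal_dual_solve(f0, mr, cfg)
            oracle = subgradient_solve(f0, mr, 8.0, iters=3000)
            assert trace.energies[-1] <= oracle * (1 + 1e-4)

    def test_output_energy_not_above_initializer(self, rng):
        for _ in range(5):
            f0, mr = rng.random((12, 12)), rng.random((12, 12))
            u, _ = primal_dual_solve(f0, mr)
            assert fusion_energy(u, f0, mr, 8.0) <= fusion_energy(
                f0, f0, mr, 8.0
            ) + 1e-12

    def test_dual_feasibility_every_iteration(self, rng):
        # re-run the iteration manually, checking |p| <= 1 after each step
        from medfuse.structure_tensor import discrete_gradient as grad

        f0, mr = rng.random((10, 10)), rng.random((10, 10))
        cfg = SolverConfig()
        u, u_bar = f0.copy(), f0.copy()
        p = np.zeros((2, 10, 10))
        gmr = grad(mr)
        atau = cfg.alpha_fid * cfg.tau
        for _ in range(50):
            p = project_dual(p + cfg.sigma * (grad(u_bar) - gmr))
            assert np.sqrt(p[0] ** 2 + p[1] ** 2).max() <= 1 + 1e-12
            u_next = (u + cfg.tau * discrete_divergence(p) + atau * f0) / (1 + atau)
            u_bar = 2 * u_next - u
            u = u_next

    def test_energy_moving_average_descends(self, default_pair):
        from medfuse.weighted_fusion import initial_fusion

        ct, mr, _ = default_pair
        f0, _, _ = initial_fusion(ct, mr)
        _, trace = primal_dual_solve(f0, mr, SolverConfig(max_iter=200, tol=0.0))
        e = np.asarray(trace.energies)
        avg = np.convolve(e, np.ones(10) / 10, mode="valid")
        # the cold-started dual lets the primal energy climb briefly; after
        # that transient the smoothed energy must descend monotonically
        burn_in = 20
        assert np.all(np.diff(avg[burn_in:]) <= 1e-8 * max(1.0, e[0]))
        assert e[-1] < e[0]

    def test_constant_shift_shifts_solution(self, rng):
        f0 = rng.random((12, 12)) * 0.4
        mr = rng.random((12, 12)) * 0.4
        c = 0.3
        cfg = SolverConfig(max_iter=400, tol=0.0)
        u1, _ = primal_dual_solve(f0, mr, cfg)
        u2, _ = primal_dual_solve(f0 + c, mr + c, cfg)
        # the shift identity holds up to the final [0,1] clip; compare
        # where neither solution was clipped
        unclipped = (u1 > 0) & (u1 < 1) & (u2 > 0) & (u2 < 1)
        assert unclipped.mean() > 0.9
        np.testing.assert_allclose(u2[unclipped], u1[unclipped] + c, atol=1e-8)

    def test_unstable_steps_rejected(self):
        with pytest.raises(ValidationError, match="stability"):
            SolverConfig(sigma=0.5, tau=0.5).validate()

    def test_max_iter_zero_returns_initializer(self, rng):
        f0, mr = rng.random((8, 8)), rng.random((8, 8))
        u, trace = primal_dual_solve(f0, mr, SolverConfig(max_iter=0))
        np.testing.assert_array_equal(u, f0)
        assert trace.iterations_run == 0
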