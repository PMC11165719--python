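"""Finite-difference engine: Laplacian, Euler stepping, growth, masks."""

import numpy as np
import pytest

from sevilletor.lattice import (
    GridState,
    NumericalScheme,
    ParameterFields,
    discrete_laplacian,
    euler_step,
    grow_posterior,
    run_simulation,
    _integrate,
)


def ghost_cell_laplacian(f: np.ndarray, mode: str) -> np.ndarray:
    """Independent oracle: pad with mirror/wrap ghost cells, apply stencil."""
    pad_mode = "edge" if mode == "zero-flux" else "wrap"
    p = np.pad(f, 1, mode=pad_mode)
    return p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * f


def zero_params(N, D=0.3):
    """Reaction fully disabled: only diffusion of u remains."""
    return ParameterFields(
        k1=np.zeros(N), k3=np.zeros(N), k4=np.zeros(N), k2=0.0, D=D, saturation=0.0
    )


class TestLaplacian:
    @pytest.mark.parametrize("mode", ["zero-flux", "periodic"])
    def test_constant_field_is_zero(self, mode):
        f = np.full((7, 5), 3.17)
        np.testing.assert_array_equal(discrete_laplacian(f, 1.0, mode), 0.0)

    @pytest.mark.parametrize("mode", ["zero-flux", "periodic"])
    def test_matches_ghost_cell_oracle(self, mode):
        rng = np.random.default_rng(0)
        for _ in range(100):
            shape = tuple(rng.integers(2, 12, 2))
            f = rng.normal(size=shape)
            ours = discrete_laplacian(f, 1.0, mode)
            np.testing.assert_allclose(ours, ghost_cell_laplacian(f, mode), atol=1e-12)

    def test_bottom_left_corner_formula(self):
        """At the (0, 0) corner, mirrored ghosts reduce the stencil to
        f[1,0] + f[0,1] - 2 f[0,0]; hand-check on a fixed 3x3 field."""
        f = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
        lap = discrete_laplacian(f, 1.0, "zero-flux")
        assert lap[0, 0] == pytest.approx(f[1, 0] + f[0, 1] - 2.0 * f[0, 0])

    def test_dx_scaling(self):
        f = np.random.default_rng(1).normal(size=(6, 6))
        np.testing.assert_allclose(
            discrete_laplacian(f, 0.5), discrete_laplacian(f, 1.0) * 4.0
        )

    def test_masked_cells_act_as_internal_walls(self):
        f = np.zeros((5, 5))
        f[2, 2] = 1.0
        mask = np.ones((5, 5), dtype=bool)
        mask[2, 2] = False
        lap = discrete_laplacian(f, 1.0, "zero-flux", mask)
        assert lap[2, 2] == 0.0
        # the unmasked neighbour of the wall sees no flux from it
        assert lap[1, 2] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            discrete_laplacian(np.zeros((3, 3)), 1.0, "zero-flux", np.ones((2, 2), bool))


class TestEulerStep:
    def test_zero_field_stays_zero(self):
        g = GridState(np.zeros((6, 6)), np.zeros((6, 6)))
        p = ParameterFields(k1=np.ones(6), k3=np.ones(6), k4=np.ones(6))
        out = euler_step(g, p, NumericalScheme())
        np.testing.assert_array_equal(out.u, 0.0)
        np.testing.assert_array_equal(out.v, 0.0)

    @pytest.mark.parametrize("mode", ["zero-flux", "periodic"])
    def test_pure_diffusion_conserves_mass(self, mode):
        rng = np.random.default_rng(5)
        g = GridState(rng.normal(size=(12, 12)), np.zeros((12, 12)), boundary_mode=mode)
        p = zero_params(12)
        s = NumericalScheme(dt=0.1)
        total0 = g.u.sum()
        for _ in range(200):
            g = euler_step(g, p, s)
            assert abs(g.u.sum() - total0) <= 1e-10 * abs(total0)

    def test_homogeneous_grid_follows_single_cell_trajectory(self):
        """With identical cells the diffusion term vanishes and every cell
        integrates the pure reaction path."""
        from sevilletor.dynamics import simulate_two_cells
        from sevilletor.core import KineticParams, PhasePoint

        k = KineticParams(k1=1.0, D=0.0)
        ref = simulate_two_cells(
            k, init=(PhasePoint(0.3, -0.2), PhasePoint(0.3, -0.2)), duration=5.0, dt=0.01
        )
        g = GridState(np.full((8, 8), 0.3), np.full((8, 8), -0.2))
        p = ParameterFields(k1=np.ones(8), k3=np.ones(8), k4=np.ones(8), D=0.3)
        s = NumericalScheme(dt=0.01)
        for i in range(500):
            g = euler_step(g, p, s)
        assert np.ptp(g.u) == 0.0  # still perfectly homogeneous
        np.testing.assert_allclose(g.u[0, 0], ref.cellA[-1, 0], rtol=1e-12)
        np.testing.assert_allclose(g.v[0, 0], ref.cellA[-1, 1], rtol=1e-12)

    def test_jit_kernel_matches_reference_step(self):
        rng = np.random.default_rng(9)
        g = GridState(rng.normal(size=(9, 7)), rng.normal(size=(9, 7)))
        g.mask[4, 3] = False
        p = ParameterFields(
            k1=rng.uniform(0, 3, 9), k3=rng.uniform(0.5, 2, 9), k4=rng.uniform(0.5, 2, 9)
        )
        s = NumericalScheme(dt=0.01)
        ref = euler_step(g, p, s)
        jit = _integrate(g, p, s, 1)
        np.testing.assert_allclose(jit.u, ref.u, rtol=1e-13, atol=1e-15)
        np.testing.assert_allclose(jit.v, ref.v, rtol=1e-13, atol=1e-15)

    def test_masked_cells_frozen_forever(self):
        rng = np.random.default_rng(2)
        g = GridState(rng.normal(size=(10, 10)), rng.normal(size=(10, 10)))
        g.mask[3:6, 3:6] = False
        held = g.u[3:6, 3:6].copy()
        p = ParameterFields(k1=np.ones(10), k3=np.ones(10), k4=np.ones(10))
        out = _integrate(g, p, NumericalScheme(dt=0.01), 300)
        np.testing.assert_array_equal(out.u[3:6, 3:6], held)

    def test_divergence_aborts_with_diagnostic(self):
        g = GridState(np.full((4, 4), 1e200), np.zeros((4, 4)))
        p = ParameterFields(k1=np.ones(4), k3=np.ones(4), k4=np.ones(4), D=0.0)
        with pytest.raises(FloatingPointError):
            euler_step(g, p, NumericalScheme(dt=10.0, dx=100.0))

    def test_stability_bound_enforced(self):
        with pytest.raises(ValueError):
            NumericalScheme(dt=1.0).check_stability(D=0.3)


class TestGrowth:
    def test_append_copies_posterior_column(self):
        rng = np.random.default_rng(4)
        g = GridState(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
        p = ParameterFields(k1=np.arange(5.0), k3=np.ones(5), k4=np.ones(5))
        g2, p2 = grow_posterior(g, p)
        assert g2.Lx == 6
        np.testing.assert_array_equal(g2.u[-1], g.u[-1])
        np.testing.assert_array_equal(g2.v[-1], g.v[-1])
        assert p2.k1[-1] == p.k1[-1]

    def test_posterior_anchored_profile_translates_with_tip(self):
        from sevilletor.models import load_preset, build_R

        preset = load_preset("cws", Lx0=20, posterior_zone=5, middle_zone=8)
        before = build_R(preset, 20)
        after = build_R(preset, 21)
        # the tip plateau is unchanged and the profile translates with it
        assert after[-1] == pytest.approx(before[-1])
        np.testing.assert_allclose(after[1:], before, atol=1e-12)

    def test_no_growth_keeps_domain_static(self):
        g = GridState(np.zeros((6, 4)), np.zeros((6, 4)))
        p = ParameterFields(k1=np.ones(6), k3=np.ones(6), k4=np.ones(6))
        s = NumericalScheme(dt=0.01, duration=5.0, snapshot_interval=1.0, growth_period=0.0)
        rec = run_simulation(g, p, s, seed=0)
        assert rec.final[0].shape == (6, 4)

    def test_growth_adds_columns_on_schedule(self):
        g = GridState(np.zeros((6, 4)), np.zeros((6, 4)))
        p = ParameterFields(k1=np.ones(6), k3=np.ones(6), k4=np.ones(6))
        s = NumericalScheme(dt=0.01, duration=10.0, snapshot_interval=1.0, growth_period=2.0)
        rec = run_simulation(g, p, s, seed=0)
        assert rec.final[0].shape[0] == 6 + 4  # events at t=2,4,6,8


class TestRunSimulation:
    def test_identical_seed_bit_identical(self):
        from sevilletor.models import NoiseSpec

        def one():
            rng = np.random.default_rng(123)
            g = GridState(rng.uniform(-0.1, 0.1, (8, 6)), rng.uniform(-0.1, 0.1, (8, 6)))
            p = ParameterFields(k1=np.full(8, 2.0), k3=np.ones(8), k4=np.ones(8))
            s = NumericalScheme(dt=0.01, duration=8.0, snapshot_interval=1.0, growth_period=2.0)
            return run_simulation(g, p, s, noise=NoiseSpec(), seed=99)

        a, b = one(), one()
        assert a.times == b.times
        for x, y in zip(a.u_snapshots, b.u_snapshots):
            np.testing.assert_array_equal(x, y)
        assert a.config_hash == b.config_hash

    def test_divergent_run_preserves_partial_record(self):
        g = GridState(np.full((4, 4), 5.0), np.zeros((4, 4)))
        p = ParameterFields(k1=np.full(4, 4.0), k3=np.ones(4), k4=np.ones(4), D=0.0)
        s = NumericalScheme(dt=0.9, duration=50.0, snapshot_interval=0.9)
        rec = run_simulation(g, p, s, seed=0)
        assert rec.diverged
        assert len(rec.u_snapshots) >= 1

    def test_frozen_patterns_at_high_k1(self, regime_records):
        """k1=4 from noise freezes: the last two snapshots are identical
        to float precision, and k1=3 ends spatially homogeneous."""
        rec4 = regime_records[(4.0, 0)]
        np.testing.assert_allclose(rec4.u_snapshots[-1], rec4.u_snapshots[-2], atol=1e-9)
        rec3 = regime_records[(3.0, 0)]
        assert rec3.u_snapshots[-1].std() < 1e-6
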