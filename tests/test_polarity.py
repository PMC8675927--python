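import numpy as np
import pytest

from epifold.polarity import (PolarityParams, MembraneField, StabilityError,
                              bazooka_peak_position, cytosolic_concentration,
                              initial_condition, integrate_to_steady_state,
                              reaction_rates, rescale_for_length_change,
                              step_rd)


def make_field(n=64, L=2.7, a=0.45, ell=1.8, bc="reflect"):
    z = np.zeros(n)
    return MembraneField(L=L, a=a, ell=ell, A=z.copy(), P=z.copy(), B=z.copy(), bc=bc)


PSI = 6.24


class TestCytosolicPool:
    def test_empty_membrane_returns_totals(self):
        p = PolarityParams()
        Ac, Pc, Bc = cytosolic_concentration(make_field(), p, PSI)
        assert (Ac, Pc, Bc) == (p.A_total, p.P_total, p.B_total)

    def test_uniform_field_exhausts_pool(self):
        p = PolarityParams()
        f = make_field()
        f.P[:] = p.P_total / PSI
        assert cytosolic_concentration(f, p, PSI)[1] == pytest.approx(0.0, abs=1e-9)

    def test_matches_trapezoid_average_oracle(self):
        rng = np.random.default_rng(11)
        p = PolarityParams()
        f = make_field(n=256)
        f.A[:] = rng.uniform(0, 200, 256)
        # independent oracle: trapezoid integral of the cell-centred samples,
        # with the half-node end segments treated as constant
        s = f.s
        inner = np.trapezoid(f.A, s)
        mean = (inner + 0.5 * f.ds * (f.A[0] + f.A[-1])) / f.L
        expected = p.A_total - PSI * mean
        Ac, _, _ = cytosolic_concentration(f, p, PSI)
        assert Ac == pytest.approx(expected, rel=1e-12)


class TestReactionRates:
    def test_zero_membrane_gives_pure_association(self):
        p = PolarityParams()
        f = make_field()
        RA, RP, RB = reaction_rates(f, p, (p.A_total, p.P_total, p.B_total))
        assert np.allclose(RA, p.kon_A * p.A_total)
        assert np.allclose(RP, p.kon_P * p.P_total)
        assert np.allclose(RB, p.kon_B * p.B_total)

    def test_no_association_means_pure_loss(self):
        p = PolarityParams(kon_A=0.0, kon_P=0.0, kon_B=0.0)
        f = make_field()
        rng = np.random.default_rng(2)
        f.A[:] = rng.uniform(1, 100, f.n_nodes)
        f.P[:] = rng.uniform(1, 100, f.n_nodes)
        f.B[:] = rng.uniform(1, 100, f.n_nodes)
        for R in reaction_rates(f, p, (0.0, 0.0, 0.0)):
            assert (R <= 0).all()

    def test_single_node_scalar_arithmetic_oracle(self):
        p = PolarityParams()
        f = make_field(n=1)
        A, P, B = 100.0, 50.0, 10.0
        f.A[0], f.P[0], f.B[0] = A, P, B
        Ac, Pc, Bc = 600.0, 400.0, 900.0
        RA, RP, RB = reaction_rates(f, p, (Ac, Pc, Bc))
        assert RA[0] == pytest.approx(
            p.kon_A * (1 + p.k_AB * B ** p.eps) * Ac - p.koff_A * A
            - p.k_AP * P ** p.alpha * A, rel=1e-14)
        assert RP[0] == pytest.approx(
            p.kon_P * Pc - p.koff_P * P - p.k_PA * A ** p.beta * P, rel=1e-14)
        assert RB[0] == pytest.approx(
            p.kon_B * Bc - p.koff_B * B - p.k_BA * A ** p.gamma * B
            - p.k_BP * P ** p.zeta * B, rel=1e-14)


class TestStepping:
    def test_stability_bound_enforced(self):
        p = PolarityParams()
        f = make_field(n=512)
        dt_bad = 0.51 * f.ds ** 2 / p.max_D
        with pytest.raises(StabilityError):
            step_rd(f, p, PSI, dt_bad)

    def test_uniform_profile_without_reactions_is_stationary(self):
        p = PolarityParams(kon_A=0, koff_A=0, k_AB=0, k_AP=0, kon_P=0,
                           koff_P=0, k_PA=0, kon_B=0, koff_B=0, k_BA=0, k_BP=0)
        f = make_field()
        f.A[:] = 42.0
        out = step_rd(f, p, PSI, 0.05, n_steps=100)
        assert np.allclose(out.A, 42.0, atol=1e-12)

    @pytest.mark.parametrize("bc", ["reflect", "periodic"])
    def test_pure_diffusion_conserves_membrane_amount(self, bc):
        p = PolarityParams(kon_A=0, koff_A=0, k_AB=0, k_AP=0, kon_P=0,
                           koff_P=0, k_PA=0, kon_B=0, koff_B=0, k_BA=0, k_BP=0)
        f = make_field(n=128, bc=bc)
        f.B[60] = 1000.0  # delta spike
        amount0 = f.B.sum() * f.ds
        out = step_rd(f, p, PSI, 0.05, n_steps=10_000)
        assert out.B.sum() * out.ds == pytest.approx(amount0, rel=1e-12)
        assert out.B.max() < 0.1 * 1000.0  # spike has spread out

    def test_diffusion_matches_finer_grid_reference(self):
        """FTCS on a smooth profile agrees with a 4x finer grid at first order."""
        p = PolarityParams(kon_A=0, koff_A=0, k_AB=0, k_AP=0, kon_P=0,
                           koff_P=0, k_PA=0, kon_B=0, koff_B=0, k_BA=0, k_BP=0)
        L = 2.7
        T = 50.0

        def run(n):
            f = make_field(n=n, L=L)
            f.A[:] = 100 + 50 * np.cos(np.pi * f.s / L)  # even profile, no-flux OK
            dt = 0.2 * f.ds ** 2 / p.max_D
            out = step_rd(f, p, PSI, dt, n_steps=int(round(T / dt)))
            return out

        coarse = run(64)
        fine = run(256)
        fine_on_coarse = np.interp(coarse.s, fine.s, fine.A)
        assert np.abs(coarse.A - fine_on_coarse).max() < 0.05


class TestRescaling:
    def test_identity_and_halving(self):
        f = make_field()
        f.A[:] = 10.0
        same = rescale_for_length_change(f, f.L, f.L)
        assert np.array_equal(same.A, f.A)
        halved = rescale_for_length_change(f, f.L, f.L / 2)
        assert np.allclose(halved.A, 20.0)
        assert halved.L == pytest.approx(f.L / 2)

    def test_membrane_amount_is_conserved(self):
        rng = np.random.default_rng(5)
        f = make_field(n=128)
        f.B[:] = rng.uniform(0, 50, 128)
        amount0 = f.B.sum() * f.ds
        out = rescale_for_length_change(f, f.L, 3.917)
        assert out.B.sum() * out.ds == pytest.approx(amount0, rel=1e-12)

    def test_nonpositive_length_rejected(self):
        f = make_field()
        with pytest.raises(ValueError):
            rescale_for_length_change(f, f.L, 0.0)


class TestInitialCondition:
    def test_heaviside_construction(self):
        p = PolarityParams()
        f = initial_condition(512, 2.7, 0.45, 1.8, p, PSI)
        assert np.all(f.B[f.s >= 0.45] == 0.0)
        assert np.all(f.B[f.s < 0.45] > 0)
        # half the Bazooka pool on the membrane, A and P fully cytosolic
        Ac, Pc, Bc = cytosolic_concentration(f, p, PSI)
        assert Bc == pytest.approx(p.B_total / 2, rel=1e-10)
        assert Ac == p.A_total and Pc == p.P_total

    def test_uniform_style_has_no_spatial_variance(self):
        p = PolarityParams()
        f = initial_condition(64, 2.7, 0.45, 1.8, p, PSI, style="uniform")
        for arr in (f.A, f.P, f.B):
            assert arr.std() <= 1e-12 * max(arr.max(), 1.0)


class TestPeakPosition:
    def test_peak_at_known_node(self):
        f = make_field(n=100, L=1.0, a=0.1)
        f.B[30] = 5.0
        s_star, ell = bazooka_peak_position(f)
        assert s_star == pytest.approx((30 + 0.5) / 100)
        assert ell == pytest.approx(s_star - 0.1)

    def test_tie_breaks_to_apical_most_node(self):
        f = make_field(n=100, L=1.0, a=0.1)
        f.B[[20, 70]] = 5.0
        s_star, _ = bazooka_peak_position(f)
        assert s_star == pytest.approx((20 + 0.5) / 100)

    def test_all_zero_peak_is_an_error(self):
        with pytest.raises(ValueError):
            bazooka_peak_position(make_field())


class TestSteadyState:
    def test_already_steady_profile_converges_immediately(self, polarized_steady):
        f, params, cs = polarized_steady
        out, ok = integrate_to_steady_state(f, params, cs.psi, dt=0.05,
                                            tol=1e-7, check_every=2000)
        assert ok
        assert np.abs(out.B - f.B).max() < 1e-3

    def test_polarized_profile_structure(self, polarized_steady):
        """A peaks apically, P basolaterally, B in a single interior peak between."""
        f, params, cs = polarized_steady
        s = f.s
        assert s[np.argmax(f.A)] < cs.a                    # aPKC apical
        s_star, ell_dom = bazooka_peak_position(f)
        assert cs.a < s_star < cs.a + cs.ell               # junction on lateral side
        assert s[np.argmax(f.P)] > s_star                  # Par-1 basal of the peak
        assert ell_dom > 0
        # single interior peak: one sign change of the discrete gradient of B
        grad_sign = np.sign(np.diff(f.B))
        changes = np.count_nonzero(np.diff(grad_sign[grad_sign != 0]))
        assert changes == 1

    def test_mass_conservation_identity_along_integration(self, polarized_steady):
        f, params, cs = polarized_steady
        out = step_rd(f, params, cs.psi, 0.05, n_steps=500)
        for total, arr in [(params.A_total, out.A), (params.P_total, out.P),
                           (params.B_total, out.B)]:
            cyto = total - cs.psi * arr.mean()
            assert cs.psi * arr.mean() + cyto == pytest.approx(total, abs=1e-12 * total)

    def test_peak_position_robust_to_tighter_tolerance(self, polarized_steady):
        f, params, cs = polarized_steady
        tighter, ok = integrate_to_steady_state(f, params, cs.psi, dt=0.05,
                                                tol=1e-10)
        assert ok
        s1, _ = bazooka_peak_position(f)
        s2, _ = bazooka_peak_position(tighter)
        assert abs(s2 - s1) <= f.ds + 1e-12
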