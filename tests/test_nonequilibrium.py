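"""Nonstationary AFS functionals and the time-dependent measures of
selection built on them."""

import math

import numpy as np
import pytest
from scipy import integrate

from neqprf import (
    GammaDFE,
    ModelParams,
    SelectionRegime,
    SizeHistory,
    afs_functional,
    afs_functional_multi,
    equilibrium_functional,
    f_pw,
    fixation_prob,
    fixation_rate,
    fixations_t,
    omega_bar,
    pi_equilibrium,
    pi_n_gamma_t,
    pi_n_t,
    pi_s_t,
    pin_pis_ratio,
    simulate_poisson_field,
)
from neqprf.nonequilibrium import compute_measure_series


@pytest.fixture(scope="module")
def dfe12():
    return GammaDFE.from_mean(0.15, 2500.0)


class TestPiS:
    def test_before_change(self):
        h = SizeHistory.single_change(1000, 1.0, 4.0)
        assert pi_s_t(h, 1.0, 0.3) == pytest.approx(2.0)
        assert pi_s_t(h, 1.0, 1.0) == pytest.approx(2.0)

    def test_long_run_limit(self):
        h = SizeHistory.single_change(1000, 1.0, 4.0)
        assert pi_s_t(h, 1.0, 500.0) == pytest.approx(8.0, rel=1e-9)

    def test_one_relaxation_time_after_change(self):
        kappa = 0.5
        h = SizeHistory.single_change(1000, 1.0, kappa)
        expected = 2 * kappa + 2 * (1 - kappa) * math.exp(-1.0)
        assert pi_s_t(h, 1.0, 1.0 + kappa) == pytest.approx(expected, rel=1e-12)

    def test_continuity_at_change(self):
        h = SizeHistory.single_change(1000, 2.0, 0.1)
        assert pi_s_t(h, 1.0, 2.0) == pytest.approx(
            pi_s_t(h, 1.0, 2.0 + 1e-9), rel=1e-6
        )


class TestAfsFunctional:
    def test_no_change_matches_equilibrium(self, pde_engine):
        h = SizeHistory.single_change(1000, 1.0, 1.0)
        r = SelectionRegime(-1.0, 1.0)
        for t in (0.5, 3.0):
            a = afs_functional(f_pw, -1.0, h, 1.0, t, pde_engine)
            b = equilibrium_functional(f_pw, r, 1.0, t)
            assert a.total == pytest.approx(b.total, rel=1e-6)

    def test_left_continuity_at_change(self, pde_engine):
        h = SizeHistory.single_change(1000, 1.0, 4.0)
        at_star = afs_functional(f_pw, -2.0, h, 1.0, 1.0, pde_engine)
        just_after = afs_functional(f_pw, -2.0, h, 1.0, 1.0 + 1e-6, pde_engine)
        assert just_after.total == pytest.approx(at_star.total, rel=1e-4)

    @pytest.mark.parametrize("kappa", [0.25, 4.0])
    def test_neutral_matches_pi_s_closed_form(self, pde_engine, kappa):
        h = SizeHistory.single_change(1000, 1.0, kappa)
        for t in (0.5, 1.5, 3.0, 8.0):
            res = afs_functional(f_pw, 0.0, h, 1.0, t, pde_engine)
            poly = res.polymorphic_mass + res.transient_mass
            assert poly == pytest.approx(pi_s_t(h, 1.0, t), abs=2e-4)


class TestAfsMulti:
    def test_single_change_reduction_is_exact(self, pde_engine):
        h = SizeHistory.single_change(1000, 1.0, 4.0)
        for gamma in (0.0, -2.0):
            for t in (0.5, 3.0):
                a = afs_functional(f_pw, gamma, h, 1.0, t, pde_engine)
                b = afs_functional_multi(f_pw, gamma, h, 1.0, t, pde_engine)
                assert b.total == a.total

    def test_constant_kappa_is_time_invariant(self, pde_engine):
        h = SizeHistory(1000, ((1.0, 1.0), (2.0, 1.0)))
        vals = [
            afs_functional_multi(f_pw, -1.0, h, 1.0, t, pde_engine)
            for t in (0.5, 1.5, 3.0)
        ]
        poly = [v.polymorphic_mass + v.transient_mass for v in vals]
        assert max(poly) - min(poly) < 1e-9

    def test_two_epoch_neutral_matches_field_simulator(self, pde_engine):
        h = SizeHistory(200, ((1.0, 2.0), (2.0, 0.5)))
        t_checks = [0.5, 1.5, 2.5, 3.5, 5.0]
        analytic = np.array(
            [
                afs_functional_multi(f_pw, 0.0, h, 1.0, t, pde_engine).polymorphic_mass
                + afs_functional_multi(f_pw, 0.0, h, 1.0, t, pde_engine).transient_mass
                for t in t_checks
            ]
        )
        params = ModelParams(theta=1.0, N=200, tstar=1.0, t_present=5.0)
        reps = 40
        emp = np.zeros((reps, len(t_checks)))
        for rep in range(reps):
            res = simulate_poisson_field(
                params, h, SelectionRegime(0.0, 1.0), 5.0, seed=500 + rep
            )
            idx = [int(np.argmin(np.abs(res.times - t))) for t in t_checks]
            emp[rep] = res.functional[idx]
        mean = emp.mean(axis=0)
        se = emp.std(axis=0, ddof=1) / math.sqrt(reps)
        assert np.all(np.abs(mean - analytic) < 3 * se + 0.05 * analytic)


class TestPiN:
    def test_before_change_is_ancestral_average(self, pde_engine, dfe12):
        h = SizeHistory.single_change(1000, 1.0, 4.0)
        val = pi_n_t(dfe12, h, 1.0, 0.5, pde_engine, n_nodes=12)
        expected = dfe12.expectation(
            lambda v: pi_equilibrium(SelectionRegime(float(v), 1.0), 1.0), n_nodes=12
        )
        assert val == pytest.approx(expected, rel=1e-10)

    def test_long_run_reaches_new_equilibrium(self, pde_engine, dfe12):
        kappa = 4.0
        h = SizeHistory.single_change(1000, 1.0, kappa)
        val = pi_n_t(dfe12, h, 1.0, 120.0, pde_engine, n_nodes=12)
        expected = dfe12.expectation(
            lambda v: pi_equilibrium(SelectionRegime(float(v), kappa), 1.0), n_nodes=12
        )
        assert val == pytest.approx(expected, rel=2e-3)

    def test_no_change_is_constant(self, pde_engine, dfe12):
        h = SizeHistory.single_change(1000, 1.0, 1.0)
        vals = pi_n_t(dfe12, h, 1.0, np.array([0.5, 2.0, 10.0]), pde_engine, n_nodes=12)
        assert np.ptp(vals) < 1e-8

    def test_ratio_is_pointwise_division(self):
        assert pin_pis_ratio(1.0, 2.0) == 0.5
        with pytest.raises(ValueError):
            pin_pis_ratio(1.0, 0.0)


class TestFixations:
    def test_linear_before_change(self, pde_engine):
        h = SizeHistory.single_change(1000, 2.0, 4.0)
        gamma = -3.0
        om1 = fixation_rate(SelectionRegime(gamma, 1.0))
        for t in (0.5, 2.0):
            assert fixations_t(gamma, h, 1.5, t, pde_engine) == pytest.approx(
                1.5 * om1 * t, rel=1e-12
            )

    def test_neutral_no_change_is_theta_t(self, pde_engine):
        h = SizeHistory.single_change(1000, 1.0, 1.0)
        for t in (0.5, 5.0, 20.0):
            assert fixations_t(0.0, h, 1.0, t, pde_engine) == pytest.approx(t, abs=1e-8)

    def test_nondecreasing(self, pde_engine):
        h = SizeHistory.single_change(1000, 1.0, 0.25)
        ts = np.linspace(0.0, 10.0, 41)
        z = fixations_t(-1.0, h, 1.0, ts, pde_engine)
        assert np.all(np.diff(z) >= -1e-10)

    def test_long_run_offset_matches_q_integral(self, pde_engine):
        # Z(t) - theta[om1 t* + omk (t - t*)] tends to the constant
        # theta * int q_{gamma,kappa}(y) [om1 psi1 - omk psik] dy
        gamma, kappa, tstar = -2.0, 4.0, 1.0
        h = SizeHistory.single_change(1000, tstar, kappa)
        t_big = 60.0
        om1 = fixation_rate(SelectionRegime(gamma, 1.0))
        omk = fixation_rate(SelectionRegime(gamma, kappa))
        z = fixations_t(gamma, h, 1.0, t_big, pde_engine)
        offset = z - (om1 * tstar + omk * (t_big - tstar))

        def integrand(y):
            q = fixation_prob(y, SelectionRegime(gamma, kappa))
            br = (
                2 * fixation_prob(1 - y, SelectionRegime(gamma, 1.0))
                - 2 * kappa * fixation_prob(1 - y, SelectionRegime(gamma, kappa))
            ) / (y * (1 - y))
            return q * br

        exact, _ = integrate.quad(integrand, 0, 1, limit=200)
        assert offset == pytest.approx(exact, rel=1e-3, abs=1e-6)


class TestOmegaBar:
    def test_before_change_is_ancestral_average(self, pde_engine, dfe12):
        h = SizeHistory.single_change(1000, 1.0, 4.0)
        val = omega_bar(dfe12, h, 1.0, 0.5, pde_engine, n_nodes=12)
        expected = dfe12.expectation(
            lambda v: fixation_rate(SelectionRegime(float(v), 1.0)), n_nodes=12
        )
        assert val == pytest.approx(expected, rel=1e-9)

    def test_long_run_approaches_new_average(self, pde_engine, dfe12):
        kappa = 0.25
        h = SizeHistory.single_change(1000, 1.0, kappa)
        val = omega_bar(dfe12, h, 1.0, 400.0, pde_engine, n_nodes=12)
        expected = dfe12.expectation(
            lambda v: fixation_rate(SelectionRegime(float(v), kappa)), n_nodes=12
        )
        assert val == pytest.approx(expected, rel=2e-2)

    def test_no_change_is_constant(self, pde_engine, dfe12):
        h = SizeHistory.single_change(1000, 1.0, 1.0)
        vals = omega_bar(dfe12, h, 1.0, np.array([0.5, 2.0, 10.0]), pde_engine, n_nodes=12)
        assert np.ptp(vals) < 1e-9


class TestMeasureSeries:
    def test_columns_and_invariants(self, pde_engine_fast, dfe12):
        h = SizeHistory.single_change(1000, 1.0, 4.0)
        ts = np.round(np.arange(0.0, 6.01, 0.5), 10)
        df = compute_measure_series(dfe12, h, 1.0, ts, pde_engine_fast, n_nodes=8)
        for col in ("pi_n", "pi_s", "pin_pis", "z_n", "z_s", "omega_bar", "omega_w"):
            assert col in df.columns
        assert np.all(df["pi_s"] > 0)
        assert np.all(np.diff(df["z_s"]) >= -1e-10)
        assert np.all(np.diff(df["z_n"]) >= -1e-10)
        assert df.attrs["engine"] == "pde"
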