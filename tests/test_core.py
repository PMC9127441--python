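"""Equilibrium building blocks: fixation probability/rate, spectrum density,
equilibrium functionals and diversity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neqprf import (
    SelectionRegime,
    equilibrium_functional,
    f_fix,
    f_pw,
    fixation_prob,
    fixation_rate,
    omega_weighted,
    pi_equilibrium,
    sfs_density,
    sfs_intensity,
)

GAMMAS = [-100.0, -10.0, -1.0, -0.1]
KAPPAS = [0.1, 1.0, 4.0]


class TestFixationProb:
    def test_neutral_is_identity(self):
        y = np.linspace(0, 1, 11)
        np.testing.assert_allclose(fixation_prob(y, SelectionRegime(0.0, 2.0)), y)

    @pytest.mark.parametrize("gamma,kappa", [(-1, 1), (-50, 0.1), (3, 2), (-1000, 4)])
    def test_absorbing_endpoints(self, gamma, kappa):
        r = SelectionRegime(gamma, kappa)
        assert fixation_prob(0.0, r) == 0.0
        assert fixation_prob(1.0, r) == 1.0

    def test_direct_evaluation(self):
        # q(0.5) at gamma=-1, kappa=1 equals (1-e)/(1-e^2)
        expected = (1.0 - math.e) / (1.0 - math.e**2)
        assert fixation_prob(0.5, SelectionRegime(-1.0, 1.0)) == pytest.approx(expected, rel=1e-12)

    @given(
        gamma=st.floats(-1000, 50),
        kappa=st.floats(0.1, 4.0),
        y=st.lists(st.floats(0, 1), min_size=2, max_size=8),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_cdf_like(self, gamma, kappa, y):
        r = SelectionRegime(gamma, kappa)
        ys = np.sort(np.asarray(y))
        qs = np.asarray(fixation_prob(ys, r))
        assert np.all(np.isfinite(qs))
        assert np.all(np.diff(qs) >= -1e-12)
        assert np.all((qs >= 0) & (qs <= 1))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            fixation_prob(1.2, SelectionRegime(-1.0, 1.0))
        with pytest.raises(ValueError):
            SelectionRegime(-1.0, 0.0)
        with pytest.raises(ValueError):
            SelectionRegime(math.inf, 1.0)


class TestFixationRate:
    def test_neutral_value(self):
        for kappa in KAPPAS:
            assert fixation_rate(SelectionRegime(0.0, kappa)) == 1.0

    def test_continuity_at_zero(self):
        for g in (1e-9, -1e-9, 1e-7, -1e-7):
            assert fixation_rate(SelectionRegime(g, 1.0)) == pytest.approx(1.0, abs=1e-6)
        # tighter near the switch point
        assert fixation_rate(SelectionRegime(1e-10, 1.0)) == pytest.approx(1.0, abs=1e-10)

    def test_direct_evaluation(self):
        assert fixation_rate(SelectionRegime(-1.0, 1.0)) == pytest.approx(
            2.0 / (math.e**2 - 1.0), rel=1e-12
        )

    def test_depends_only_on_product(self):
        for g, k in [(-2.5, 1.6), (-100.0, 0.3), (0.7, 3.0)]:
            assert fixation_rate(SelectionRegime(g, k)) == fixation_rate(
                SelectionRegime(g * k, 1.0)
            )

    @given(g1=st.floats(-500, 20), g2=st.floats(-500, 20))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_gamma(self, g1, g2):
        lo, hi = sorted([g1, g2])
        assert fixation_rate(SelectionRegime(lo, 1.0)) <= fixation_rate(
            SelectionRegime(hi, 1.0)
        ) + 1e-12

    def test_strong_selection_underflows_gracefully(self):
        w = fixation_rate(SelectionRegime(-1000.0, 4.0))
        assert 0.0 <= w < 1e-300
        assert math.isfinite(w)


class TestSfsDensity:
    def test_neutral_limit(self):
        assert sfs_density(0.5, SelectionRegime(0.0, 2.0)) == pytest.approx(8.0)
        # gamma -> 0 through the general expression
        assert sfs_density(0.5, SelectionRegime(1e-12, 2.0)) == pytest.approx(8.0)

    def test_direct_evaluation(self):
        expected = (math.e - 1.0) / 0.25
        assert sfs_density(0.5, SelectionRegime(-1.0, 1.0)) == pytest.approx(expected, rel=1e-12)

    def test_rejects_boundary(self):
        with pytest.raises(ValueError):
            sfs_density(0.0, SelectionRegime(-1.0, 1.0))
        with pytest.raises(ValueError):
            sfs_density(1.0, SelectionRegime(-1.0, 1.0))

    def test_intensity_identity(self):
        # omega * psi == sfs_intensity where psi is representable
        y = np.linspace(0.05, 0.95, 7)
        for g in (-5.0, -0.5, 2.0):
            r = SelectionRegime(g, 2.0)
            np.testing.assert_allclose(
                fixation_rate(r) * np.asarray(sfs_density(y, r)),
                sfs_intensity(y, r),
                rtol=1e-10,
            )

    def test_stability_over_simulated_range(self):
        y = np.linspace(1e-6, 1 - 1e-6, 101)
        for g in np.linspace(-1000, 0, 21):
            for k in (0.1, 1.0, 4.0):
                vals = sfs_intensity(y, SelectionRegime(g, k))
                # graceful underflow to 0 deep in the deleterious tail is fine
                assert np.all(np.isfinite(vals)) and np.all(vals >= 0)


class TestEquilibriumFunctional:
    def test_neutral_pairwise_mass(self):
        for kappa in KAPPAS:
            res = equilibrium_functional(f_pw, SelectionRegime(0.0, kappa), theta=1.3, t=0.0)
            assert res.polymorphic_mass == pytest.approx(2 * 1.3 * kappa, rel=1e-10)
            assert res.fixation_mass == 0.0

    def test_fixation_indicator(self):
        r = SelectionRegime(-2.0, 1.0)
        res = equilibrium_functional(f_fix, r, theta=2.0, t=5.0)
        assert res.polymorphic_mass == 0.0
        assert res.fixation_mass == pytest.approx(2.0 * fixation_rate(r) * 5.0)

    def test_matches_closed_form_diversity(self):
        res = equilibrium_functional(f_pw, SelectionRegime(-1.0, 1.0), theta=1.0, t=0.0)
        assert res.polymorphic_mass == pytest.approx(4 * (1 / (1 - math.e**2) + 0.5), rel=1e-10)

    @pytest.mark.parametrize("gamma", GAMMAS)
    @pytest.mark.parametrize("kappa", KAPPAS)
    def test_quadrature_vs_closed_form_grid(self, gamma, kappa):
        r = SelectionRegime(gamma, kappa)
        quad = equilibrium_functional(f_pw, r, theta=1.0, t=0.0).polymorphic_mass
        closed = pi_equilibrium(r, 1.0)
        assert quad == pytest.approx(closed, rel=1e-8)


class TestPiEquilibrium:
    def test_neutral_limit(self):
        assert pi_equilibrium(SelectionRegime(0.0, 3.0), 1.5) == pytest.approx(2 * 1.5 * 3.0)

    def test_strong_selection_vanishes(self):
        assert pi_equilibrium(SelectionRegime(-1e6, 1.0), 1.0) < 1e-5

    def test_series_branch_is_continuous(self):
        # straddle the series/direct switch at |2 gamma kappa| = 1e-3
        lo = pi_equilibrium(SelectionRegime(-0.0005 * (1 - 1e-10), 1.0), 1.0)
        hi = pi_equilibrium(SelectionRegime(-0.0005 * (1 + 1e-10), 1.0), 1.0)
        assert lo == pytest.approx(hi, rel=1e-9)


class TestOmegaWeighted:
    def test_endpoints(self):
        assert omega_weighted(1.0, 1.0, 0.9, 0.3) == pytest.approx(0.9)
        assert omega_weighted(1e9, 1.0, 0.9, 0.3) == pytest.approx(0.3, abs=1e-8)

    def test_arithmetic(self):
        assert omega_weighted(2.0, 1.0, 1.0, 0.5) == pytest.approx(0.75)

    def test_rejects_bad_times(self):
        with pytest.raises(ValueError):
            omega_weighted(0.5, 1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            omega_weighted(1.0, 0.0, 1.0, 0.5)
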