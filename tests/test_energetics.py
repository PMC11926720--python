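import math

import numpy as np
import pytest

from nanonuc import energetics, eos
from nanonuc.constants import K_BOLTZMANN
from nanonuc.errors import NoNucleationDriveError, SuperStabilizedError

GAMMA_L = 27.0 / 256.0


class TestDimensionlessWork:
    def test_unit_barrier_without_elasticity(self):
        assert energetics.dimensionless_work(1.0, 0.0) == pytest.approx(1.0)

    def test_equilibrium_anchor(self):
        # at gamma = 1/16 the stable minimum X = 2 sits at zero work
        assert energetics.dimensionless_work(2.0, 1.0 / 16.0) == pytest.approx(0.0, abs=1e-14)

    def test_degenerate_barrier(self):
        w = energetics.dimensionless_work(4.0 / 3.0, GAMMA_L)
        assert w == pytest.approx(32.0 / 27.0, rel=1e-14)

    def test_vectorized(self):
        X = np.array([0.0, 1.0, 2.0])
        w = energetics.dimensionless_work(X, 0.0)
        assert w == pytest.approx([0.0, 1.0, -4.0])


class TestStationaryPoints:
    def test_no_elasticity(self):
        X_CR, X_SCR, regime = energetics.stationary_points(0.0)
        assert X_CR == 1.0 and X_SCR is None
        assert regime == energetics.REGIME_NO_ELASTICITY

    def test_degenerate(self):
        X_CR, X_SCR, regime = energetics.stationary_points(GAMMA_L)
        assert X_CR == pytest.approx(4.0 / 3.0, abs=1e-10)
        assert regime == energetics.REGIME_DEGENERATE

    def test_equilibrium_gamma(self):
        X_CR, X_SCR, regime = energetics.stationary_points(1.0 / 16.0)
        assert X_SCR == pytest.approx(2.0, abs=1e-10)
        # remaining real root of the deflated cubic X^3 + 2X^2 + 4X - 8
        cubic_root = min(r.real for r in np.roots([1, 2, 4, -8]) if abs(r.imag) < 1e-12)
        assert X_CR == pytest.approx(cubic_root, abs=1e-10)
        assert regime == energetics.REGIME_BISTABLE

    def test_super_stabilized(self):
        X_CR, X_SCR, regime = energetics.stationary_points(0.2)
        assert X_CR is None and X_SCR is None
        assert regime == energetics.REGIME_SUPER_STABILIZED

    def test_ordering_in_bistable_regime(self):
        for gamma in np.linspace(0.01, GAMMA_L * 0.98, 25):
            X_CR, X_SCR, _ = energetics.stationary_points(gamma)
            assert 1.0 < X_CR < 4.0 / 3.0 < X_SCR

    def test_brute_force_oracle(self):
        # grid extremization of w(X) vs the quartic root solver
        rng = np.random.default_rng(42)
        X = np.linspace(0.0, 6.0, 1_000_001)
        for gamma in rng.uniform(0.01, GAMMA_L * 0.99, size=50):
            w = energetics.dimensionless_work(X, gamma)
            interior = slice(1, -1)
            is_max = (w[1:-1] >= w[:-2]) & (w[1:-1] >= w[2:])
            is_min = (w[1:-1] <= w[:-2]) & (w[1:-1] <= w[2:])
            maxima = X[interior][is_max]
            minima = X[interior][is_min]
            maxima = maxima[(maxima > 1e-3) & (maxima < 5.9)]
            minima = minima[(minima > 1e-3) & (minima < 5.9)]
            X_CR, X_SCR, _ = energetics.stationary_points(gamma)
            assert abs(maxima[0] - X_CR) < 1e-5
            assert abs(minima[0] - X_SCR) < 1e-5

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            energetics.stationary_points(-0.1)


class TestClosedFormAnchors:
    def test_coalescence(self):
        gamma_l, X_l = energetics.coalescence_point()
        assert gamma_l == pytest.approx(GAMMA_L, abs=1e-10)
        assert X_l == pytest.approx(4.0 / 3.0, abs=1e-10)

    def test_equilibrium(self):
        gamma_n, X_n = energetics.equilibrium_point()
        assert gamma_n == pytest.approx(1.0 / 16.0, abs=1e-10)
        assert X_n == pytest.approx(2.0, abs=1e-10)


class TestBarrier:
    def test_monotone_in_gamma(self):
        gammas = np.linspace(0.0, GAMMA_L, 60)
        barriers = []
        for g in gammas:
            X_CR, _, _ = energetics.stationary_points(g)
            barriers.append(energetics.dimensionless_work(X_CR, g))
        barriers = np.array(barriers)
        assert np.all(np.diff(barriers) > 0)
        assert barriers[0] == pytest.approx(1.0)
        assert np.all(barriers >= 1.0)

    def test_super_stabilized_error(self):
        with pytest.raises(SuperStabilizedError):
            energetics.elastic_barrier(6.8e-3, 1e9, 140e-9, 0.694e6, 0.5e6)


class TestGammaParameter:
    def test_zero_without_confinement(self):
        assert energetics.gamma_parameter(6.8e-3, 0.0, 140e-9, 7e5, -4.5e6) == 0.0

    def test_paper_scale_value(self):
        # frozen from direct arithmetic; documents negligibility at defaults
        gamma = energetics.gamma_parameter(5.5e-3, 4e5, 140e-9, 0.0, 5.2e6)
        assert gamma == pytest.approx(2.654e-7, rel=1e-3)

    def test_scalings(self):
        base = energetics.gamma_parameter(5e-3, 4e5, 140e-9, 7e5, -4e6)
        assert energetics.gamma_parameter(5e-3, 8e5, 140e-9, 7e5, -4e6) == \
            pytest.approx(2 * base)
        assert energetics.gamma_parameter(5e-3, 4e5, 280e-9, 7e5, -4e6) == \
            pytest.approx(base / 8)

    def test_divergence(self):
        with pytest.raises(NoNucleationDriveError):
            energetics.gamma_parameter(5e-3, 4e5, 140e-9, 1e5, 1e5)


class TestCriticalRadiusAndWork:
    def test_radius_value(self):
        R = energetics.critical_radius_unconfined(6.81e-3, 0.694e6, -3.77e6)
        assert R == pytest.approx(2 * 6.81e-3 / 4.464e6, rel=1e-12)
        assert R == pytest.approx(3.05e-9, rel=1e-2)

    def test_radius_halves(self):
        r1 = energetics.critical_radius_unconfined(6.81e-3, 0.694e6, -3.77e6)
        r2 = energetics.critical_radius_unconfined(6.81e-3, 0.694e6 * 2 + 3.77e6, -3.77e6)
        assert r2 == pytest.approx(r1 / 2, rel=1e-9)

    def test_no_drive_error(self):
        with pytest.raises(NoNucleationDriveError):
            energetics.critical_radius_unconfined(6.81e-3, 1e5, 1e5)

    def test_work_value(self):
        W = energetics.critical_work(6.81e-3, 0.694e6, -3.77e6)
        assert W == pytest.approx(2.655e-19, rel=1e-3)

    def test_inverse_square(self):
        W1 = energetics.critical_work(6.81e-3, 1e6, -4e6)
        W2 = energetics.critical_work(6.81e-3, 6e6, -4e6)
        assert W2 == pytest.approx(W1 / 4, rel=1e-12)

    def test_barrier_identity_at_zero_gamma(self):
        # 16 pi s^3 / (3 dP^2) == (4 pi / 3) s (2s/dP)^2
        rng = np.random.default_rng(7)
        for _ in range(20):
            s = rng.uniform(1e-3, 1e-2)
            dP = rng.uniform(1e6, 8e6)
            R = energetics.critical_radius_unconfined(s, dP, 0.0)
            assert energetics.unconfined_barrier(s, R) == \
                pytest.approx(energetics.critical_work(s, dP, 0.0), rel=1e-12)


class TestDimensionalConsistency:
    def test_work_assembly_identity(self):
        # surface + bulk + elastic dimensional work equals W1wo * w(X; gamma)
        rng = np.random.default_rng(11)
        for _ in range(30):
            sigma1 = rng.uniform(2e-3, 9e-3)
            K = rng.uniform(0.0, 1e6)
            R20 = rng.uniform(5e-8, 1e-6)
            dP = rng.uniform(1e6, 8e6)  # P1 - P2wo
            gamma = energetics.gamma_parameter(sigma1, K, R20, dP, 0.0)
            Rstar = energetics.critical_radius_unconfined(sigma1, dP, 0.0)
            W1wo = energetics.unconfined_barrier(sigma1, Rstar)
            V20 = 4 * math.pi * R20**3 / 3
            for X in rng.uniform(0.1, 2.5, size=5):
                R1 = X * Rstar
                V1 = 4 * math.pi * R1**3 / 3
                W_dim = (4 * math.pi * R1**2 * sigma1
                         - V1 * dP + K * V1**2 / (2 * V20))
                assert W_dim == pytest.approx(
                    W1wo * energetics.dimensionless_work(X, gamma), rel=1e-10)


class TestKineticPrefactor:
    def test_value(self, pfp):
        J0 = energetics.kinetic_prefactor(6.81e-3, 310.0, pfp)
        assert J0 == pytest.approx(2.557e38, rel=1e-3)

    def test_sqrt_scaling(self, pfp):
        J0 = energetics.kinetic_prefactor(2e-3, 310.0, pfp)
        J0_quad = energetics.kinetic_prefactor(8e-3, 310.0, pfp)
        assert J0_quad == pytest.approx(2 * J0, rel=1e-12)

    def test_rejects_nonpositive(self, pfp):
        with pytest.raises(ValueError):
            energetics.kinetic_prefactor(0.0, 310.0, pfp)


class TestNucleationRate:
    def test_rate_prefactor_consistency(self, pfp, pspin_310):
        from nanonuc import interfaces
        J, state = energetics.nucleation_rate(-4e6, 310.0, interfaces.default_gases(),
                                              pfp, pspin=pspin_310)
        assert J == pytest.approx(state.J0 * math.exp(
            -state.W_star / (K_BOLTZMANN * 310.0)), rel=1e-12)
        assert J <= state.J0

    def test_monotone_in_tension(self, pfp, pspin_310):
        from nanonuc import interfaces
        gases = interfaces.default_gases()
        P2_grid = np.linspace(-3e6, pspin_310 * 0.999, 40)
        J = [energetics.nucleation_rate(P2, 310.0, gases, pfp, pspin=pspin_310)[0]
             for P2 in P2_grid]
        assert np.all(np.diff(J) > 0)

    def test_temperature_sensitivity(self):
        # at fixed liquid pressure, the superheated state nucleates far faster
        from nanonuc import interfaces
        gases = interfaces.default_gases()
        J_cold, _ = energetics.nucleation_rate(
            -5e6, 294.0, gases, eos.FluidProperties.pfp(Psat=70e3))
        J_hot, _ = energetics.nucleation_rate(
            -2e6, 343.0, gases, eos.FluidProperties.pfp(Psat=400e3))
        assert J_hot > J_cold


class TestProbabilityAndCriticalRate:
    def test_half_probability_point(self):
        V20, tau = 1.1e-20, 2e-8
        J = math.log(2.0) / (V20 * tau)
        assert energetics.nucleation_probability(J, V20, tau) == pytest.approx(0.5)

    def test_zero_rate(self):
        assert energetics.nucleation_probability(0.0, 1e-20, 1e-8) == 0.0

    def test_monotone(self):
        probs = [energetics.nucleation_probability(J, 1e-20, 1e-8)
                 for J in np.geomspace(1e24, 1e28, 20)]
        assert np.all(np.diff(probs) > 0)

    def test_critical_rate_one_period(self):
        V20 = 4 * math.pi * (140e-9) ** 3 / 3
        assert energetics.critical_rate(V20, 1.0 / 5e6) == \
            pytest.approx(4.4e26, rel=0.02)

    def test_critical_rate_tenth_period(self):
        V20 = 4 * math.pi * (140e-9) ** 3 / 3
        assert energetics.critical_rate(V20, 1.0 / (10 * 5e6)) == \
            pytest.approx(4.35e27, rel=0.01)

    def test_volume_scaling(self):
        assert energetics.critical_rate(2e-20, 1e-8) == \
            pytest.approx(energetics.critical_rate(1e-20, 1e-8) / 2)
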