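"""Constitutive law: closed forms, finite-difference consistency, relaxation
limits, and the recurrence-vs-quadrature oracle."""

import numpy as np
import pytest

from mammosim.constitutive import (
    DeformationState,
    InvertedElementError,
    MaterialParams,
    MaterialSet,
    PronySeries,
    make_material,
    neo_hookean_energy,
    neo_hookean_stress,
    relaxation_modulus,
    visco_update,
)


def random_rotation(rng):
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def random_F(rng, j_range=(0.7, 1.4)):
    F = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
    J = np.linalg.det(F)
    if J <= 0:
        return random_F(rng, j_range)
    target = rng.uniform(*j_range)
    return F * (target / J) ** (1.0 / 3.0)


MAT = MaterialParams(mu0=200.0, K0=20000.0)


class TestTypes:
    def test_prony_invariants(self):
        with pytest.raises(ValueError):
            PronySeries(g=(0.5, 0.6), tau=(0.01, 0.1))  # sum >= 1
        with pytest.raises(ValueError):
            PronySeries(g=(0.5,), tau=(-1.0,))
        p = PronySeries(g=(0.3, 0.2), tau=(0.01, 0.1))
        assert p.g_inf == pytest.approx(0.5)
        G, eta = p.moduli(100.0)
        np.testing.assert_allclose(G, [30.0, 20.0])
        np.testing.assert_allclose(eta, [0.3, 2.0])  # eta_k = G_k tau_k

    def test_material_invariants(self):
        with pytest.raises(ValueError):
            MaterialParams(mu0=200.0, K0=200.0)  # violates K0 >= 50 mu0
        with pytest.raises(ValueError):
            MaterialParams(mu0=-1.0, K0=1000.0)
        assert MAT.G0 == MAT.mu0

    def test_material_set_scaling(self):
        ms = MaterialSet.from_breast(make_material(220.0, g=0.8), f=6.0)
        assert ms.skin.mu0 / ms.breast.mu0 == pytest.approx(6.0)
        assert ms.skin.prony == ms.breast.prony
        assert ms.breast.rho == 1000.0

    def test_deformation_state_invariants(self):
        state = DeformationState.from_F(np.eye(3))
        assert state.J == pytest.approx(1.0)
        assert state.I1_bar == pytest.approx(3.0)
        with pytest.raises(InvertedElementError):
            DeformationState.from_F(-np.eye(3))
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = DeformationState.from_F(random_F(rng))
            assert s.I1_bar >= 3.0 - 1e-12


class TestEnergy:
    def test_identity_zero(self):
        assert neo_hookean_energy(DeformationState.from_F(np.eye(3)), MAT) == pytest.approx(0.0)

    def test_rotation_zero(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            R = random_rotation(rng)
            assert neo_hookean_energy(DeformationState.from_F(R), MAT) == pytest.approx(0.0, abs=1e-9)

    def test_isochoric_uniaxial_closed_form(self):
        # F = diag(lam, 1/sqrt(lam), 1/sqrt(lam)), J = 1:
        # Psi = (mu0/2)(lam^2 + 2/lam - 3)
        lam = 1.2
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        expected = 100.0 * (lam ** 2 + 2.0 / lam - 3.0)
        got = neo_hookean_energy(DeformationState.from_F(F), MAT)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_objectivity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            F = random_F(rng)
            R = random_rotation(rng)
            e1 = neo_hookean_energy(DeformationState.from_F(F), MAT)
            e2 = neo_hookean_energy(DeformationState.from_F(R @ F), MAT)
            assert e2 == pytest.approx(e1, rel=1e-10, abs=1e-10)


class TestStress:
    def test_identity_zero(self):
        sigma = neo_hookean_stress(DeformationState.from_F(np.eye(3)), MAT)
        np.testing.assert_allclose(sigma, 0.0, atol=1e-12)

    def test_simple_shear(self):
        # J = 1 simple shear: sigma_12 = mu0 * gamma
        gamma = 0.3
        F = np.eye(3)
        F[0, 1] = gamma
        sigma = neo_hookean_stress(DeformationState.from_F(F), MAT)
        assert sigma[0, 1] == pytest.approx(200.0 * gamma, rel=1e-12)
        np.testing.assert_allclose(sigma, sigma.T, atol=1e-10)

    def test_incompressible_uniaxial_nominal(self):
        # nominal stress -> mu0 (lam - lam^-2) as K0/mu0 -> inf
        lam = 1.2
        mu0 = 200.0
        mat = MaterialParams(mu0=mu0, K0=1e4 * mu0)
        # lateral stretch from sigma_22 = 0 (solve numerically)
        from scipy.optimize import brentq

        def lateral_stress(s):
            F = np.diag([lam, s, s])
            return neo_hookean_stress(DeformationState.from_F(F), mat)[1, 1]

        s = brentq(lateral_stress, 0.5, 1.5, xtol=1e-14)
        F = np.diag([lam, s, s])
        sigma = neo_hookean_stress(DeformationState.from_F(F), mat)
        J = np.linalg.det(F)
        nominal = sigma[0, 0] * J / lam  # P = J sigma F^-T for diagonal F
        assert nominal == pytest.approx(mu0 * (lam - lam ** -2), rel=0.01)

    def test_stress_energy_fd_consistency(self):
        rng = np.random.default_rng(3)
        eps = 1e-6
        for _ in range(100):
            F = random_F(rng)
            state = DeformationState.from_F(F)
            sigma = neo_hookean_stress(state, MAT)
            # P = d Psi / d F; sigma = P F^T / J
            P_fd = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp = F.copy()
                    Fp[i, j] += eps
                    Fm = F.copy()
                    Fm[i, j] -= eps
                    ep = neo_hookean_energy(DeformationState.from_F(Fp), MAT)
                    em = neo_hookean_energy(DeformationState.from_F(Fm), MAT)
                    P_fd[i, j] = (ep - em) / (2 * eps)
            sigma_fd = P_fd @ F.T / np.linalg.det(F)
            scale = max(np.abs(sigma).max(), 1.0)
            assert np.abs(sigma - sigma_fd).max() / scale < 1e-5

    def test_inverted_element_error(self):
        with pytest.raises(InvertedElementError):
            DeformationState.from_F(np.diag([1.0, 1.0, -1.0]))


class TestRelaxation:
    MATV = make_material(200.0, g=0.8, tau=0.01)

    def test_instantaneous(self):
        assert relaxation_modulus(0.0, self.MATV) == pytest.approx(200.0)

    def test_long_term(self):
        assert relaxation_modulus(1e3, self.MATV) == pytest.approx(0.2 * 200.0, rel=1e-9)

    def test_value_at_tau(self):
        # G/G0 = 1 - 0.8 (1 - e^-1)
        expected = 200.0 * (1.0 - 0.8 * (1.0 - np.exp(-1.0)))
        assert relaxation_modulus(0.01, self.MATV) == pytest.approx(expected, rel=1e-12)
        assert expected / 200.0 == pytest.approx(0.4943, abs=1e-4)

    def test_monotone_nonincreasing(self):
        t = np.linspace(0, 0.2, 200)
        G = relaxation_modulus(t, self.MATV)
        assert np.all(np.diff(G) <= 1e-12)

    def test_negative_time_error(self):
        with pytest.raises(ValueError):
            relaxation_modulus(-0.1, self.MATV)


def convolution_oracle(times, S, prony, n_sub=40):
    """Direct quadrature of the hereditary integral for a piecewise-linear
    stress history: relaxed(t) = int_0^t g(t - s) dS/ds ds with
    g(t) = 1 - sum g_k (1 - exp(-t/tau_k)).  Independent of the recurrence."""
    t_end = times[-1]
    fine_t = np.linspace(0.0, t_end, n_sub * (len(times) - 1) + 1)
    fine_S = np.interp(fine_t, times, S)
    dS = np.diff(fine_S)
    mid = 0.5 * (fine_t[1:] + fine_t[:-1])
    out = np.empty(len(times))
    for i, t in enumerate(times):
        mask = mid <= t
        gfun = np.ones(mask.sum())
        for g_k, tau_k in zip(prony.g, prony.tau):
            gfun -= g_k * (1.0 - np.exp(-(t - mid[mask]) / tau_k))
        out[i] = float((gfun * dS[mask]).sum())
    return out


class TestViscoUpdate:
    def test_zero_g_passthrough(self):
        prony = PronySeries()
        S = np.array([[1.0, 2.0], [2.0, -1.0]])
        relaxed, h = visco_update(S, 0 * S, None, 1e-3, prony)
        np.testing.assert_allclose(relaxed, S)
        assert h == []

    def test_step_load_relaxes_to_long_term(self):
        prony = PronySeries(g=(0.8,), tau=(0.01,))
        S = 5.0
        relaxed, h = visco_update(S, 0.0, None, 1e-4, prony)
        for _ in range(5000):  # 0.5 s >> tau
            relaxed, h = visco_update(S, S, h, 1e-4, prony)
        assert relaxed == pytest.approx((1 - 0.8) * S, rel=1e-6)

    def test_recurrence_matches_convolution_quadrature(self):
        rng = np.random.default_rng(4)
        prony = PronySeries(g=(0.6,), tau=(0.02,))
        n = 200
        dt = 5e-4
        times = np.arange(n + 1) * dt
        # smooth random history starting at 0
        S = np.cumsum(rng.standard_normal(n + 1))
        S -= S[0]
        S = np.convolve(S, np.ones(9) / 9.0, mode="same")
        S[0] = 0.0
        relaxed = np.zeros(n + 1)
        h = None
        prev = 0.0
        for i in range(1, n + 1):
            r, h = visco_update(S[i], prev, h, dt, prony)
            relaxed[i] = r
            prev = S[i]
        oracle = convolution_oracle(times, S, prony)
        scale = np.abs(oracle).max()
        assert np.abs(relaxed - oracle).max() / scale < 0.005

    def test_multi_term_matches_quadrature(self):
        rng = np.random.default_rng(5)
        prony = PronySeries(g=(0.4, 0.3), tau=(0.005, 0.05))
        n = 200
        dt = 5e-4
        times = np.arange(n + 1) * dt
        S = np.sin(8 * times) + 0.3 * np.cumsum(rng.standard_normal(n + 1)) * np.sqrt(dt)
        S -= S[0]
        relaxed = np.zeros(n + 1)
        h = None
        for i in range(1, n + 1):
            r, h = visco_update(S[i], S[i - 1], h, dt, prony)
            relaxed[i] = r
        oracle = convolution_oracle(times, S, prony)
        assert np.abs(relaxed - oracle).max() / np.abs(oracle).max() < 0.005

    def test_dissipation_nonnegative_on_closed_cycles(self):
        # work of the relaxed stress around a closed strain loop is >= 0
        rng = np.random.default_rng(6)
        prony = PronySeries(g=(0.5,), tau=(0.01,))
        G0 = 200.0
        for _ in range(10):
            n = 400
            dt = 2e-4
            k = int(rng.integers(1, 8))  # whole periods -> exactly closed loop
            w = 2 * np.pi * k / (n * dt)
            phi = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.5, 2.0)
            eps = amp * (np.sin(w * np.arange(n + 1) * dt + phi) - np.sin(phi))
            S = G0 * eps
            h = None
            work = 0.0
            prev_r = S[0]
            for i in range(1, n + 1):
                r, h = visco_update(S[i], S[i - 1], h, dt, prony)
                work += 0.5 * (r + prev_r) * (eps[i] - eps[i - 1])
                prev_r = r
            assert work > -1e-9 * G0 * amp ** 2

    def test_bad_dt(self):
        with pytest.raises(ValueError):
            visco_update(1.0, 0.0, None, 0.0, PronySeries(g=(0.5,), tau=(0.01,)))
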