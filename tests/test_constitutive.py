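"""HGO membrane constitutive model: energy, stress, tangent, dispersion."""

import numpy as np
import pytest
from scipy.optimize import brentq

from scleramap.constitutive import (
    DeformationState,
    HGOParameters,
    energy_stress_tangent,
    hgo_strain_energy,
    kappa_from_distribution,
    material_tangent,
    membrane_pk2_stress,
    vonmises_fiber_density,
)
from scleramap.errors import EnergyOverflowError, ParameterError


def _random_states(n, seed=0, spread=0.08):
    rng = np.random.default_rng(seed)
    Fs = []
    while len(Fs) < n:
        F = np.eye(2) + spread * rng.standard_normal((2, 2))
        if np.linalg.det(F) > 0.3:
            Fs.append(F)
    return Fs


def _random_params(n, seed=1):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            HGOParameters(
                c10=rng.uniform(20, 500),
                k1=rng.uniform(0, 5000),
                k2=rng.uniform(5, 200),
                kappa=rng.uniform(0, 1 / 3),
                fiber_angle=rng.uniform(0, np.pi),
            )
        )
    return out


class TestEnergy:
    def test_reference_state_zero(self):
        for p in _random_params(5):
            st = DeformationState.from_F(np.eye(2), p.fiber_vector)
            assert abs(hgo_strain_energy(st, p)) < 1e-20

    def test_neo_hookean_reduction_equibiaxial(self):
        p = HGOParameters(c10=120.0, k1=0.0, k2=1.0, kappa=0.2)
        for lam in (1.05, 1.2, 1.5):
            st = DeformationState.from_F(lam * np.eye(2), p.fiber_vector)
            expected = 120.0 * (2 * lam**2 + lam**-4 - 3)
            assert np.isclose(hgo_strain_energy(st, p), expected, rtol=1e-12)

    def test_macaulay_no_energy_for_compressed_fibers(self):
        # kappa = 0: Ea = I4 - 1 < 0 under fiber-direction compression
        p = HGOParameters(c10=100.0, k1=1000.0, k2=50.0, kappa=0.0, fiber_angle=0.0)
        F = np.diag([0.95, 1.06])
        st = DeformationState.from_F(F, p.fiber_vector)
        assert st.I4 < 1
        p0 = HGOParameters(c10=100.0, k1=0.0, k2=50.0, kappa=0.0, fiber_angle=0.0)
        assert hgo_strain_energy(st, p) == hgo_strain_energy(st, p0)

    def test_k2_zero_limit_series(self):
        lam = 1.08
        F = lam * np.eye(2)
        w = []
        for k2 in (1e-12, 1e-9, 1e-4):
            p = HGOParameters(c10=100.0, k1=500.0, k2=k2, kappa=0.1)
            st = DeformationState.from_F(F, p.fiber_vector)
            ea = st.fiber_strain(0.1)
            expected_fiber = 0.5 * 500.0 * ea**2
            w.append(hgo_strain_energy(st, p) - 100.0 * (st.I1 - 3))
            assert np.isclose(w[-1], expected_fiber, rtol=1e-3)

    def test_overflow_raises(self):
        p = HGOParameters(c10=100.0, k1=1000.0, k2=300.0, kappa=0.0, fiber_angle=0.0)
        st = DeformationState.from_F(np.diag([3.0, 1.0]), p.fiber_vector)
        with pytest.raises(EnergyOverflowError):
            hgo_strain_energy(st, p)

    def test_monotone_in_k1_when_fibers_stretched(self):
        F = np.diag([1.1, 1.02])
        w_prev = -1.0
        for k1 in (0.0, 100.0, 1000.0):
            p = HGOParameters(c10=50.0, k1=k1, k2=30.0, kappa=0.15, fiber_angle=0.0)
            st = DeformationState.from_F(F, p.fiber_vector)
            assert st.fiber_strain(0.15) > 0
            w = hgo_strain_energy(st, p)
            assert w > w_prev
            w_prev = w

    def test_isotropy_at_kappa_third(self):
        F = np.array([[1.08, 0.03], [0.01, 0.97]])
        ws = []
        for ang in np.linspace(0, np.pi, 7):
            p = HGOParameters(c10=80.0, k1=900.0, k2=40.0, kappa=1 / 3, fiber_angle=ang)
            st = DeformationState.from_F(F, p.fiber_vector)
            ws.append(hgo_strain_energy(st, p))
        assert np.ptp(ws) < 1e-12

    def test_rotation_invariance(self):
        p = HGOParameters(c10=80.0, k1=900.0, k2=40.0, kappa=0.2, fiber_angle=0.5)
        F = np.array([[1.08, 0.03], [0.01, 0.97]])
        c, s = np.cos(0.8), np.sin(0.8)
        Q = np.array([[c, -s], [s, c]])
        w1 = hgo_strain_energy(DeformationState.from_F(F, p.fiber_vector), p)
        w2 = hgo_strain_energy(DeformationState.from_F(Q @ F, p.fiber_vector), p)
        assert np.isclose(w1, w2, rtol=1e-12)


class TestStressAndTangent:
    def test_reference_stress_free(self):
        for p in _random_params(5, seed=3):
            S = membrane_pk2_stress(np.eye(2), p)
            assert np.abs(S).max() < 1e-12

    def test_stress_matches_finite_difference_of_energy(self):
        h = 1e-6
        for F, p in zip(_random_states(100, seed=4), _random_params(100, seed=5)):
            C = F.T @ F
            a = p.fiber_vector
            S = membrane_pk2_stress(F, p)

            def W(Cm):
                return energy_stress_tangent(
                    Cm[None], a[None], p.c10, p.k1, p.k2, p.kappa, want=("W",)
                )["W"][0]

            for i in range(2):
                for j in range(2):
                    dC = np.zeros((2, 2))
                    dC[i, j] += h
                    dC[j, i] += h
                    fd = (W(C + dC) - W(C - dC)) / (4 * h) * 2  # dW/dE_ij
                    assert abs(S[i, j] - fd) <= 1e-6 * max(1.0, abs(S).max())

    def test_tangent_matches_finite_difference_of_stress(self):
        h = 1e-6
        for F, p in zip(_random_states(100, seed=6), _random_params(100, seed=7)):
            C = F.T @ F
            a = p.fiber_vector
            T = material_tangent(F, p)

            def S_of(Cm):
                return energy_stress_tangent(
                    Cm[None], a[None], p.c10, p.k1, p.k2, p.kappa, want=("S",)
                )["S"][0]

            scale = max(1.0, np.abs(T).max())
            for k in range(2):
                for l in range(2):
                    dC = np.zeros((2, 2))
                    dC[k, l] += h
                    dC[l, k] += h
                    fd = (S_of(C + dC) - S_of(C - dC)) / (4 * h) * 2
                    assert np.abs(T[:, :, k, l] - fd).max() <= 1e-5 * scale

    def test_major_symmetry(self):
        for F, p in zip(_random_states(10, seed=8), _random_params(10, seed=9)):
            T = material_tangent(F, p)
            assert np.abs(T - T.transpose(2, 3, 0, 1)).max() < 1e-10 * np.abs(T).max()

    def test_tangent_positive_definite_at_reference(self):
        for p in _random_params(10, seed=10):
            T = material_tangent(np.eye(2), p)
            M = T.reshape(4, 4)[np.ix_([0, 1, 3], [0, 1, 3])]  # unique (ij) pairs
            assert np.linalg.eigvalsh(0.5 * (M + M.T)).min() > 0

    def test_neo_hookean_uniaxial_membrane(self):
        # lateral-free uniaxial stretch: S22 = 0 fixes lam2, closed-form check
        c10 = 100.0
        p = HGOParameters(c10=c10, k1=0.0, k2=1.0, kappa=0.0, fiber_angle=0.0)
        lam = 1.3

        def s22(lam2):
            return membrane_pk2_stress(np.diag([lam, lam2]), p)[1, 1]

        lam2 = brentq(s22, 0.5, 1.2, xtol=1e-14)
        # incompressible uniaxial: lam2 = lam^{-1/2}
        assert np.isclose(lam2, lam**-0.5, rtol=1e-10)
        S11 = membrane_pk2_stress(np.diag([lam, lam2]), p)[0, 0]
        lam3 = 1 / (lam * lam2)
        sigma11 = lam**2 * S11  # Cauchy = lam1^2 S11 (J = 1)
        assert np.isclose(sigma11, 2 * c10 * (lam**2 - lam3**2), rtol=1e-10)

    def test_energy_consistency_along_path(self):
        # integrate S : dE along a straight path in C-space, compare with dW
        p = HGOParameters(c10=90.0, k1=800.0, k2=30.0, kappa=0.2, fiber_angle=0.4)
        a = p.fiber_vector
        C0, C1 = np.eye(2), np.array([[1.25, 0.05], [0.05, 1.1]])
        n = 2000
        ts = np.linspace(0, 1, n + 1)
        Cs = C0[None] + ts[:, None, None] * (C1 - C0)[None]
        out = energy_stress_tangent(Cs, np.tile(a, (n + 1, 1)), p.c10, p.k1, p.k2, p.kappa,
                                    want=("W", "S"))
        dE = 0.5 * (C1 - C0) / n
        mid = 0.5 * (out["S"][:-1] + out["S"][1:])
        work = np.einsum("mij,ij->", mid, dE)
        dW = out["W"][-1] - out["W"][0]
        assert np.isclose(work, dW, rtol=1e-6)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"c10": -1.0},
            {"k1": -5.0},
            {"k2": 0.0},
            {"kappa": 0.4},
            {"N": 2},
        ],
    )
    def test_invalid_rejected(self, kw):
        base = dict(c10=100.0, k1=500.0, k2=50.0, kappa=0.2)
        base.update(kw)
        with pytest.raises(ParameterError):
            HGOParameters(**base)


class TestKappaFromDistribution:
    def test_delta_is_zero(self):
        assert kappa_from_distribution("delta") == 0.0

    def test_narrow_spike_tends_to_zero(self):
        th = np.linspace(0, np.pi, 20001)
        for width in (0.05, 0.02, 0.01):
            rho = np.exp(-0.5 * (th / width) ** 2)
            with pytest.warns(UserWarning):
                k = kappa_from_distribution(rho, theta=th)
            assert k < width**2  # kappa ~ width^2 / 2 for a narrow spike

    def test_uniform_is_one_third(self):
        assert abs(kappa_from_distribution("uniform") - 1 / 3) < 1e-9

    def test_von_mises_matches_dense_trapezoid(self):
        for b in (0.5, 2.0, 8.0):
            rho = vonmises_fiber_density(b)
            k = kappa_from_distribution(rho)
            th = np.linspace(0, np.pi, 1_000_001)
            dense = 0.25 * np.trapezoid(rho(th) * np.sin(th) ** 3, th)
            assert abs(k - dense) < 1e-9
            assert 0 < k < 1 / 3

    def test_negative_density_rejected(self):
        th = np.linspace(0, np.pi, 101)
        with pytest.raises(ParameterError):
            kappa_from_distribution(np.sin(2 * th), theta=th)
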