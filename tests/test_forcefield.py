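"""Analytic force-field checks: closed forms, gradients, continuity."""

import math

import numpy as np
import pytest

import lcd_llps as m
from lcd_llps.constants import COULOMB, KB, KJ_PER_KCAL, N_AVOGADRO
from lcd_llps.forcefield import (PairTable, mlj_force_components,
                                 _TWO_POW_SIXTH)


def numerical_gradient(f, r, h=1e-7):
    return (f(r + h) - f(r - h)) / (2 * h)


class TestIonicStrength:
    def test_buffer_only(self):
        # 20 mM phosphate, 70/30 dibasic/monobasic with K+ counterions
        assert m.ionic_strength(0.0) == pytest.approx(0.048)

    def test_with_salt(self):
        assert m.ionic_strength(1.25) == pytest.approx(1.298)

    def test_zero_everything(self):
        assert m.ionic_strength(0.0, m.BufferSpec.none()) == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            m.ionic_strength(-0.1)


class TestDebyeLength:
    def test_high_salt_printed_value(self):
        """1250 mM NaCl + buffer at 298 K / eps_r 78.4 -> 0.267 nm."""
        assert m.debye_length(1.25) == pytest.approx(0.267, abs=5e-4)

    def test_closed_form_oracle_pure_salt(self):
        """Independent evaluation from physical constants (SI route)."""
        eps0_si = 8.8541878128e-12   # F/m
        e_si = 1.602176634e-19       # C
        kb_si = 1.380649e-23         # J/K
        I = 0.1                      # mol/L of 1:1 salt
        n = I * 1e3 * N_AVOGADRO     # ions per m^3 per species... via 2*I below
        lam_si = math.sqrt(eps0_si * 78.4 * kb_si * 298.0 /
                           (2.0 * n * e_si**2)) * 1e9
        got = m.debye_length(0.1, m.BufferSpec.none())
        assert got == pytest.approx(lam_si, rel=1e-6)

    def test_monotone_decreasing_in_salt(self):
        cs = [0.0, 0.05, 0.2, 0.5, 1.25]
        lams = [m.debye_length(c) for c in cs]
        assert all(a > b for a, b in zip(lams, lams[1:]))

    def test_zero_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            m.debye_length(0.0, m.BufferSpec.none())


class TestEpsilonOfSalt:
    def test_calibrated_endpoints(self):
        assert m.epsilon_of_salt(0.0) / KJ_PER_KCAL == pytest.approx(0.1985)
        assert m.epsilon_of_salt(1.25) / KJ_PER_KCAL == pytest.approx(0.205)

    def test_linear_midpoint(self):
        assert m.epsilon_of_salt(0.625) / KJ_PER_KCAL == pytest.approx(0.20175)

    def test_relative_increase_is_about_three_percent(self):
        rel = m.epsilon_of_salt(1.25) / m.epsilon_of_salt(0.0) - 1.0
        assert rel == pytest.approx(0.033, abs=0.005)

    def test_constant_epsilon_control(self):
        ctrl = m.InteractionModel.constant_epsilon_control()
        for c in (0.0, 0.2, 1.25):
            assert m.epsilon_of_salt(c, ctrl) / KJ_PER_KCAL == pytest.approx(0.205)

    def test_large_system_recalibration(self):
        big = m.InteractionModel.large_system()
        assert m.epsilon_of_salt(0.0, big) / KJ_PER_KCAL == pytest.approx(0.1875)
        assert m.epsilon_of_salt(1.25, big) / KJ_PER_KCAL == pytest.approx(0.1905)

    def test_monotone_increasing(self):
        cs = np.linspace(0, 1.25, 7)
        es = [m.epsilon_of_salt(c) for c in cs]
        assert all(a < b for a, b in zip(es, es[1:]))


class TestBondTerm:
    def test_rest_length(self):
        e, f = m.bond_term(0.38)
        assert e == 0.0 and f == 0.0

    def test_printed_constant_at_stretched_bond(self):
        e, _ = m.bond_term(0.48)
        assert e == pytest.approx(0.5 * 8305 * 0.01)

    def test_force_is_negative_gradient(self):
        rng = np.random.default_rng(0)
        for r in rng.uniform(0.2, 0.6, 100):
            _, f = m.bond_term(r)
            g = numerical_gradient(lambda x: m.bond_term(x)[0], r)
            assert f == pytest.approx(-g, rel=1e-6, abs=1e-6)


class TestYukawaTerm:
    def test_zero_charge_product(self):
        for r in (0.3, 1.0, 3.0):
            assert m.yukawa_term(r, 0.0) == (0.0, 0.0)

    def test_truncated_beyond_cutoff(self):
        mod = m.InteractionModel(c_nacl=0.1)
        e, f = m.yukawa_term(3.6, 1.0, mod)
        assert e == 0.0 and f == 0.0
        e_in, f_in = m.yukawa_term(3.4, 1.0, mod)
        assert e_in > 0.0 and f_in > 0.0

    def test_screening_ratio_against_coulomb(self):
        """energy(r)/coulomb(r) = exp(-r/lambda_D) (closed-form oracle)."""
        mod = m.InteractionModel(c_nacl=0.15)
        lam_d = mod.debye_length
        for r in (0.4, 1.1, 2.7):
            e, _ = m.yukawa_term(r, 1.0, mod)
            coulomb = COULOMB / mod.relative_permittivity / r
            assert e / coulomb == pytest.approx(math.exp(-r / lam_d), rel=1e-12)

    def test_force_is_negative_gradient(self):
        mod = m.InteractionModel(c_nacl=0.2)
        rng = np.random.default_rng(1)
        for r in rng.uniform(0.3, 3.0, 100):
            for qq in (-1.0, 1.0):
                _, f = m.yukawa_term(r, qq, mod)
                g = numerical_gradient(lambda x: m.yukawa_term(x, qq, mod)[0], r)
                assert f == pytest.approx(-g, rel=1e-6)

    def test_like_charges_repel_opposite_attract(self):
        mod = m.InteractionModel(c_nacl=0.1)
        assert m.yukawa_term(0.5, 1.0, mod)[1] > 0
        assert m.yukawa_term(0.5, -1.0, mod)[1] < 0


class TestMljTerm:
    SIGMA, LAM, EPS = 0.57, 0.65, 0.83

    def test_continuity_at_branch_point(self):
        rmin = _TWO_POW_SIXTH * self.SIGMA
        e_at, _ = m.mlj_term(rmin, self.SIGMA, self.LAM, self.EPS)
        e_below, _ = m.mlj_term(rmin * (1 - 1e-12), self.SIGMA, self.LAM, self.EPS)
        e_above, _ = m.mlj_term(rmin * (1 + 1e-12), self.SIGMA, self.LAM, self.EPS)
        assert e_at == pytest.approx(-self.LAM * self.EPS, rel=1e-12)
        assert e_below == pytest.approx(e_above, rel=1e-9)

    def test_value_at_sigma(self):
        e, _ = m.mlj_term(self.SIGMA, self.SIGMA, self.LAM, self.EPS)
        assert e == pytest.approx(self.EPS * (1 - self.LAM), rel=1e-12)

    def test_lambda_one_is_plain_lj(self):
        rng = np.random.default_rng(2)
        for r in rng.uniform(0.5, 1.99, 50):
            e, f = m.mlj_term(r, self.SIGMA, 1.0, self.EPS)
            sr6 = (self.SIGMA / r) ** 6
            lj = 4 * self.EPS * (sr6**2 - sr6)
            assert e == pytest.approx(lj, rel=1e-12, abs=1e-15)

    def test_truncated_beyond_cutoff(self):
        assert m.mlj_term(2.01, self.SIGMA, self.LAM, self.EPS) == (0.0, 0.0)

    def test_force_is_negative_gradient_away_from_branch(self):
        rng = np.random.default_rng(3)
        rmin = _TWO_POW_SIXTH * self.SIGMA
        rs = rng.uniform(0.45, 1.9, 120)
        rs = rs[np.abs(rs - rmin) > 1e-3]
        for r in rs:
            _, f = m.mlj_term(r, self.SIGMA, self.LAM, self.EPS)
            g = numerical_gradient(
                lambda x: m.mlj_term(x, self.SIGMA, self.LAM, self.EPS)[0], r)
            assert f == pytest.approx(-g, rel=1e-5, abs=1e-9)


class TestHydrophobicDecomposition:
    def test_lambda_zero_has_no_hydrophobic_component(self):
        for r in (0.4, 0.6, 1.0, 1.8):
            assert m.hydrophobic_force_component(r, 0.57, 0.0, 0.83) == 0.0

    def test_equals_full_force_beyond_branch_point(self):
        sigma, lam, eps = 0.6, 0.7, 0.83
        for r in np.linspace(_TWO_POW_SIXTH * sigma + 1e-6, 1.99, 20):
            _, full = m.mlj_term(r, sigma, lam, eps)
            hyd = m.hydrophobic_force_component(r, sigma, lam, eps)
            assert hyd == pytest.approx(full, rel=1e-12, abs=1e-15)

    def test_decomposition_identity(self):
        """full = repulsive + hydrophobic at random (r, sigma, lambda)."""
        rng = np.random.default_rng(4)
        for _ in range(100):
            r = rng.uniform(0.4, 1.99)
            sigma = rng.uniform(0.45, 0.68)
            lam = rng.uniform(0.0, 1.0)
            rep, hyd = mlj_force_components(r, sigma, lam, 0.83)
            _, full = m.mlj_term(r, sigma, lam, 0.83)
            assert rep + hyd == pytest.approx(full, rel=1e-10, abs=1e-12)

    def test_hydrophobic_component_is_lambda_weighted_lj_force(self):
        sigma, eps = 0.55, 0.9
        for r in (0.5, 0.7, 1.2):
            h1 = m.hydrophobic_force_component(r, sigma, 0.3, eps)
            h2 = m.hydrophobic_force_component(r, sigma, 0.6, eps)
            assert h2 == pytest.approx(2 * h1, rel=1e-12)


class TestPairTable:
    def test_symmetric_mixing_rules(self):
        pt = PairTable.from_params()
        assert np.allclose(pt.sigma, pt.sigma.T)
        assert np.allclose(pt.lam, pt.lam.T)
        assert np.allclose(pt.qq, pt.qq.T)
        assert np.all(pt.sigma > 0)
        assert np.all((pt.lam >= 0) & (pt.lam <= 1))

    def test_values_are_arithmetic_means(self):
        pt = PairTable.from_params()
        i = pt.residues.index("G")
        j = pt.residues.index("W")
        assert pt.sigma[i, j] == pytest.approx(0.5 * (0.450 + 0.678))
        assert pt.qq[pt.residues.index("D"), pt.residues.index("K")] == -1.0


class TestModelSerialization:
    def test_roundtrip(self):
        mod = m.InteractionModel(c_nacl=0.2, lambda_scale=0.9)
        back = m.InteractionModel.from_dict(mod.to_dict())
        assert back == mod

    def test_temperature_default_reproduces_thermal_energy(self):
        mod = m.InteractionModel()
        assert mod.kT == pytest.approx(KB * 298.0)


class TestPotentialProperties:
    """Property-based invariants of the pair potentials."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(r=st.floats(0.35, 1.99), sigma=st.floats(0.45, 0.678),
           lam=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_mlj_decomposition_closes(self, r, sigma, lam):
        rep, hyd = mlj_force_components(r, sigma, lam, 0.83)
        _, full = m.mlj_term(r, sigma, lam, 0.83)
        assert rep + hyd == pytest.approx(full, rel=1e-9, abs=1e-12)

    @given(r=st.floats(0.3, 3.4), c=st.floats(0.0, 1.25))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_screening_never_exceeds_bare_coulomb(self, r, c):
        mod = m.InteractionModel(c_nacl=c)
        e, f = m.yukawa_term(r, 1.0, mod)
        bare = COULOMB / mod.relative_permittivity / r
        assert 0.0 < e <= bare * (1 + 1e-12)
        assert f > 0.0

    @given(c1=st.floats(0.0, 1.25), c2=st.floats(0.0, 1.25))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_salt_ordering_of_screening_and_well_depth(self, c1, c2):
        lo, hi = sorted((c1, c2))
        assert m.debye_length(hi) <= m.debye_length(lo)
        assert m.epsilon_of_salt(hi) >= m.epsilon_of_salt(lo)
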