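"""Model equations: closed forms, mass balances, steady states."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gastropbpk as g
from gastropbpk.model import stomach_system_matrix

TINY = 1e-30


def _stomach(**overrides):
    base = dict(Q_t=1.1, V_e=0.441, fb_PSinf=0.174, fu_PSeff=0.006,
                V_T=0.133, k_ass=3.2e-5, k_dis=4.85e-6)
    base.update(overrides)
    return g.StomachParams(**base)


class TestPlasmaToBlood:
    def test_reference_ratio(self):
        assert g.plasma_to_blood(1.0, 0.84) == pytest.approx(0.84)
        assert g.plasma_to_blood(2.5, 0.84) == pytest.approx(2.1)

    def test_zero_and_errors(self):
        assert g.plasma_to_blood(0.0, 0.5) == 0.0
        with pytest.raises(g.InvalidArgumentError):
            g.plasma_to_blood(-0.1, 0.84)
        with pytest.raises(g.InvalidArgumentError):
            g.plasma_to_blood(1.0, 0.0)


class TestMacroConstants:
    def test_reference_roots_against_quadratic_oracle(self, ref):
        # independent oracle: numpy polynomial roots of the characteristic polynomial
        k10 = 56.9 / 302
        roots = np.sort(np.roots([1.0, -(k10 + 0.126 + 0.0313), k10 * 0.0313]))
        mc = g.macro_constants(ref.blood)
        assert mc.beta == pytest.approx(roots[0], rel=1e-12)
        assert mc.alpha == pytest.approx(roots[1], rel=1e-12)
        assert mc.alpha == pytest.approx(0.3277, abs=5e-5)
        assert mc.beta == pytest.approx(0.0180, abs=5e-5)

    def test_decoupled_limit(self):
        # k1 → 0: the compartments decouple and the exponents tend to k10, k2
        p = g.BloodPKParams(V1=100.0, k1=1e-12, k2=0.03, CL_tot=10.0)
        mc = g.macro_constants(p)
        assert mc.alpha == pytest.approx(max(p.k10, p.k2), rel=1e-9)
        assert mc.beta == pytest.approx(min(p.k10, p.k2), rel=1e-9)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(V1=st.floats(50, 1000), k1=st.floats(1e-3, 0.5),
           k2=st.floats(1e-3, 0.5), CL=st.floats(1, 200))
    def test_root_identity(self, V1, k1, k2, CL):
        p = g.BloodPKParams(V1=V1, k1=k1, k2=k2, CL_tot=CL)
        mc = g.macro_constants(p)
        assert mc.alpha * mc.beta / p.k2 == pytest.approx(CL / V1, rel=1e-10)

    def test_amplitude_sum(self, ref):
        mc = g.macro_constants(ref.blood)
        assert mc.A + mc.B == pytest.approx(1.0 / ref.blood.V1, rel=1e-12)


class TestBloodForcing:
    def test_initial_concentration_is_dose_over_v1(self, ref):
        # 1.85 μmol/kg over 302 ml/kg = 6.13 μM
        c0 = g.blood_forcing(0.0, ref.blood, ref.dose)
        assert c0 == pytest.approx(1850.0 / 302.0, rel=1e-12)
        assert c0 == pytest.approx(6.13, abs=5e-3)

    def test_matches_direct_two_exponential_arithmetic(self, ref):
        # independent evaluation of the closed form at t = 120 min
        k10 = 56.9 / 302
        lam = np.sort(np.roots([1.0, -(k10 + 0.126 + 0.0313), k10 * 0.0313]))
        beta, alpha = lam
        D = 1.85e3
        t = 120.0
        expected = (
            D * (alpha - 0.0313) / (302 * (alpha - beta)) * np.exp(-alpha * t)
            + D * (0.0313 - beta) / (302 * (alpha - beta)) * np.exp(-beta * t)
        )
        assert g.blood_forcing(t, ref.blood, ref.dose) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decay_to_zero(self, ref):
        t = np.linspace(0, 5000, 400)
        c = g.blood_forcing(t, ref.blood, ref.dose)
        assert np.all(np.diff(c) < 0)
        assert g.blood_forcing(1e6, ref.blood, ref.dose) == pytest.approx(0.0, abs=1e-12)

    def test_negative_time_rejected(self, ref):
        with pytest.raises(g.InvalidArgumentError):
            g.blood_forcing(-1.0, ref.blood, ref.dose)


class TestStomachRHS:
    def test_empty_system(self):
        sp = _stomach()
        d = g.stomach_rhs((0.0, 0.0, 0.0), 0.0, sp, lambda t: 0.0)
        assert d == (0.0, 0.0, 0.0)

    def test_constant_forcing_steady_state_oracle(self):
        """Steady state solved independently as a 3×3 linear system."""
        sp = _stomach()
        c = 3.7  # arbitrary constant blood level
        # oracle: write the mass balances from first principles and solve
        V_d = sp.V_T * sp.k_ass / sp.k_dis
        A = np.array([
            [-(sp.Q_t + sp.fb_PSinf), sp.fu_PSeff, 0.0],
            [sp.fb_PSinf, -(sp.fu_PSeff + sp.V_T * sp.k_ass), V_d * sp.k_dis],
            [0.0, sp.V_T * sp.k_ass, -V_d * sp.k_dis],
        ])
        b = np.array([-sp.Q_t * c, 0.0, 0.0])
        ss = np.linalg.solve(A, b)
        # the steady state satisfies C_e = c and C_T/C_e = fb/fu = 29
        derivs = g.stomach_rhs(tuple(ss), 0.0, sp, lambda t: c)
        assert np.allclose(derivs, 0.0, atol=1e-9)
        assert ss[0] == pytest.approx(c, rel=1e-9)
        assert ss[1] / ss[0] == pytest.approx(sp.fb_PSinf / sp.fu_PSeff, rel=1e-9)
        assert ss[1] / ss[0] == pytest.approx(29.0, rel=1e-9)
        # deep-pool flux balance V_T·C_T·k_ass = V_d·C_d·k_dis
        assert sp.V_T * ss[1] * sp.k_ass == pytest.approx(V_d * ss[2] * sp.k_dis, rel=1e-9)

    def test_decoupled_deep_pool(self):
        # with vanishing association/dissociation, a pulse in the precursor
        # pool never reaches the deep pool
        sp = _stomach(k_ass=TINY, k_dis=TINY)
        _, _, dCd = g.stomach_rhs((0.0, 5.0, 0.0), 0.0, sp, lambda t: 0.0)
        assert abs(dCd) < 1e-20

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(Ce=st.floats(0, 50), CT=st.floats(0, 50), Cd=st.floats(0, 50),
           C1=st.floats(0, 50))
    def test_mass_conservation_identity(self, Ce, CT, Cd, C1):
        """d/dt of the total stomach amount equals the blood exchange flux."""
        sp = _stomach()
        V_d = sp.V_T * sp.k_ass / sp.k_dis
        dCe, dCT, dCd = g.stomach_rhs((Ce, CT, Cd), 0.0, sp, lambda t: C1)
        total_flux = sp.V_e * dCe + sp.V_T * dCT + V_d * dCd
        assert total_flux == pytest.approx(sp.Q_t * (C1 - Ce), rel=1e-12, abs=1e-12)

    def test_alternate_deep_pool_exit_breaks_conservation(self):
        """The non-corrected exit constant leaks mass (kept for comparison)."""
        sp = _stomach()
        V_d = sp.V_T * sp.k_ass / sp.k_dis
        dCe, dCT, dCd = g.stomach_rhs((1.0, 1.0, 1.0), 0.0, sp, lambda t: 1.0,
                                      deep_pool_exit="k_ass")
        total_flux = sp.V_e * dCe + sp.V_T * dCT + V_d * dCd
        assert total_flux != pytest.approx(sp.Q_t * (1.0 - 1.0), abs=1e-12)

    def test_system_matrix_matches_rhs(self):
        sp = _stomach()
        M, gvec = stomach_system_matrix(sp)
        x = np.array([1.3, 2.7, 0.4])
        c1 = 0.9
        assert np.allclose(M @ x + gvec * c1,
                           g.stomach_rhs(tuple(x), 0.0, sp, lambda t: c1), rtol=1e-12)


class TestStomachConcentration:
    def test_uniform_pools(self):
        sp = _stomach()
        assert g.stomach_concentration((0.0, 1.0, 1.0), sp) == pytest.approx(1.0)

    def test_precursor_only_reference_values(self):
        sp = _stomach()
        V_d = 0.133 * 3.2e-5 / 4.85e-6
        expected = 2 * 0.133 / (0.133 + V_d)
        assert g.stomach_concentration((0.0, 2.0, 0.0), sp) == pytest.approx(expected)
        assert expected == pytest.approx(0.263, abs=5e-4)
        lit = g.stomach_concentration((0.0, 2.0, 0.0), sp, "literature")
        assert lit == pytest.approx(2 * 0.133 / 1.1)

    def test_single_pool_limit(self):
        sp = _stomach(k_ass=1e-12, k_dis=1.0)  # V_d → 0
        assert g.stomach_concentration((0.0, 4.2, 0.0), sp) == pytest.approx(4.2, rel=1e-10)

    def test_unknown_convention(self):
        with pytest.raises(g.InvalidArgumentError):
            g.stomach_concentration((0.0, 1.0, 1.0), _stomach(), "bogus")


class TestInhibitionAndPD:
    def test_inhibition_fraction_landmarks(self):
        assert g.inhibition_fraction(1.79, 1.79) == pytest.approx(0.5)
        assert g.inhibition_fraction(0.0, 1.79) == 0.0
        assert g.inhibition_fraction(3 * 1.79, 1.79) == pytest.approx(0.75)
        c = np.linspace(0, 100, 500)
        f = g.inhibition_fraction(c, 1.79)
        assert np.all(np.diff(f) > 0) and np.all(f < 1.0)

    def test_pd_baseline_steady_state(self, ref):
        assert g.pd_rhs(ref.pd.R0, 0.0, ref.pd) == pytest.approx(0.0, abs=1e-15)

    def test_pd_half_inhibition_steady_state(self, ref):
        R_ss = 2 * ref.pd.k_in / ref.pd.k_out
        assert g.pd_rhs(R_ss, ref.pd.IC50, ref.pd) == pytest.approx(0.0, abs=1e-15)

    def test_pd_direct_substitution(self, ref):
        # k_in − k_out·R at R = 1, no drug
        assert g.pd_rhs(1.0, 0.0, ref.pd) == pytest.approx(0.00314 - 0.00415, rel=1e-12)
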