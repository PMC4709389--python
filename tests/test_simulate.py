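"""Simulation: solver accuracy against independent oracles, invariants."""

import numpy as np
import pytest
from scipy.linalg import expm

import gastropbpk as g
from gastropbpk.model import stomach_system_matrix
from gastropbpk.simulate import default_grid

TINY = 1e-30


def _analytic_stomach_solution(ref, times):
    """Independent closed form for the linear stomach system driven by a
    biexponential blood curve: particular solutions −(M+λI)⁻¹ g c for each
    exponential plus a matrix-exponential homogeneous part."""
    mc = g.macro_constants(ref.blood)
    D = ref.dose.dose_nmol_per_kg
    M, gvec = stomach_system_matrix(ref.stomach)
    lams = (mc.alpha, mc.beta)
    coefs = (D * mc.A, D * mc.B)
    parts = [-np.linalg.solve(M + lam * np.eye(3), gvec) * c
             for lam, c in zip(lams, coefs)]
    x0 = -sum(p for p in parts)  # initial condition is zero
    out = np.zeros((3, len(times)))
    for k, t in enumerate(times):
        hom = expm(M * t) @ x0
        part = sum(p * np.exp(-lam * t) for p, lam in zip(parts, lams))
        out[:, k] = hom + part
    return out


class TestSolverAccuracy:
    def test_matches_analytic_convolution_oracle(self, ref):
        """Adaptive solution vs the eigen/expm closed form, 48 h grid."""
        times = np.unique(np.concatenate([np.linspace(0, 2880, 97),
                                          np.geomspace(0.5, 2880, 60)]))
        sim = g.simulate_acotiamide(ref.dose, ref.blood, ref.stomach,
                                    t_end=2880.0, t_eval=times)
        exact = _analytic_stomach_solution(ref, times)
        for i, series in enumerate((sim.C_e, sim.C_T, sim.C_d)):
            scale = np.max(np.abs(exact[i]))
            assert np.max(np.abs(series - exact[i])) / scale < 1e-6

    def test_fixed_step_rk4_oracle(self, ref):
        """Classical RK4 at h = 0.01 min agrees with the adaptive solver."""
        h = 0.01
        t_end = 480.0
        mc = g.macro_constants(ref.blood)
        D = ref.dose.dose_nmol_per_kg
        M, gvec = stomach_system_matrix(ref.stomach)
        pd_p = ref.pd

        def rhs(t, y):
            c1 = D * (mc.A * np.exp(-mc.alpha * t) + mc.B * np.exp(-mc.beta * t))
            dx = M @ y[:3] + gvec * c1
            dR = pd_p.k_in - pd_p.k_out * (1 - y[1] / (pd_p.IC50 + y[1])) * y[3]
            return np.append(dx, dR)

        n = int(round(t_end / h))
        y = np.array([0.0, 0.0, 0.0, pd_p.R0])
        t = 0.0
        keep_t, keep_y = [0.0], [y.copy()]
        for i in range(n):
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            if (i + 1) % 1000 == 0:  # keep every 10 min
                keep_t.append(t)
                keep_y.append(y.copy())
        keep_t = np.array(keep_t)
        keep_y = np.array(keep_y).T

        sim = g.simulate_coupled(ref.dose, ref.blood, ref.stomach, ref.pd,
                                 t_end=t_end, t_eval=keep_t)
        for i, series in enumerate((sim.C_e, sim.C_T, sim.C_d, sim.R)):
            scale = np.max(np.abs(keep_y[i]))
            assert np.max(np.abs(series - keep_y[i])) / scale < 1e-5

    def test_grid_refinement_stability(self, ref):
        """Halving tolerances changes every summary by < 0.1 %."""
        grid = default_grid(2880.0)
        a = g.simulate_coupled(ref.dose, ref.blood, ref.stomach, ref.pd,
                               t_eval=grid)
        b = g.simulate_coupled(ref.dose, ref.blood, ref.stomach, ref.pd,
                               t_eval=grid, rtol=5e-9, atol=5e-11)
        sa, sb = g.summarize(a), g.summarize(b)
        for key in sa:
            for field, va in sa[key].items():
                vb = sb[key][field]
                assert vb == pytest.approx(va, rel=1e-3)


class TestTrajectoryInvariants:
    def test_mass_conservation_along_trajectory(self, ref, ref_sim):
        """Numerical d/dt of total stomach amount tracks the blood exchange flux."""
        sp = ref.stomach
        V_d = g.deep_pool_volume(sp)
        vols = np.array([sp.V_e, sp.V_T, V_d])
        ts = np.geomspace(1.0, 2870.0, 50)
        h = 1e-3
        peak_amount = np.max(vols @ ref_sim.dense_state(ref_sim.time)[:3])
        for t in ts:
            amt = lambda tt: vols @ ref_sim.dense_state(tt)[:3]
            d_num = (amt(t + h) - amt(t - h)) / (2 * h)
            c1 = g.blood_forcing(t, ref.blood, ref.dose)
            ce = ref_sim.dense_state(t)[0]
            assert abs(d_num - sp.Q_t * (c1 - ce)) < 1e-6 * peak_amount

    def test_non_negative_states(self, ref_sim):
        for series in (ref_sim.C_e, ref_sim.C_T, ref_sim.C_d, ref_sim.R):
            assert np.all(series >= -1e-10)

    def test_zero_dose_gives_zero_drug_and_flat_ach(self, ref):
        d0 = g.DoseRegimen(dose_per_kg=0.0)
        sim = g.simulate_coupled(d0, ref.blood, ref.stomach, ref.pd, t_end=480.0)
        for series in (sim.C1, sim.C_e, sim.C_T, sim.C_d):
            assert np.allclose(series, 0.0, atol=1e-12)
        assert np.allclose(sim.percent_baseline, 100.0, atol=1e-6)

    def test_blocked_uptake(self, ref):
        sp = g.StomachParams(Q_t=1.1, V_e=0.441, fb_PSinf=TINY, fu_PSeff=0.006,
                             V_T=0.133, k_ass=3.2e-5, k_dis=4.85e-6)
        sim = g.simulate_acotiamide(ref.dose, ref.blood, sp, t_end=480.0)
        assert np.max(sim.C_T) < 1e-12
        assert np.max(sim.C_d) < 1e-12
        assert np.max(sim.C_e) > 0.1  # vascular space still fills from blood

    def test_pd_lag_property(self, ref, ref_sim, rng):
        """Indirect response peaks strictly later than its driving concentration."""
        t_ct = ref_sim.time[np.argmax(ref_sim.C_T)]
        t_r = ref_sim.time[np.argmax(ref_sim.R)]
        assert t_r > t_ct
        # randomized positive parameter sets
        for _ in range(5):
            pdp = g.PDParams(k_in=float(rng.uniform(1e-3, 1e-2)),
                             k_out=float(rng.uniform(1e-3, 1e-2)),
                             IC50=float(rng.uniform(0.5, 10.0)))
            sim = g.simulate_coupled(ref.dose, ref.blood, ref.stomach, pdp,
                                     t_end=2880.0)
            assert sim.time[np.argmax(sim.R)] > sim.time[np.argmax(sim.C_T)]


class TestSimulateACh:
    def test_no_drug_baseline_constant(self, ref):
        t, R, pb = g.simulate_ach(ref.pd, lambda t: 0.0, t_end=2880.0)
        assert np.allclose(pb, 100.0, atol=1e-6)

    def test_constant_ic50_forcing_doubles_baseline(self, ref):
        # at C_T ≡ IC50 the loss rate halves, so R → 2·R0 with rate k_out/2
        t_end = 12.0 / (ref.pd.k_out / 2)
        t, R, pb = g.simulate_ach(ref.pd, lambda t: ref.pd.IC50, t_end=t_end)
        assert pb[-1] == pytest.approx(200.0, rel=1e-4)

    def test_joint_and_sequential_paths_agree(self, ref, ref_sim):
        C_T_fn = lambda t: float(ref_sim.dense_state(t)[1])
        t, R, pb = g.simulate_ach(ref.pd, C_T_fn, t_end=2880.0,
                                  t_eval=ref_sim.time)
        assert np.max(np.abs(R - ref_sim.R)) / np.max(ref_sim.R) < 1e-6


class TestThresholdCrossing:
    def _fake_sim(self, fn):
        t = np.linspace(0.0, 10.0, 50)
        dense = lambda tt: np.atleast_2d(fn(np.asarray(tt)))
        z = fn(t)
        return g.SimulationResult(time=t, C1=z, C_e=z, C_T=z, C_d=z,
                                  C_stomach=z, _dense=dense)

    def test_exponential_decay_analytic(self):
        sim = self._fake_sim(lambda t: np.exp(-t))
        t_star = g.threshold_crossing_time(sim, "C_e", np.exp(-1.0))
        assert t_star == pytest.approx(1.0, abs=0.01)

    def test_rising_series_has_no_downward_crossing(self):
        sim = self._fake_sim(lambda t: t)
        with pytest.raises(g.NotFoundError):
            g.threshold_crossing_time(sim, "C_e", 5.0, direction="down")
        # but it does have an upward crossing
        up = g.threshold_crossing_time(sim, "C_e", 5.0, direction="up")
        assert up == pytest.approx(5.0, abs=0.01)

    def test_latest_crossing_is_returned(self, ref_sim):
        # the precursor pool rises through 2 μM then falls through it again
        t_down = g.threshold_crossing_time(ref_sim, "C_T", 2.0, "down")
        t_up = g.threshold_crossing_time(ref_sim, "C_T", 2.0, "up")
        assert t_up < t_down


class TestSummarize:
    def test_constant_and_monotone_series(self):
        t = np.linspace(0, 10, 11)
        const = np.full_like(t, 2.5)
        sim = g.SimulationResult(time=t, C1=np.exp(-t), C_e=const, C_T=const,
                                 C_d=const, C_stomach=const)
        s = g.summarize(sim)
        assert s["C_e"]["t_max_min"] == 0.0 and s["C_e"]["c_max"] == 2.5
        assert s["C1"]["t_max_min"] == 0.0  # monotone decay peaks at t = 0

    def test_ach_peak_after_two_hours(self, ref_sim):
        s = g.summarize(ref_sim)
        assert s["percent_baseline"]["t_peak_min"] >= 120.0
        assert s["R"]["t_max_min"] == s["percent_baseline"]["t_peak_min"]

    def test_empty_rejected(self):
        empty = g.SimulationResult(time=np.array([]), C1=np.array([]),
                                   C_e=np.array([]), C_T=np.array([]),
                                   C_d=np.array([]), C_stomach=np.array([]))
        with pytest.raises(g.InvalidArgumentError):
            g.summarize(empty)
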