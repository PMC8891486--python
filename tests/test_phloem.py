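import numpy as np
import pytest
from hypothesis import given, strategies as st

from munchflow import load_preset, run
from munchflow import phloem as phl
from munchflow import _kernel as K
from munchflow.params import ParameterError


class TestMichaelisMenten:
    def test_half_saturation(self):
        assert phl.mm_rate(1.58e-7, 3.3, 3.3) == pytest.approx(7.9e-8)

    def test_limits(self):
        assert phl.mm_rate(1.0, 0.0, 3.3) == 0.0
        assert phl.mm_rate(1.0, 1e12, 3.3) == pytest.approx(1.0, rel=1e-9)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ParameterError):
            phl.mm_rate(1.0, -0.1, 3.3)


class TestRegulatedLoading:
    @given(st.floats(0.0, 1e4), st.floats(-5.0, 50.0))
    def test_beta_zero_reduces_to_plain_kinetics(self, conc, p_l):
        assert phl.regulated_loading(1.58e-7, conc, 3.3, p_l, 0.0) == \
            phl.mm_rate(1.58e-7, conc, 3.3)

    def test_downregulation_multiplier(self):
        base = phl.mm_rate(1.58e-7, 100.0, 3.3)
        reg = phl.regulated_loading(1.58e-7, 100.0, 3.3, 1.0, 0.6)
        assert reg / base == pytest.approx(np.exp(-0.6), rel=1e-12)

    def test_negative_turgor_upregulates(self, caplog):
        base = phl.mm_rate(1.58e-7, 100.0, 3.3)
        with caplog.at_level("INFO"):
            reg = phl.regulated_loading(1.58e-7, 100.0, 3.3, -0.5, 0.6)
        assert reg > base
        assert "up-regulated" in caplog.text


class TestOsmoticAndTurgor:
    def test_vant_hoff(self):
        assert phl.osmotic_potential(0.0) == 0.0
        assert phl.osmotic_potential(500.0, 8.3, 293.0) == \
            pytest.approx(-1.216, abs=1e-3)
        assert phl.osmotic_potential(1000.0) == \
            pytest.approx(2 * phl.osmotic_potential(500.0))

    def test_turgor_difference(self):
        assert phl.turgor(-0.5, -1.5) == pytest.approx(1.0)
        assert phl.turgor(-0.7, -0.7) == 0.0

    def test_r1_wet_steady_pressure_in_empirical_window(self, r1_wet):
        _, _, outcome = r1_wet
        assert 0.6 <= outcome.stats["P_l_tail"] <= 2.4


class TestSapViscosity:
    def test_dilute_limit_is_water(self):
        v0, flag = phl.sap_viscosity(0.0, 293.0)
        assert not flag
        assert v0 == pytest.approx(1.0e-9, rel=0.05)

    def test_strictly_increasing_and_convex(self):
        grid = np.linspace(0.0, 2000.0, 400)
        v = np.array([phl.sap_viscosity(c)[0] for c in grid])
        assert np.all(np.diff(v) > 0)
        assert np.all(np.diff(v, 2) > 0)

    def test_severalfold_rise_by_mid_concentration(self):
        # 0.73 M sits around 23% mass fraction, roughly 2-3x water viscosity
        v0 = phl.sap_viscosity(0.0)[0]
        v, flag = phl.sap_viscosity(730.0)
        assert not flag
        assert 2.0 < v / v0 < 5.0

    def test_supersaturated_flagged_but_finite(self):
        v, flag = phl.sap_viscosity(4000.0)
        assert flag
        assert np.isfinite(v) and v > phl.sap_viscosity(2000.0)[0]


class TestConduitAndFlow:
    def test_resistance_linear_in_viscosity(self):
        assert phl.conduit_resistance(2.4e20, 1.0e-9) == pytest.approx(2.4e11)
        assert phl.conduit_resistance(2.4e20, 2.0e-9) == \
            pytest.approx(2 * phl.conduit_resistance(2.4e20, 1.0e-9))

    def test_preset_resistance_ratio(self):
        r1 = load_preset("R1").phloem.R_p
        r5 = load_preset("R5").phloem.R_p
        v = 1.3e-9
        assert phl.conduit_resistance(r5, v) / phl.conduit_resistance(r1, v) \
            == pytest.approx(8.5e21 / 2.4e20)

    def test_flow_and_velocity(self):
        assert phl.phloem_flow(1.0, 1.0, 1e12) == 0.0
        r = 5.5e-6
        fp = np.pi * r * r * 1e-4
        assert phl.sap_velocity(fp, r) == pytest.approx(1e-4)
        # reverse flow is legal
        assert phl.phloem_flow(0.5, 1.5, 1e12) < 0


class TestSucroseStep:
    def _phloem_state(self, **kv):
        defaults = dict(pi_l=0.0, pi_u=0.0, P_l=0.0, P_u=0.0, v=1e-9,
                        R_conduit=2.4e11, F_p=0.0, V_s=0.0, E_s=0.0,
                        L_sucL=0.0, L_sucU=0.0)
        defaults.update(kv)
        return phl.PhloemState(**defaults)

    def test_quiescent_fixed_point(self, default_params):
        s0 = phl.SucroseState()
        s1 = phl.sucrose_step(s0, self._phloem_state(), 0.0,
                              default_params, 1.0)
        assert s1 == s0

    def test_closed_system_conserves_mass(self, default_params):
        # unloading and transport disabled: S_m + S_pL tracks production
        p = default_params
        s = phl.SucroseState(S_m=1e-8, S_pL=2e-9)
        anet = 15.0
        total0 = s.S_m + s.S_pL
        produced = 0.0
        for _ in range(500):
            ps = self._phloem_state(L_sucL=5e-8)
            s = phl.sucrose_step(s, ps, anet, p, 1.0)
            produced += anet * 1e-6 / 12.0 * p.hydraulic.LA
        assert (s.S_m + s.S_pL) - total0 == pytest.approx(produced, rel=1e-12)

    def test_pools_never_negative_under_overdraw(self, default_params):
        s = phl.SucroseState(S_m=1e-12, S_pL=1e-12, S_U=0.0)
        ps = self._phloem_state(L_sucL=1.0, E_s=1.0, L_sucU=1.0)
        s = phl.sucrose_step(s, ps, 0.0, default_params, 1.0)
        assert s.S_m >= 0 and s.S_pL >= 0 and s.S_U >= 0


def test_stepwise_sucrose_conservation_in_integration():
    """Delta(S_m+S_pL+S_U+S_tot) equals the photosynthetic source term
    every step, to 1e-9 relative."""
    p = load_preset("R1")
    traj, _ = run(p, t_end=1800.0, dt=1.0, stride=1.0)
    d = traj.data
    total = (d["S_m"] + d["S_pL"] + d["S_U"] + d["S_tot"]).to_numpy()
    a_suc = d["A_net"].to_numpy() * 1e-6 / 12.0 * p.hydraulic.LA
    gained = np.diff(total)
    expected = a_suc[1:] * 1.0  # dt = 1 s, source evaluated within the step
    scale = max(total[-1], 1e-30)
    assert np.max(np.abs(gained - expected)) / scale < 1e-9


def test_steady_state_loading_equals_transport_equals_unloading(r1_wet):
    params, traj, outcome = r1_wet
    assert outcome.status == "steady"
    la = params.hydraulic.LA
    tail = traj.tail(3600.0)
    load = tail["L_sucL"].mean() * la
    es = tail["E_s"].mean()
    unload = tail["L_sucU"].mean() * la
    assert abs(load - es) / es < 1e-3
    assert abs(es - unload) / es < 1e-3


def test_cumulative_export_monotone_and_reported_in_mg(r1_wet):
    _, traj, _ = r1_wet
    stot = traj.data["S_tot"].to_numpy()
    assert np.all(np.diff(stot) >= 0)
    assert traj.stot_mg == pytest.approx(stot[-1] * 342.3e3)
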