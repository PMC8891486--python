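import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from munchflow import load_preset, run
from munchflow.params import ParameterError
from munchflow import hydraulics as hyd

AF, PI_O, EPS = 0.3, -1.2, 12.0


class TestRelativeWaterContent:
    def test_basic_ratio(self):
        assert hyd.relative_water_content(1.0, 1.0) == 1.0
        assert hyd.relative_water_content(0.9, 1.0) == pytest.approx(0.9)

    def test_supersaturation_clamps_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert hyd.relative_water_content(1.01, 1.0) == 1.0
        assert "clamping" in caplog.text

    def test_emptied_symplasm_is_an_error(self):
        with pytest.raises(ParameterError, match="symplasm"):
            hyd.relative_water_content(0.25, 1.0, af=0.3)


class TestPressureVolumeCurve:
    def test_zero_at_full_hydration(self):
        assert hyd.pv_water_potential(1.0, PI_O, AF, EPS) == pytest.approx(0.0)

    def test_continuous_at_turgor_loss_point(self):
        # branch point: symplastic content where turgor hits zero
        rs_tlp = 1.0 + PI_O / EPS
        rwc_tlp = AF + rs_tlp * (1.0 - AF)
        left = hyd.pv_water_potential(rwc_tlp - 1e-9, PI_O, AF, EPS)
        right = hyd.pv_water_potential(rwc_tlp + 1e-9, PI_O, AF, EPS)
        assert abs(left - right) < 1e-7
        pi_tlp = PI_O * EPS / (PI_O + EPS)
        assert hyd.pv_water_potential(rwc_tlp, PI_O, AF, EPS) == \
            pytest.approx(pi_tlp, rel=1e-12)

    def test_strictly_increasing_in_rwc(self):
        grid = np.linspace(AF + 1e-3, 1.0, 1000)
        vals = [hyd.pv_water_potential(r, PI_O, AF, EPS) for r in grid]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] == pytest.approx(0.0)


class TestVulnerabilityIntegral:
    def test_empty_interval(self):
        assert hyd.vulnerability_flow(-1.0, -1.0, 20.0, 2.0, -2.0) == 0.0

    def test_saturated_range_approximates_kmax_times_width(self):
        flow = hyd.vulnerability_flow(-0.2, -0.1, 20.0, 2.0, -2.0)
        assert flow == pytest.approx(20.0 * 0.1, rel=0.03)

    def test_matches_adaptive_quadrature(self):
        rng = np.random.default_rng(42)
        kmax, alpha, psi50 = 20.0, 2.0, -2.0

        def k(psi):
            return kmax / (1.0 + np.exp(-alpha * (psi - psi50)))

        for _ in range(100):
            a, b = sorted(rng.uniform(-5.0, 0.0, size=2))
            expected, _ = quad(k, a, b, epsabs=1e-13, epsrel=1e-12)
            got = hyd.vulnerability_flow(a, b, kmax, alpha, psi50)
            assert got == pytest.approx(expected, rel=1e-8, abs=1e-12)

    def test_sign_follows_integration_direction(self):
        down = hyd.vulnerability_flow(-1.0, -0.5, 20.0, 2.0, -2.0)
        up = hyd.vulnerability_flow(-0.5, -1.0, 20.0, 2.0, -2.0)
        assert down > 0 and up == -down


class TestStomata:
    def test_half_closure_at_gs_psi50(self):
        assert hyd.stomatal_conductance(-1.5, 400.0, 2.0, -1.5) == \
            pytest.approx(200.0)

    def test_table_values(self):
        gs = hyd.stomatal_conductance(0.0, 400.0, 2.0, -1.5)
        assert gs == pytest.approx(400.0 / (1.0 + np.exp(-3.0)), rel=1e-12)
        assert gs == pytest.approx(381.0, abs=0.1)

    def test_closes_fully_under_extreme_stress(self):
        assert hyd.stomatal_conductance(-50.0, 400.0, 2.0, -1.5) < 1e-10

    @given(st.floats(-5.0, 0.0), st.floats(-5.0, 0.0))
    def test_monotone_in_water_potential(self, a, b):
        lo, hi = sorted((a, b))
        assert hyd.stomatal_conductance(lo, 400.0, 2.0, -1.5) <= \
            hyd.stomatal_conductance(hi, 400.0, 2.0, -1.5) + 1e-12


class TestAssimilation:
    def test_closed_stomata_respire(self, default_params):
        assert hyd.net_assimilation(0.0, default_params) <= 0.0

    def test_monotone_and_bounded(self, default_params):
        gs_grid = np.linspace(0.0, default_params.hydraulic.g_max, 200)
        a = [hyd.net_assimilation(g, default_params) for g in gs_grid]
        assert np.all(np.diff(a) >= 0)
        assert a[-1] < default_params.A_max  # below the saturating ceiling
        assert a[-1] == pytest.approx(0.9 * default_params.A_max,
                                      rel=0.05)  # by construction of k


class TestWaterBalance:
    def test_no_demand_no_gradient_fixed_point(self, default_params):
        p = default_params.with_overrides(VPD=0.0, psi_s=-0.0)
        state = hyd.initial_water_state(p)
        for _ in range(50):
            state = hyd.water_balance_step(state, p, dt=1.0)
        assert state.W_m == pytest.approx(p.hydraulic.V_sat_m, rel=1e-12)
        assert state.psi_m == pytest.approx(0.0, abs=1e-12)
        assert state.inflow == pytest.approx(0.0, abs=1e-12)
        assert state.E == 0.0

    def test_hydraulic_steady_state_flux_balance(self, r1_wet):
        _, traj, _ = r1_wet
        tail = traj.tail(3600.0)
        inflow = tail["inflow"].mean()
        e = tail["E"].mean()
        assert abs(inflow - e) / e < 1e-3
        # xylem inflow equals mesophyll inflow by the steady-xylem update
        psi_x = tail["psi_x"].mean()
        p = traj.params
        xylem_in = p.hydraulic.K_max_x * (p.env.psi_s - psi_x)
        assert abs(xylem_in - inflow) / e < 1e-3

    def test_drier_soil_lowers_psi_m_and_gs(self, r1_wet, r1_dry):
        _, wet, _ = r1_wet
        _, dry, _ = r1_dry
        assert dry.tail_mean("psi_m") < wet.tail_mean("psi_m")
        assert dry.tail_mean("g_s") < wet.tail_mean("g_s")


def test_timestep_halving_converges():
    p = load_preset("R1")
    t1, _ = run(p, t_end=43200.0, dt=1.0)
    t2, _ = run(p, t_end=43200.0, dt=0.5)
    assert abs(t1.data["psi_m"].iloc[-1] - t2.data["psi_m"].iloc[-1]) < 0.01
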