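import numpy as np
import pandas as pd
import pytest

from calshock.biophysics import StimulusProtocol
from calshock.signaling import KineticParameters
from calshock.simulator import (
    SolverSettings,
    StrainConfig,
    Trace,
    calibrate_resting_calmodulin,
    flux_decomposition,
    mixing_time_scan,
    resting_baseline,
    simulate,
    stationary_resting_state,
    strain_parameters,
    trace_metrics,
)


class TestStrainParameters:
    def test_cnb1_patch(self, kinetic):
        p = strain_parameters("cnb1", kinetic)
        assert p.CaN_t == 0.0
        assert p.v_Pmc1 == 41_079.0
        assert p.k_Cch1 == kinetic.k_Cch1

    def test_cch1_patch(self, kinetic):
        p = strain_parameters("cch1Δ", kinetic)
        assert p.k_Cch1 == 0.0
        assert p.v_Pmc1 == 41_079.0

    def test_flc2_patch(self, kinetic):
        p = strain_parameters("flc2", kinetic)
        assert p.k_MS == 238_519.0
        assert p.v_Pmc1 == kinetic.v_Pmc1

    def test_extra_overrides_stack_on_named_strain(self, kinetic):
        cfg = StrainConfig(name="cnb1", overrides={"k_MS": 0.0})
        p = strain_parameters(cfg, kinetic)
        assert p.CaN_t == 0.0 and p.k_MS == 0.0

    def test_unknown_strain_rejected(self):
        with pytest.raises(ValueError):
            StrainConfig(name="nonexistent")


class TestRestingBaseline:
    def test_ms_knockout_baseline_near_160(self, kinetic, biophys, protocol):
        params = kinetic.with_overrides(k_MS=0.0)
        ca, camb = stationary_resting_state(params, biophys, protocol)
        assert ca == pytest.approx(160.0, rel=0.10)
        # insensitive to the resting bound calmodulin (Vcx1 is suppressed)
        for camb0 in (0.5, 5.0, 500.0, 2500.0):
            assert resting_baseline(params, camb0, biophys, protocol) == pytest.approx(
                ca, rel=0.02
            )

    def test_efflux_only_limit(self, biophys, protocol):
        params = KineticParameters(k_MS=0.0, k_Cch1=0.0, v_IN=0.0)
        assert resting_baseline(params, 1.0, biophys, protocol) == 0.0

    def test_agrees_with_independent_bisection(self, kinetic, biophys, protocol):
        from scipy.optimize import bisect
        from calshock.signaling import SignalingState, calcium_rate, quasi_steady_canb

        camb0 = 1.0

        def residual(ca):
            state = SignalingState(ca, camb0, quasi_steady_canb(camb0, kinetic))
            return calcium_rate(state, 0.0, biophys.P_0, kinetic, protocol)[0]

        expected = bisect(residual, 1.0, 29_500.0, xtol=1e-8)
        assert resting_baseline(kinetic, camb0, biophys, protocol) == pytest.approx(
            expected, abs=1e-6
        )


class TestCalibration:
    def test_wild_type_target_215(self, kinetic, biophys, protocol):
        camb0 = calibrate_resting_calmodulin(kinetic, 215.0, biophys, protocol)
        assert 0.5 < camb0 < 1.5  # ~1 nM of bound calmodulin at rest
        assert resting_baseline(kinetic, camb0, biophys, protocol) == pytest.approx(
            215.0, abs=1e-6
        )

    def test_fixed_point_identity(self, kinetic, biophys, protocol):
        b0 = resting_baseline(kinetic, 0.0, biophys, protocol)
        assert calibrate_resting_calmodulin(
            kinetic, b0, biophys, protocol
        ) == pytest.approx(0.0, abs=1e-6)

    def test_non_identifiable_when_ms_inert(self, kinetic, biophys, protocol):
        params = kinetic.with_overrides(k_MS=0.0)
        with pytest.raises(RuntimeError, match="non-identifiable"):
            calibrate_resting_calmodulin(params, 160.0, biophys, protocol)

    def test_unreachable_target_reports_range(self, kinetic, biophys, protocol):
        with pytest.raises(ValueError, match="achievable"):
            calibrate_resting_calmodulin(kinetic, 50.0, biophys, protocol)

    def test_knockout_continuity(self, kinetic, biophys, protocol):
        # the calibrated-CaMb-free baseline approaches the MS-off baseline
        off = stationary_resting_state(
            kinetic.with_overrides(k_MS=0.0), biophys, protocol
        )[0]
        baselines = [
            resting_baseline(
                kinetic.with_overrides(k_MS=k), 2_500.0, biophys, protocol
            )
            for k in (1e4, 1e2, 1.0, 1e-2)
        ]
        gaps = [abs(b - off) for b in baselines]
        assert all(np.diff(gaps) <= 0)
        assert gaps[-1] < 0.1


class TestSimulate:
    def test_no_shock_stays_near_baseline(self, kinetic, biophys):
        proto = StimulusProtocol(d=1.0)
        trace = simulate(kinetic, biophys, proto)
        # pre-stimulus window is flat to a fraction of a percent ...
        m = trace_metrics(trace, proto)
        assert m["baseline"] == pytest.approx(215.0, rel=0.005)
        # ... while the slow calmodulin creep drifts the long tail by ~2%
        assert np.abs(trace.Ca_cyt / 215.0 - 1.0).max() < 0.025

    def test_wild_type_single_transient(self, wt_trace, protocol):
        m = trace_metrics(wt_trace, protocol)
        assert m["peak"] > 2 * m["baseline"]
        assert 0 < m["time_to_peak"] < 60
        post = wt_trace.time >= protocol.t_off
        final = wt_trace.Ca_cyt[post][-1]
        assert final < 0.5 * m["peak"]  # decays back toward baseline

    def test_volume_increases_only_a_few_percent(self, wt_trace, biophys):
        total = wt_trace.V_os + biophys.V_b
        rel = total.max() / biophys.V_total0 - 1.0
        assert 0.0 < rel < 0.10

    def test_deterministic_bitwise(self, kinetic, biophys, protocol):
        a = simulate(kinetic, biophys, protocol)
        b = simulate(kinetic, biophys, protocol)
        np.testing.assert_array_equal(a.Ca_cyt, b.Ca_cyt)
        np.testing.assert_array_equal(a.V_os, b.V_os)

    def test_grid_refinement_converges(self, kinetic, biophys, protocol):
        coarse = simulate(kinetic, biophys, protocol,
                          settings=SolverSettings(output_dt=0.5))
        fine = simulate(kinetic, biophys, protocol,
                        settings=SolverSettings(output_dt=0.25))
        common = np.isin(fine.time, coarse.time)
        assert np.abs(fine.Ca_cyt[common] - coarse.Ca_cyt).max() < 0.05

    def test_tolerance_robustness(self, kinetic, biophys, protocol):
        loose = simulate(kinetic, biophys, protocol)
        tight = simulate(
            kinetic, biophys, protocol,
            settings=SolverSettings(rtol=1e-9, atol=(1e-23, 1e-7, 1e-10, 1e-10)),
        )
        m1, m2 = (trace_metrics(t, protocol) for t in (loose, tight))
        assert abs(m1["baseline"] / m2["baseline"] - 1) < 1e-3
        assert abs(m1["peak"] / m2["peak"] - 1) < 1e-3

    def test_conservation_bounds_along_trajectories(self, kinetic, biophys, protocol):
        for strain in ("wild-type", "cnb1", "cch1", "flc2"):
            params = strain_parameters(strain, kinetic)
            trace = simulate(kinetic, biophys, protocol, strain=strain)
            assert (trace.Ca_cyt >= 0).all()
            assert (trace.CaMb >= -1e-9).all()
            assert (trace.CaMb <= params.CaM_t + 1e-9).all()
            assert (trace.CaNb >= -1e-9).all()
            assert (trace.CaNb <= params.CaN_t + 1e-9).all()

    def test_metadata_records_resting_state(self, wt_trace):
        rs = wt_trace.metadata["resting_state"]
        assert rs["Ca_cyt0"] == pytest.approx(215.0, abs=1e-6)
        assert "parameter_hash" in wt_trace.metadata


class TestTraceMetrics:
    def test_flat_trace(self):
        proto = StimulusProtocol(t_off=30.0, t_end=160.0)
        t = np.arange(0.0, 161.0)
        trace = _bare_trace(t, np.full_like(t, 100.0))
        m = trace_metrics(trace, proto)
        assert (m["baseline"], m["peak"], m["time_to_peak"]) == (100.0, 100.0, 0.0)

    def test_triangular_pulse(self):
        proto = StimulusProtocol(t_off=30.0, t_end=160.0)
        t = np.arange(0.0, 161.0)
        ca = np.full_like(t, 100.0)
        rise = (t >= 30) & (t <= 50)
        fall = (t > 50) & (t <= 70)
        ca[rise] = 100 + (t[rise] - 30) * 20
        ca[fall] = 500 - (t[fall] - 50) * 20
        m = trace_metrics(_bare_trace(t, ca), proto)
        assert m["baseline"] == 100.0
        assert m["peak"] == 500.0
        assert m["time_to_peak"] == 20.0

    def test_missing_window_rejected(self):
        proto = StimulusProtocol(t_off=30.0, t_end=160.0)
        t = np.arange(40.0, 161.0)
        with pytest.raises(ValueError):
            trace_metrics(_bare_trace(t, np.full_like(t, 1.0)), proto)


class TestMixingTimeScan:
    def test_single_element_grid(self, kinetic, biophys, protocol):
        table, best = mixing_time_scan(kinetic, biophys, protocol, [9.1])
        assert best == 9.1
        assert len(table) == 1

    def test_grid_order_irrelevant(self, kinetic, biophys, protocol):
        grid = [5.0, 15.0, 10.0]
        t1, b1 = mixing_time_scan(kinetic, biophys, protocol, grid)
        t2, b2 = mixing_time_scan(kinetic, biophys, protocol, sorted(grid))
        pd.testing.assert_frame_equal(t1, t2)
        assert b1 == b2

    def test_invalid_grid_rejected(self, kinetic, biophys, protocol):
        with pytest.raises(ValueError):
            mixing_time_scan(kinetic, biophys, protocol, [])
        with pytest.raises(ValueError):
            mixing_time_scan(kinetic, biophys, protocol, [-1.0])


class TestFluxDecomposition:
    def test_net_flux_matches_calcium_derivative(self, wt_trace, protocol):
        table = flux_decomposition(wt_trace)
        dca_fd = np.gradient(wt_trace.Ca_cyt, wt_trace.time)
        keep = np.abs(wt_trace.time - protocol.t_off) > 1.0
        err = np.abs(table["net_flux"].to_numpy()[keep] - dca_fd[keep])
        assert err.max() < 0.01 * np.abs(dca_fd).max()

    def test_vcx1_heavily_suppressed(self, wt_trace):
        table = flux_decomposition(wt_trace)
        assert (table["vcx1_inhibition_ratio"] < 1e-3).all()

    def test_pmc1_dominates_recovery(self, wt_trace, protocol):
        m = trace_metrics(wt_trace, protocol)
        t_peak = protocol.t_off + m["time_to_peak"]
        table = flux_decomposition(wt_trace)
        post = table["time_s"] > t_peak
        assert (table.loc[post, "j_pmc1"] > table.loc[post, "j_pmr1"]).all()
        assert (table.loc[post, "j_pmc1"] > table.loc[post, "j_vcx1"]).all()


class TestTraceIO:
    def test_csv_round_trip(self, wt_trace, tmp_path):
        path = wt_trace.to_csv(tmp_path / "wt.csv")
        back = Trace.from_csv(path)
        np.testing.assert_allclose(back.Ca_cyt, wt_trace.Ca_cyt, rtol=1e-10)
        np.testing.assert_allclose(back.V_os, wt_trace.V_os, rtol=1e-10)
        assert back.metadata["strain"] == "wild-type"

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            Trace.from_frame(pd.DataFrame({"time_s": [0.0, 1.0]}))


def _bare_trace(t, ca):
    z = np.zeros_like(t)
    return Trace(
        time=t, V_os=z, Ca_cyt=ca, CaMb=z, CaNb=z, turgor=z, P_open=z,
        Ca_ex=z, j_Cch1=z, j_MS=z, j_Pmc1=z, j_Vcx1=z, j_Pmr1=z,
        j_MS0=z, j_Vcx10=z,
    )
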