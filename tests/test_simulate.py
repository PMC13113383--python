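"""Simulator tests: RHS assembly, integration contract, trace persistence."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from prfield import (CircuitParameters, FieldStimulus, NeuronParameters,
                     NeuronState, SimulationConfig, Trace, derivatives,
                     initial_state, read_trace, simulate, write_trace)
from prfield.simulate import STATE_ORDER, _make_rhs
from conftest import random_states


class TestInitialState:
    def test_gates_start_at_steady_state(self, params):
        from prfield import gate_steady_and_tau
        st = initial_state(params)
        assert st.Vs == st.Vd == 0.0
        for gate in ("h", "n", "s", "c"):
            assert getattr(st, gate) == gate_steady_and_tau(gate, 0.0)[0]
        assert st.q == gate_steady_and_tau("q", 0.0, 0.2)[0]
        assert st.Ca == 0.2 and st.Si == 0.0 and st.Wi == 0.0

    def test_override_applies(self, params):
        assert initial_state(params, Vs=10.0).Vs == 10.0

    def test_deterministic(self, params):
        assert initial_state(params) == initial_state(params)

    def test_unknown_override_rejected(self, params):
        with pytest.raises(ValueError):
            initial_state(params, Vz=1.0)


class TestDerivatives:
    def test_quiescent_passive_cell(self):
        pr = NeuronParameters(gc=0, gL=0, gNa=0, gKDR=0, gCa=0, gKAHP=0,
                              gKC=0, gNMDA=0, gAMPA=0, Is=0.0, Id=0.0)
        d = derivatives(0.0, NeuronState(), pr)
        assert d[0] == 0.0 and d[1] == 0.0

    def test_reference_path_matches_fast_closure(self, params, circuit, rng):
        stim = FieldStimulus(A=100.0, f=10.0)
        rhs = _make_rhs(params, circuit, stim, "self")
        for st in random_states(rng, 50):
            t = float(rng.uniform(0.0, 200.0))
            ref = derivatives(t, st, params, circuit, stim, "self")
            fast = np.asarray(rhs(t, st.as_array()))
            np.testing.assert_allclose(fast, ref, rtol=1e-12, atol=1e-12)

    def test_field_off_zero_rout_limit_matches_isolated_cell(self, params, rng):
        # RDSout -> 0 with no field recovers the isolated two-compartment RHS
        tiny = CircuitParameters.from_rout(1e-9, RDSin=80.0)
        for st in random_states(rng, 20):
            with_circ = derivatives(0.0, st, params, tiny, None)
            isolated = derivatives(0.0, st, params, None, None)
            np.testing.assert_allclose(with_circ, isolated, rtol=1e-9,
                                       atol=1e-9)

    def test_nonfinite_state_identified(self, params):
        bad = NeuronState(Vs=math.nan)
        with pytest.raises(ValueError, match="Vs"):
            derivatives(0.0, bad, params)


class TestSimulate:
    def test_baseline_cell_fires(self):
        cfg = SimulationConfig(t_end=1500.0, burn_in=500.0, sample_dt=0.05)
        trace = simulate(cfg)
        from prfield import detect_spikes
        assert detect_spikes(trace).n > 0

    def test_passive_cell_settles(self):
        # without Na channels or drive the cell relaxes to a fixed point;
        # the slowest mode is the 1000 ms AHP gate, hence the long horizon
        pr = NeuronParameters(gNa=0.0, Id=0.0)
        cfg = SimulationConfig(params=pr, t_end=9000.0, burn_in=1000.0,
                               sample_dt=0.5)
        trace = simulate(cfg)
        from prfield import detect_spikes
        assert detect_spikes(trace).n == 0
        dvs = np.diff(trace.Vs[-20:]) / cfg.sample_dt
        assert np.abs(dvs).max() < 1e-6

    def test_bitwise_deterministic(self, short_config):
        a = simulate(short_config)
        b = simulate(short_config)
        assert np.array_equal(a.Vs, b.Vs)
        assert np.array_equal(a.Vd, b.Vd)
        assert np.array_equal(a.VDSout, b.VDSout)

    def test_gating_bounds_and_calcium_positive(self, short_config):
        from dataclasses import replace
        trace = simulate(replace(short_config, t_end=800.0, burn_in=200.0),
                         keep_gates=True)
        for gate in ("h", "n", "s", "c", "q"):
            g = trace.extras[gate]
            assert g.min() >= 0.0 and g.max() <= 1.0
        assert trace.extras["Ca"].min() >= 0.0

    def test_uniform_grid_and_lengths(self, short_config):
        trace = simulate(short_config)
        dt = np.diff(trace.t)
        assert np.allclose(dt, short_config.sample_dt, rtol=0, atol=1e-9)
        assert len(trace.t) == len(trace.Vs) == len(trace.Vd) == len(trace.VDSout)

    def test_reduction_to_plain_two_compartment_dynamics(self):
        """Field off + RDSout->0 matches an independently coded isolated-cell
        integrator to < 0.5 mV over 1 s."""
        # tight tolerances so the comparison probes the equations rather than
        # spike-timing amplification of solver-level rounding
        cfg = SimulationConfig(circuit=CircuitParameters.from_rout(1e-12, RDSin=80.0),
                               stimulus=None, t_end=1000.0, burn_in=0.0,
                               sample_dt=0.05, rel_tol=1e-9, abs_tol=1e-11)
        trace = simulate(cfg)
        oracle = _integrate_isolated_cell_oracle(cfg)
        assert np.abs(trace.Vs - oracle).max() < 0.5

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(t_end=100.0, burn_in=100.0)
        with pytest.raises(ValueError):
            SimulationConfig(sample_dt=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(synapse_mode="maybe")

    def test_config_hash_sensitivity(self, short_config):
        from dataclasses import replace
        assert short_config.content_hash() == short_config.content_hash()
        other = replace(short_config,
                        params=NeuronParameters(VK=-40.0))
        assert other.content_hash() != short_config.content_hash()


def _integrate_isolated_cell_oracle(cfg):
    """Literal, self-contained integrator of the isolated two-compartment
    cell (no extracellular network), written independently of the package's
    RHS assembly."""
    p, Cm, gc = 0.5, 3.0, 2.1
    gL, gNa, gKDR, gCa, gKAHP, gKC = 0.1, 30.0, 15.0, 10.0, 0.8, 15.0
    gNMDA, gAMPA = 0.03, 0.0045
    VNa, VCa, VK, Vsyn = 120.0, 140.0, -38.56, 60.0
    Is, Id = 0.0, 0.7

    def f(t, y):
        Vs, Vd, h, n, s, c, q, Ca, Si, Wi = y
        am = 0.32 * (13.1 - Vs) / (math.exp((13.1 - Vs) / 4.0) - 1.0)
        bm = 0.28 * (Vs - 40.1) / (math.exp((Vs - 40.1) / 5.0) - 1.0)
        ah = 0.128 * math.exp((17.0 - Vs) / 18.0)
        bh = 4.0 / (1.0 + math.exp((40.0 - Vs) / 5.0))
        an = 0.016 * (35.1 - Vs) / (math.exp((35.1 - Vs) / 5.0) - 1.0)
        bn = 0.25 * math.exp(0.5 - 0.025 * Vs)
        a_s = 1.6 / (1.0 + math.exp(-0.072 * (Vd - 65.0)))
        b_s = 0.02 * (Vd - 51.1) / (math.exp((Vd - 51.1) / 5.0) - 1.0)
        if Vd <= 50.0:
            ac = math.exp((Vd - 10.0) / 11.0 - (Vd - 6.5) / 27.0) / 18.975
            bc = 2.0 * math.exp((6.5 - Vd) / 27.0) - ac
        else:
            ac = 2.0 * math.exp((6.5 - Vd) / 27.0)
            bc = 0.0
        aq, bq = min(0.00002 * Ca, 0.01), 0.001
        minf = am / (am + bm)
        INa = gNa * minf * minf * h * (Vs - VNa)
        IKDR = gKDR * n * (Vs - VK)
        ICa = gCa * s * s * (Vd - VCa)
        IKC = gKC * c * min(Ca / 250.0, 1.0) * (Vd - VK)
        IKAHP = gKAHP * q * (Vd - VK)
        INMDA = gNMDA * Si / (1.0 + 0.28 * math.exp(-0.062 * (Vd - 60.0))) \
            * (Vd - Vsyn)
        IAMPA = gAMPA * Wi * (Vd - Vsyn)
        IDS = gc * (Vd - Vs)
        return [(-gL * Vs - INa - IKDR + IDS / p + Is / p) / Cm,
                (-gL * Vd - ICa - IKAHP - IKC - INMDA - IAMPA
                 - IDS / (1.0 - p) + Id / (1.0 - p)) / Cm,
                ah * (1 - h) - bh * h, an * (1 - n) - bn * n,
                a_s * (1 - s) - b_s * s, ac * (1 - c) - bc * c,
                aq * (1 - q) - bq * q, -0.13 * ICa - 0.075 * Ca,
                (1.0 if Vs >= 10.0 else 0.0) - Si / 150.0,
                (1.0 if Vs >= 20.0 else 0.0) - Wi / 2.0]

    y0 = initial_state(NeuronParameters()).as_array()
    t_eval = np.arange(0.0, cfg.t_end + cfg.sample_dt / 2, cfg.sample_dt)
    sol = solve_ivp(f, (0.0, cfg.t_end), y0, method="BDF", t_eval=t_eval,
                    rtol=cfg.rel_tol, atol=cfg.abs_tol, max_step=cfg.max_step)
    assert sol.success
    return sol.y[0]


class TestTracePersistence:
    @pytest.mark.parametrize("suffix", [".csv", ".npz"])
    def test_round_trip(self, tmp_path, suffix):
        t = np.arange(0.0, 1.0, 0.05)
        trace = Trace(t=t, Vs=np.sin(t), Vd=np.cos(t), VDSout=0.1 * t,
                      extras={"Ca": t ** 2})
        path = tmp_path / f"trace{suffix}"
        write_trace(trace, path)
        back = read_trace(path)
        for a, b in [(trace.t, back.t), (trace.Vs, back.Vs),
                     (trace.Vd, back.Vd), (trace.VDSout, back.VDSout),
                     (trace.extras["Ca"], back.extras["Ca"])]:
            np.testing.assert_allclose(b, a, rtol=1e-9, atol=1e-12)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_trace(path)

    def test_truncated_record_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t_ms,Vs_mV,Vd_mV,VDSout_mV\n0.0,1.0,2.0,0.0\n0.05,1.0\n")
        with pytest.raises(ValueError, match="malformed|fields"):
            read_trace(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("t_ms,Vs_mV\n0.0,1.0\n")
        with pytest.raises(ValueError, match="Vd_mV|fields"):
            read_trace(path)
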