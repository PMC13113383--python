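"""Assembly and stiff integration of the full field-coupled neuron model.

The ODE state is ordered (Vs, Vd, h, n, s, c, q, Ca, Si, Wi).  At every
derivative evaluation the extracellular network is solved algebraically
(quasi-static approximation) for VDSout, which enters the coupling current
IDSin = gc*(Vd + VDSout - Vs); the membrane equations are

    Cm dVs/dt = -Isleak - INa - IKDR + IDSin/p       + Is/p
    Cm dVd/dt = -Idleak - ICa - IKAHP - IKC - Isyn - IDSin/(1-p) + Id/(1-p)

Integration uses a BDF stiff solver at rel_tol 1e-6 / abs_tol 1e-8 with a
0.5 ms maximum step, sampled on a uniform 0.01 ms grid over 0-5000 ms by
default; the first 1000 ms are kept in the trace but masked out by the
analysis layer as burn-in.  The Heaviside synaptic drive makes the RHS
discontinuous; no event detection is used — the bounded step size keeps
the induced error small.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .circuit import CircuitParameters, FieldStimulus, field_voltage, vdsout_closed_form
from .model import (NeuronParameters, NeuronState, gate_steady_and_tau,
                    ionic_currents, calcium_derivative, rate_constants,
                    synaptic_gate_derivatives)

__all__ = [
    "STATE_ORDER",
    "SimulationConfig",
    "Trace",
    "SimulationError",
    "initial_state",
    "derivatives",
    "simulate",
    "write_trace",
    "read_trace",
]

#: Fixed ordering of the ODE state vector.
STATE_ORDER = ("Vs", "Vd", "h", "n", "s", "c", "q", "Ca", "Si", "Wi")

_GATE_TOL = 1e-6  # permitted numerical excursion of gates outside [0,1]


class SimulationError(RuntimeError):
    """Raised when the stiff solver fails or produces a non-finite trace."""


@dataclass(frozen=True)
class SimulationConfig:
    """One fully specified simulation run.

    ``circuit=None`` removes the extracellular network entirely (VDSout = 0,
    the isolated two-compartment cell); ``stimulus=None`` silences the field
    source (Ve = 0) while keeping the resistive feedback of an attached
    circuit.  ``synapse_mode`` selects whether the cell's own somatic spikes
    drive its NMDA/AMPA gates ("self", the single-neuron reading of the
    recurrent synapse) or the synaptic current is ablated ("off").
    """

    params: NeuronParameters = field(default_factory=NeuronParameters)
    circuit: CircuitParameters | None = None
    stimulus: FieldStimulus | None = None
    t_end: float = 5000.0     # ms
    sample_dt: float = 0.01   # ms
    burn_in: float = 1000.0   # ms
    rel_tol: float = 1e-6
    abs_tol: float = 1e-8
    max_step: float = 0.5     # ms
    synapse_mode: str = "self"
    initial: NeuronState | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.burn_in < self.t_end:
            raise ValueError(
                f"need 0 <= burn_in < t_end, got burn_in={self.burn_in}, "
                f"t_end={self.t_end}")
        if self.sample_dt <= 0.0:
            raise ValueError(f"sample_dt must be positive, got {self.sample_dt}")
        if self.rel_tol <= 0.0 or self.abs_tol <= 0.0 or self.max_step <= 0.0:
            raise ValueError("solver tolerances and max_step must be positive")
        if self.synapse_mode not in ("self", "off"):
            raise ValueError(
                f"synapse_mode must be 'self' or 'off', got {self.synapse_mode!r}")

    def resolved(self) -> dict:
        """Plain-dict view of every parameter that affects the run."""
        d: dict = {
            "params": {f: getattr(self.params, f) for f in
                       self.params.__dataclass_fields__},
            "circuit": None if self.circuit is None else
                       {"RDSin": self.circuit.RDSin, "RDSout": self.circuit.RDSout},
            "stimulus": None if self.stimulus is None else
                        {"A": self.stimulus.A, "f": self.stimulus.f},
            "t_end": self.t_end, "sample_dt": self.sample_dt,
            "burn_in": self.burn_in, "rel_tol": self.rel_tol,
            "abs_tol": self.abs_tol, "max_step": self.max_step,
            "synapse_mode": self.synapse_mode,
            "initial": None if self.initial is None else
                       list(self.initial.as_array()),
        }
        return d

    def content_hash(self) -> str:
        """SHA-256 of the resolved configuration (cache/provenance key)."""
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class Trace:
    """Uniformly sampled simulation output.

    ``extras`` may carry the gating/calcium/synaptic series keyed by state
    name; ``meta`` holds free-form provenance (e.g. ground-truth spike times
    for synthetic fixtures).
    """

    t: np.ndarray
    Vs: np.ndarray
    Vd: np.ndarray
    VDSout: np.ndarray
    config: SimulationConfig | None = None
    extras: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("Vs", "Vd", "VDSout"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name} length != time grid length")
        if n > 1:
            dt = np.diff(self.t)
            if not (dt > 0).all():
                raise ValueError("time grid must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])


def initial_state(params: NeuronParameters, **overrides: float) -> NeuronState:
    """Deterministic rest initialisation.

    Both compartments start at 0 mV (the model-frame rest), the h, n, s, c
    gates at their steady state for 0 mV, q at its steady state for the
    initial calcium level 0.2, and the synaptic weights at zero.  Any state
    component can be overridden by keyword.
    """
    Ca0 = float(overrides.get("Ca", 0.2))
    st = NeuronState(
        Vs=0.0, Vd=0.0,
        h=gate_steady_and_tau("h", 0.0)[0],
        n=gate_steady_and_tau("n", 0.0)[0],
        s=gate_steady_and_tau("s", 0.0)[0],
        c=gate_steady_and_tau("c", 0.0)[0],
        q=gate_steady_and_tau("q", 0.0, Ca0)[0],
        Ca=Ca0, Si=0.0, Wi=0.0)
    for k, v in overrides.items():
        if k not in STATE_ORDER:
            raise ValueError(f"unknown state component {k!r}")
        setattr(st, k, float(v))
    return st


def derivatives(t: float, state: NeuronState, params: NeuronParameters,
                circuit: CircuitParameters | None = None,
                stim: FieldStimulus | None = None,
                synapse_mode: str = "self") -> np.ndarray:
    """Readable reference evaluation of the full right-hand side.

    Mirrors the fast closure used by :func:`simulate` term by term; kept as
    the inspectable public contract (and cross-checked against the closure
    in the test suite).
    """
    y = state.as_array()
    for name, v in zip(STATE_ORDER, y):
        if not math.isfinite(v):
            raise ValueError(f"non-finite state component {name} = {v}")
    Ve = float(field_voltage(stim, t)) if stim is not None else 0.0
    if circuit is not None:
        VDSout = vdsout_closed_form(circuit.RDSin, circuit.RDSout,
                                    state.Vs - state.Vd, Ve)
    else:
        VDSout = 0.0
    cur = ionic_currents(state, params, VDSout)
    p, Cm = params.p, params.Cm
    dVs = (-cur.Isleak - cur.INa - cur.IKDR + cur.IDSin / p + params.Is / p) / Cm
    dVd = (-cur.Idleak - cur.ICa - cur.IKAHP - cur.IKC - cur.Isyn
           - cur.IDSin / (1.0 - p) + params.Id / (1.0 - p)) / Cm
    out = [dVs, dVd]
    for gate, val in zip(("h", "n", "s", "c"), (state.h, state.n, state.s, state.c)):
        V = state.Vs if gate in ("h", "n") else state.Vd
        a, b = rate_constants(gate, V)
        out.append(a * (1.0 - val) - b * val)
    aq, bq = rate_constants("q", 0.0, state.Ca)
    out.append(aq * (1.0 - state.q) - bq * state.q)
    out.append(calcium_derivative(state.Ca, cur.ICa))
    vs_pre = state.Vs if synapse_mode == "self" else None
    dSi, dWi = synaptic_gate_derivatives(state.Si, state.Wi, vs_pre)
    out.extend([dSi, dWi])
    return np.array(out)


def _make_rhs(params: NeuronParameters, circuit: CircuitParameters | None,
              stim: FieldStimulus | None, synapse_mode: str) -> Callable:
    """Build a scalar-arithmetic RHS closure for the stiff solver."""
    p = params.p
    Cm = params.Cm
    gc = params.gc
    gL, gNa, gKDR = params.gL, params.gNa, params.gKDR
    gCa, gKAHP, gKC = params.gCa, params.gKAHP, params.gKC
    gNMDA, gAMPA = params.gNMDA, params.gAMPA
    VNa, VCa, VK, VL, Vsyn = params.VNa, params.VCa, params.VK, params.VL, params.Vsyn
    Is_over_p = params.Is / p
    Id_over_1p = params.Id / (1.0 - p)
    self_syn = synapse_mode == "self"

    if stim is not None:
        A = stim.A
        w = 2.0 * math.pi * stim.f / 1000.0  # rad/ms
    else:
        A = w = 0.0
    if circuit is not None:
        Rin, Rout = circuit.RDSin, circuit.RDSout
        denom = 2.0 * Rin + Rout
    else:
        Rin = Rout = denom = 0.0

    exp, expm1 = math.exp, math.expm1

    def rhs(t, y):
        Vs, Vd, h, n, s, c, q, Ca, Si, Wi = y.tolist()
        if not (math.isfinite(Vs) and math.isfinite(Vd)):
            raise SimulationError(
                f"non-finite membrane potential at t={t} ms: Vs={Vs}, Vd={Vd}")

        Ve = A * math.sin(w * t) if A != 0.0 else 0.0
        if denom != 0.0:
            VDSout = (Rout * (Vs - Vd) + Rin * Ve) / denom
        else:
            VDSout = 0.0

        # soma gating rates
        x = 13.1 - Vs
        u = x * 0.25
        am = 0.32 * (4.0 * (1.0 - 0.5 * u + u * u / 12.0) if -1e-9 < u < 1e-9
                     else x / expm1(u))
        x = Vs - 40.1
        u = x * 0.2
        bm = 0.28 * (5.0 * (1.0 - 0.5 * u + u * u / 12.0) if -1e-9 < u < 1e-9
                     else x / expm1(u))
        ah = 0.128 * exp((17.0 - Vs) / 18.0)
        bh = 4.0 / (1.0 + exp((40.0 - Vs) * 0.2))
        x = 35.1 - Vs
        u = x * 0.2
        an = 0.016 * (5.0 * (1.0 - 0.5 * u + u * u / 12.0) if -1e-9 < u < 1e-9
                      else x / expm1(u))
        bn = 0.25 * exp(0.5 - 0.025 * Vs)
        # dendrite gating rates
        a_s = 1.6 / (1.0 + exp(-0.072 * (Vd - 65.0)))
        x = Vd - 51.1
        u = x * 0.2
        b_s = 0.02 * (5.0 * (1.0 - 0.5 * u + u * u / 12.0) if -1e-9 < u < 1e-9
                      else x / expm1(u))
        if Vd <= 50.0:
            ac = exp((Vd - 10.0) / 11.0 - (Vd - 6.5) / 27.0) / 18.975
            bc = 2.0 * exp((6.5 - Vd) / 27.0) - ac
        else:
            ac = 2.0 * exp((6.5 - Vd) / 27.0)
            bc = 0.0
        aq = 0.00002 * Ca
        if aq > 0.01:
            aq = 0.01
        bq = 0.001

        m_inf = am / (am + bm)

        Isleak = gL * (Vs - VL)
        Idleak = gL * (Vd - VL)
        INa = gNa * m_inf * m_inf * h * (Vs - VNa)
        IKDR = gKDR * n * (Vs - VK)
        ICa = gCa * s * s * (Vd - VCa)
        chi_ca = Ca / 250.0
        if chi_ca > 1.0:
            chi_ca = 1.0
        IKC = gKC * c * chi_ca * (Vd - VK)
        IKAHP = gKAHP * q * (Vd - VK)
        INMDA = gNMDA * Si / (1.0 + 0.28 * exp(-0.062 * (Vd - 60.0))) * (Vd - Vsyn)
        IAMPA = gAMPA * Wi * (Vd - Vsyn)
        Isyn = INMDA + IAMPA
        IDSin = gc * (Vd + VDSout - Vs)

        dVs = (-Isleak - INa - IKDR + IDSin / p + Is_over_p) / Cm
        dVd = (-Idleak - ICa - IKAHP - IKC - Isyn - IDSin / (1.0 - p)
               + Id_over_1p) / Cm
        if self_syn:
            dSi = (1.0 if Vs >= 10.0 else 0.0) - Si / 150.0
            dWi = (1.0 if Vs >= 20.0 else 0.0) - Wi * 0.5
        else:
            dSi = -Si / 150.0
            dWi = -Wi * 0.5
        return [dVs, dVd,
                ah * (1.0 - h) - bh * h,
                an * (1.0 - n) - bn * n,
                a_s * (1.0 - s) - b_s * s,
                ac * (1.0 - c) - bc * c,
                aq * (1.0 - q) - bq * q,
                -0.13 * ICa - 0.075 * Ca,
                dSi, dWi]

    return rhs


def simulate(config: SimulationConfig, keep_gates: bool = False) -> Trace:
    """Integrate one configuration and sample it on the uniform grid.

    Deterministic: identical configs produce bitwise-identical traces.
    Set ``keep_gates`` to also return the gating/calcium/synaptic series
    in ``Trace.extras``.
    """
    y0 = (config.initial or initial_state(config.params)).as_array()
    rhs = _make_rhs(config.params, config.circuit, config.stimulus,
                    config.synapse_mode)
    n = int(round(config.t_end / config.sample_dt)) + 1
    t_eval = np.arange(n) * config.sample_dt
    sol = solve_ivp(rhs, (0.0, config.t_end), y0, method="BDF",
                    t_eval=t_eval, rtol=config.rel_tol, atol=config.abs_tol,
                    max_step=config.max_step)
    if not sol.success:
        raise SimulationError(f"stiff solver failed: {sol.message}")
    if not np.isfinite(sol.y).all():
        raise SimulationError("solver returned a non-finite trace")

    y = sol.y
    # gates may exit [0,1] only within interpolation error; larger excursions
    # indicate a genuine integration failure
    gates = y[2:7]
    if gates.min() < -_GATE_TOL or gates.max() > 1.0 + _GATE_TOL:
        raise SimulationError("gating variable left [0,1] beyond solver tolerance")
    np.clip(gates, 0.0, 1.0, out=gates)
    ca = y[7]
    if ca.min() < -_GATE_TOL:
        raise SimulationError("calcium went negative beyond solver tolerance")
    np.clip(ca, 0.0, None, out=ca)

    Vs, Vd = y[0], y[1]
    if config.stimulus is not None:
        Ve = field_voltage(config.stimulus, sol.t)
    else:
        Ve = np.zeros_like(sol.t)
    if config.circuit is not None:
        VDSout = vdsout_closed_form(config.circuit.RDSin, config.circuit.RDSout,
                                    Vs - Vd, Ve)
    else:
        VDSout = np.zeros_like(sol.t)

    extras = {}
    if keep_gates:
        extras = {name: y[i] for i, name in enumerate(STATE_ORDER) if i >= 2}
    return Trace(t=sol.t, Vs=Vs, Vd=Vd, VDSout=np.asarray(VDSout),
                 config=config, extras=extras)


# ---------------------------------------------------------------------------
# trace persistence: delimited text (.csv) or binary container (.npz)

def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace to CSV (header t_ms,Vs_mV,Vd_mV,VDSout_mV,...) or NPZ."""
    path = Path(path)
    cols = {"t_ms": trace.t, "Vs_mV": trace.Vs, "Vd_mV": trace.Vd,
            "VDSout_mV": trace.VDSout}
    for k, v in trace.extras.items():
        cols[k] = np.asarray(v)
    if path.suffix == ".npz":
        np.savez_compressed(path, **cols)
        return
    data = np.column_stack(list(cols.values()))
    np.savetxt(path, data, delimiter=",", header=",".join(cols), comments="",
               fmt="%.10g")


def read_trace(path: str | Path) -> Trace:
    """Read a trace written by :func:`write_trace`; lossless for NPZ."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            cols = {k: z[k] for k in z.files}
    else:
        with open(path) as fh:
            header = fh.readline().strip()
        if not header:
            raise ValueError(f"{path}: empty trace file")
        names = header.split(",")
        try:
            data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed trace record ({exc})") from exc
        if data.size == 0:
            raise ValueError(f"{path}: trace file has a header but no records")
        if data.shape[1] != len(names):
            raise ValueError(
                f"{path}: records have {data.shape[1]} fields, header names "
                f"{len(names)}")
        cols = {name: data[:, i] for i, name in enumerate(names)}
    required = ("t_ms", "Vs_mV", "Vd_mV", "VDSout_mV")
    for name in required:
        if name not in cols:
            raise ValueError(f"{path}: missing column {name}")
    extras = {k: v for k, v in cols.items() if k not in required}
    return Trace(t=cols["t_ms"], Vs=cols["Vs_mV"], Vd=cols["Vd_mV"],
                 VDSout=cols["VDSout_mV"], extras=extras)
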