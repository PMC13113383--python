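"""Ionic machinery of the two-compartment CA3 pyramidal cell.

The neuron is reduced to a spiking soma (fast Na+ and delayed-rectifier K+
currents) electrically coupled to a dendrite carrying the slow Ca2+ and
Ca-dependent K+ currents, in the Pinsky–Rinzel tradition.  All voltages
live in the model frame referenced to -60 mV, so rest sits near 0 mV; no
conversion to absolute millivolts happens anywhere in this module.

Units: voltages mV, time ms, conductances mS/cm^2, currents uA/cm^2,
capacitance uF/cm^2.  Calcium is in the model's dimensionless concentration
units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

__all__ = [
    "GATES",
    "NeuronParameters",
    "NeuronState",
    "CurrentSet",
    "rate_constants",
    "gate_steady_and_tau",
    "chi",
    "ionic_currents",
    "calcium_derivative",
    "synaptic_gate_derivatives",
]

#: Gating variables of the model.  ``m`` is instantaneous (replaced by its
#: steady state in the Na+ current) and therefore not part of the ODE state.
GATES = ("m", "h", "n", "s", "c", "q")


@dataclass(frozen=True)
class NeuronParameters:
    """Biophysical constants of the two-compartment cell.

    Defaults are the standard parameter set of the model: a 50/50 split of
    membrane area between soma and dendrite, 3 uF/cm^2 capacitance, and the
    canonical conductance densities.  ``Id`` = 0.7 uA/cm^2 is the sole
    tonic drive; with it the unstimulated cell fires repetitive bursts.
    """

    p: float = 0.5            # soma fraction of total membrane area
    Cm: float = 3.0           # uF/cm^2
    gc: float = 2.1           # soma-dendrite coupling conductance, mS/cm^2
    gL: float = 0.1
    gNa: float = 30.0
    gKDR: float = 15.0
    gCa: float = 10.0
    gKAHP: float = 0.8
    gKC: float = 15.0
    gNMDA: float = 0.03
    gAMPA: float = 0.0045
    VNa: float = 120.0        # reversal potentials, model frame (ref -60 mV)
    VCa: float = 140.0
    VK: float = -38.56
    VL: float = 0.0
    Vsyn: float = 60.0
    Is: float = 0.0           # somatic injected current, uA/cm^2
    Id: float = 0.7           # dendritic injected current, uA/cm^2
    area: float = 6e-6        # total membrane area, cm^2

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"soma area fraction p must lie in (0,1), got {self.p}")
        if self.Cm <= 0.0:
            raise ValueError(f"membrane capacitance must be positive, got {self.Cm}")
        if self.area <= 0.0:
            raise ValueError(f"membrane area must be positive, got {self.area}")
        for name in ("gc", "gL", "gNa", "gKDR", "gCa", "gKAHP", "gKC", "gNMDA", "gAMPA"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"conductance {name} must be non-negative")

    def with_overrides(self, **kwargs: float) -> "NeuronParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class NeuronState:
    """Full ODE state: compartment voltages, gates, calcium, synaptic weights."""

    Vs: float = 0.0
    Vd: float = 0.0
    h: float = 0.0
    n: float = 0.0
    s: float = 0.0
    c: float = 0.0
    q: float = 0.0
    Ca: float = 0.0
    Si: float = 0.0
    Wi: float = 0.0

    def as_array(self):
        import numpy as np

        return np.array(
            [self.Vs, self.Vd, self.h, self.n, self.s, self.c, self.q,
             self.Ca, self.Si, self.Wi], dtype=float)

    @classmethod
    def from_array(cls, y) -> "NeuronState":
        names = [f.name for f in fields(cls)]
        if len(y) != len(names):
            raise ValueError(f"state vector must have {len(names)} entries, got {len(y)}")
        return cls(**{k: float(v) for k, v in zip(names, y)})


@dataclass(frozen=True)
class CurrentSet:
    """All membrane currents (uA/cm^2) evaluated at one instant.

    ``Isyn`` is always the exact sum of the NMDA and AMPA components.
    ``IDSin`` is the soma->dendrite coupling current including the
    extracellular feedback voltage VDSout.
    """

    Isleak: float
    Idleak: float
    INa: float
    IKDR: float
    IKC: float
    ICa: float
    IKAHP: float
    INMDA: float
    IAMPA: float
    Isyn: float
    IDSin: float


def _vtrap(x: float, b: float) -> float:
    """Numerically stable x / (exp(x/b) - 1), with analytic limit b at x = 0."""
    u = x / b
    if abs(u) < 1e-9:
        # second-order expansion of u/expm1(u); exact value b at u=0
        return b * (1.0 - 0.5 * u + u * u / 12.0)
    return x / math.expm1(u)


def rate_constants(gate: str, V: float, Ca: float = 0.0) -> tuple[float, float]:
    """Forward/backward kinetic rates (1/ms) for one gating variable.

    ``V`` is the somatic voltage for m, h, n and the dendritic voltage for
    s, c; gate q depends on calcium only.  The expressions are the original
    Pinsky–Rinzel rate functions in the -60 mV-referenced frame.  Those
    with removable singularities (alpha_m, beta_m, alpha_n, beta_s) are
    evaluated by their analytic limit at the singular point.
    """
    if not math.isfinite(V):
        raise ValueError(f"non-finite voltage {V!r} passed to rate_constants")
    if gate == "m":
        alpha = 0.32 * _vtrap(13.1 - V, 4.0)
        beta = 0.28 * _vtrap(V - 40.1, 5.0)
    elif gate == "h":
        alpha = 0.128 * math.exp((17.0 - V) / 18.0)
        beta = 4.0 / (1.0 + math.exp((40.0 - V) / 5.0))
    elif gate == "n":
        alpha = 0.016 * _vtrap(35.1 - V, 5.0)
        beta = 0.25 * math.exp(0.5 - 0.025 * V)
    elif gate == "s":
        alpha = 1.6 / (1.0 + math.exp(-0.072 * (V - 65.0)))
        beta = 0.02 * _vtrap(V - 51.1, 5.0)
    elif gate == "c":
        if V <= 50.0:
            alpha = math.exp((V - 10.0) / 11.0 - (V - 6.5) / 27.0) / 18.975
            beta = 2.0 * math.exp((6.5 - V) / 27.0) - alpha
        else:
            alpha = 2.0 * math.exp((6.5 - V) / 27.0)
            beta = 0.0
    elif gate == "q":
        if Ca < 0.0:
            raise ValueError(f"calcium concentration must be non-negative, got {Ca}")
        alpha = min(0.00002 * Ca, 0.01)
        beta = 0.001
    else:
        raise ValueError(f"unknown gating variable {gate!r}; expected one of {GATES}")
    return alpha, beta


def gate_steady_and_tau(gate: str, V: float, Ca: float = 0.0) -> tuple[float, float]:
    """Steady-state activation y_inf = a/(a+b) and time constant tau = 1/(a+b)."""
    alpha, beta = rate_constants(gate, V, Ca)
    denom = alpha + beta
    if denom <= 0.0:
        raise ValueError(
            f"degenerate kinetics for gate {gate!r} at V={V}: alpha+beta={denom}")
    return alpha / denom, 1.0 / denom


def chi(Ca: float) -> float:
    """Calcium saturation factor min(Ca/250, 1) gating the fast K(Ca) current."""
    if Ca < 0.0:
        raise ValueError(f"calcium concentration must be non-negative, got {Ca}")
    return min(Ca / 250.0, 1.0)


def ionic_currents(state: NeuronState, params: NeuronParameters,
                   VDSout: float = 0.0) -> CurrentSet:
    """Evaluate every membrane current at one instant.

    Sodium activation is instantaneous: m is replaced by m_inf(Vs).  The
    coupling current includes the extracellular feedback term,
    IDSin = gc * (Vd + VDSout - Vs); pass VDSout = 0 for the isolated cell.
    """
    pr = params
    Vs, Vd = state.Vs, state.Vd
    m_inf, _ = gate_steady_and_tau("m", Vs)

    Isleak = pr.gL * (Vs - pr.VL)
    Idleak = pr.gL * (Vd - pr.VL)
    INa = pr.gNa * m_inf * m_inf * state.h * (Vs - pr.VNa)
    IKDR = pr.gKDR * state.n * (Vs - pr.VK)
    ICa = pr.gCa * state.s * state.s * (Vd - pr.VCa)
    IKC = pr.gKC * state.c * chi(state.Ca) * (Vd - pr.VK)
    IKAHP = pr.gKAHP * state.q * (Vd - pr.VK)
    INMDA = (pr.gNMDA * state.Si
             / (1.0 + 0.28 * math.exp(-0.062 * (Vd - 60.0)))
             * (Vd - pr.Vsyn))
    IAMPA = pr.gAMPA * state.Wi * (Vd - pr.Vsyn)
    IDSin = pr.gc * (Vd + VDSout - Vs)
    return CurrentSet(
        Isleak=Isleak, Idleak=Idleak, INa=INa, IKDR=IKDR, IKC=IKC, ICa=ICa,
        IKAHP=IKAHP, INMDA=INMDA, IAMPA=IAMPA, Isyn=INMDA + IAMPA, IDSin=IDSin)


def calcium_derivative(Ca: float, ICa: float) -> float:
    """dCa/dt = -0.13*ICa - 0.075*Ca (ICa is negative for inward flux)."""
    return -0.13 * ICa - 0.075 * Ca


def synaptic_gate_derivatives(Si: float, Wi: float,
                              Vs_pre: float | None) -> tuple[float, float]:
    """First-order kinetics of the NMDA (Si) and AMPA (Wi) synaptic weights.

    The presynaptic drive is a Heaviside step on the presynaptic somatic
    voltage: Si charges while Vs_pre >= 10 mV and decays with a 150 ms time
    constant; Wi charges while Vs_pre >= 20 mV and decays with 2 ms.  Pass
    ``Vs_pre=None`` for a synapse with no presynaptic partner (pure decay).
    """
    if Vs_pre is None:
        hs = hw = 0.0
    else:
        hs = 1.0 if Vs_pre >= 10.0 else 0.0
        hw = 1.0 if Vs_pre >= 20.0 else 0.0
    return hs - Si / 150.0, hw - Wi / 2.0
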