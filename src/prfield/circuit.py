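"""Extracellular equivalent circuit coupling an applied AC field to the cell.

The extracellular space between the dendrite and soma nodes is a purely
resistive two-loop network (the medium's capacitance is negligible at the
quasi-static frequencies of interest): the intracellular dendro-somatic
resistance ``RDSin``, its extracellular counterpart ``RDSout``, and two
terminal resistors ``RTD`` (field terminal to dendrite) and ``RSG`` (soma
to ground), each fixed at RDSout/2.  A sinusoidal voltage source
Ve(t) = A sin(2 pi f t) drives the outer loop; solving Kirchhoff's current
law for the two loop currents yields the instantaneous voltage ``VDSout``
across RDSout, which feeds back into the inter-compartment coupling
current of the membrane equations.

Physiologically, RDSout tracks extracellular potassium: raising [K+]o
shrinks the extracellular volume fraction and so raises the effective
extracellular resistance.  That dependence enters through the ratio
r = RDSout/RDSin = 0.1 + ([K+]o - 3.5 mM) * 0.01.

Units: resistances MOhm, voltages mV, loop currents nA (mV / MOhm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircuitParameters",
    "FieldStimulus",
    "resistance_ratio_from_potassium",
    "intracellular_resistance",
    "field_voltage",
    "extracellular_voltage",
    "vdsout_closed_form",
]


def resistance_ratio_from_potassium(Ko: float) -> float:
    """Extracellular/intracellular resistance ratio from [K+]o (mM).

    r = 0.1 + (Ko - 3.5) * 0.01; the physiological span 3.5-8.5 mM maps to
    r in [0.1, 0.15].
    """
    if Ko < 0.0:
        raise ValueError(f"potassium concentration must be non-negative, got {Ko}")
    r = 0.1 + (Ko - 3.5) * 0.01
    if r <= 0.0:
        raise ValueError(
            f"[K+]o = {Ko} mM yields non-physical resistance ratio r = {r}")
    return r


def intracellular_resistance(gc: float, area: float) -> float:
    """Dendro-somatic intracellular resistance RDSin = 1/(gc*area) in MOhm.

    ``gc`` in mS/cm^2 and ``area`` in cm^2 give a conductance in mS, whose
    reciprocal is kOhm; the result is reported in MOhm.  The default cell
    (gc = 2.1 mS/cm^2, area = 6e-6 cm^2) gives about 79.4 MOhm.
    """
    if gc <= 0.0 or area <= 0.0:
        raise ValueError(f"gc and area must be positive, got gc={gc}, area={area}")
    return 1e-3 / (gc * area)


@dataclass(frozen=True)
class CircuitParameters:
    """Resistances of the two-loop extracellular network (MOhm).

    The terminal resistors are tied to the extracellular dendrite-soma
    resistance: RTD = RSG = RDSout/2, so the network is fully determined by
    (RDSin, RDSout).  Construct via :meth:`from_rout` when an experiment
    prescribes RDSout directly, or :meth:`from_potassium` /
    :meth:`from_ratio` to derive it from the extracellular milieu.
    """

    RDSin: float
    RDSout: float

    def __post_init__(self) -> None:
        if self.RDSin <= 0.0 or self.RDSout <= 0.0:
            raise ValueError(
                f"resistances must be positive, got RDSin={self.RDSin}, "
                f"RDSout={self.RDSout}")

    @property
    def r(self) -> float:
        """Extracellular/intracellular resistance ratio RDSout/RDSin."""
        return self.RDSout / self.RDSin

    @property
    def RTD(self) -> float:
        """Field-terminal-to-dendrite resistance, RDSout/2."""
        return 0.5 * self.RDSout

    @property
    def RSG(self) -> float:
        """Soma-to-ground resistance, RDSout/2."""
        return 0.5 * self.RDSout

    @classmethod
    def from_rout(cls, RDSout: float, RDSin: float | None = None,
                  gc: float = 2.1, area: float = 6e-6) -> "CircuitParameters":
        """Build from a directly specified RDSout (MOhm)."""
        if RDSin is None:
            RDSin = intracellular_resistance(gc, area)
        return cls(RDSin=RDSin, RDSout=RDSout)

    @classmethod
    def from_ratio(cls, r: float, RDSin: float | None = None,
                   gc: float = 2.1, area: float = 6e-6) -> "CircuitParameters":
        """Build from the resistance ratio r = RDSout/RDSin."""
        if r <= 0.0:
            raise ValueError(f"resistance ratio must be positive, got {r}")
        if RDSin is None:
            RDSin = intracellular_resistance(gc, area)
        return cls(RDSin=RDSin, RDSout=r * RDSin)

    @classmethod
    def from_potassium(cls, Ko: float, RDSin: float | None = None,
                       gc: float = 2.1, area: float = 6e-6) -> "CircuitParameters":
        """Build from extracellular potassium concentration (mM)."""
        return cls.from_ratio(resistance_ratio_from_potassium(Ko), RDSin, gc, area)


@dataclass(frozen=True)
class FieldStimulus:
    """Sinusoidal extracellular voltage source Ve(t) = A sin(2 pi f t).

    ``A`` is the source amplitude in mV and ``f`` the field frequency in Hz.
    For a uniform field of intensity E0 (mV/mm) across an effective
    soma-dendrite distance d (mm), A = E0 * d; supply (E0, d) to record
    that provenance, in which case A must equal their product.
    """

    A: float
    f: float
    E0: float | None = None
    d: float | None = None

    def __post_init__(self) -> None:
        if self.A < 0.0:
            raise ValueError(f"field amplitude must be non-negative, got {self.A}")
        if self.f <= 0.0:
            raise ValueError(f"field frequency must be positive, got {self.f}")
        if (self.E0 is None) != (self.d is None):
            raise ValueError("E0 and d must be given together")
        if self.E0 is not None and not math.isclose(self.A, self.E0 * self.d):
            raise ValueError(
                f"amplitude {self.A} mV inconsistent with E0*d = {self.E0 * self.d}")

    @classmethod
    def from_field(cls, E0: float, d: float, f: float) -> "FieldStimulus":
        """Build from field intensity E0 (mV/mm) and electrode-frame distance d (mm)."""
        return cls(A=E0 * d, f=f, E0=E0, d=d)


def field_voltage(stim: FieldStimulus, t):
    """Source voltage Ve (mV) at time t (ms); accepts scalars or arrays."""
    return stim.A * np.sin(2.0 * np.pi * stim.f * np.asarray(t) / 1000.0)


def extracellular_voltage(circuit: CircuitParameters, Vs: float, Vd: float,
                          Ve: float) -> tuple[float, float, float]:
    """Solve the two-loop Kirchhoff system for (i1, i2, VDSout).

    Loop equations (resistances MOhm, voltages mV, currents nA):

        i1*(RDSin + RDSout) + i2*RDSout             = Vs - Vd
        i1*RDSout + i2*(RTD + RSG + RDSout)         = Ve

    and VDSout = (i1 + i2)*RDSout.  With RTD = RSG = RDSout/2 this equals
    the closed form of :func:`vdsout_closed_form`, which the simulator uses.
    """
    Rin, Rout = circuit.RDSin, circuit.RDSout
    M = np.array([[Rin + Rout, Rout],
                  [Rout, circuit.RTD + circuit.RSG + Rout]])
    try:
        i1, i2 = np.linalg.solve(M, np.array([Vs - Vd, Ve]))
    except np.linalg.LinAlgError as exc:  # unreachable for positive resistances
        raise ValueError(f"singular extracellular network: {exc}") from exc
    return float(i1), float(i2), float((i1 + i2) * Rout)


def vdsout_closed_form(RDSin: float, RDSout: float, dV, Ve):
    """Closed-form VDSout = (RDSout*(Vs-Vd) + RDSin*Ve) / (2*RDSin + RDSout).

    Valid for the standard terminal choice RTD = RSG = RDSout/2; ``dV`` is
    Vs - Vd.  Vectorises over dV and Ve.
    """
    return (RDSout * dV + RDSin * Ve) / (2.0 * RDSin + RDSout)
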