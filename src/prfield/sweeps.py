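"""Parameter-sweep engine and summary statistics.

A sweep runs one simulation + spike analysis per grid cell over one or two
swept parameters (field amplitude or frequency, extracellular resistance
Rout, extracellular potassium Ko, potassium reversal VK, or dendritic drive
Id), producing gridded firing-rate and phase-locking-ratio maps.  Cells are
content-addressed by a hash of the fully resolved configuration, so a sweep
re-run against the same cache directory performs no new simulations.
Per-cell solver failures are recorded as missing values and never abort the
sweep.
"""

from __future__ import annotations

import datetime
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import CircuitParameters, FieldStimulus
from .simulate import SimulationConfig, SimulationError, simulate
from .spikes import DetectionConfig, detect_spikes, mean_firing_rate

__all__ = [
    "SWEEPABLE",
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "mean_rate_over_axis",
    "locking_jump_threshold",
    "export_surface",
    "load_surface",
]

log = logging.getLogger(__name__)

#: Parameters a sweep axis may range over.
SWEEPABLE = ("amplitude", "frequency", "Rout", "VK", "Ko", "Id")


@dataclass(frozen=True)
class SweepSpec:
    """One- or two-axis sweep: axis = (parameter name, grid values)."""

    axes: tuple[tuple[str, tuple[float, ...]], ...]
    base: SimulationConfig = field(default_factory=SimulationConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    cache_dir: Path | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.axes) <= 2:
            raise ValueError("a sweep has one or two axes")
        names = [a[0] for a in self.axes]
        if len(set(names)) != len(names):
            raise ValueError(f"axis parameters must be distinct, got {names}")
        norm = []
        for name, values in self.axes:
            if name not in SWEEPABLE:
                raise ValueError(f"unknown sweep parameter {name!r}; "
                                 f"expected one of {SWEEPABLE}")
            vals = tuple(float(v) for v in values)
            if not all(np.isfinite(vals)):
                raise ValueError(f"axis {name!r} has non-finite values")
            if list(vals) != sorted(vals):
                raise ValueError(f"axis {name!r} values must be sorted")
            norm.append((name, vals))
        object.__setattr__(self, "axes", tuple(norm))
        if self.cache_dir is not None:
            object.__setattr__(self, "cache_dir", Path(self.cache_dir))


def apply_parameter(config: SimulationConfig, name: str,
                    value: float) -> SimulationConfig:
    """Return a copy of ``config`` with one sweepable parameter overridden."""
    if name == "amplitude":
        if config.stimulus is None:
            raise ValueError("cannot set amplitude: base config has no stimulus")
        return replace(config, stimulus=replace(config.stimulus, A=value))
    if name == "frequency":
        if config.stimulus is None:
            raise ValueError("cannot set frequency: base config has no stimulus")
        return replace(config, stimulus=replace(config.stimulus, f=value))
    if name == "Rout":
        RDSin = (config.circuit.RDSin if config.circuit is not None
                 else None)
        circ = CircuitParameters.from_rout(value, RDSin=RDSin,
                                           gc=config.params.gc,
                                           area=config.params.area)
        return replace(config, circuit=circ)
    if name == "Ko":
        RDSin = (config.circuit.RDSin if config.circuit is not None
                 else None)
        circ = CircuitParameters.from_potassium(value, RDSin=RDSin,
                                                gc=config.params.gc,
                                                area=config.params.area)
        return replace(config, circuit=circ)
    if name == "VK":
        return replace(config, params=config.params.with_overrides(VK=value))
    if name == "Id":
        return replace(config, params=config.params.with_overrides(Id=value))
    raise ValueError(f"unknown sweep parameter {name!r}")


@dataclass
class SweepResult:
    """Gridded sweep output.

    Matrices have one dimension per axis, in axis order; missing cells
    (solver failures) are NaN.  ``locking`` is rate/frequency wherever a
    field frequency is defined for the cell, else NaN.
    """

    axis_names: tuple[str, ...]
    axis_values: tuple[np.ndarray, ...]
    rate: np.ndarray
    locking: np.ndarray
    counts: np.ndarray
    failures: list = field(default_factory=list)
    base_hash: str = ""
    created: str = ""
    n_simulated: int = 0

    def __post_init__(self) -> None:
        shape = tuple(len(v) for v in self.axis_values)
        for name in ("rate", "locking", "counts"):
            m = getattr(self, name)
            if m.shape != shape:
                raise ValueError(f"matrix {name} shape {m.shape} != grid {shape}")

    def axis_index(self, name: str) -> int:
        try:
            return self.axis_names.index(name)
        except ValueError:
            raise ValueError(f"no axis named {name!r}; have {self.axis_names}")


def _cell_cache_path(cache_dir: Path, key: str) -> Path:
    return cache_dir / f"{key}.json"


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run (or resume) a sweep: one simulate + analyze per grid cell."""
    shape = tuple(len(a[1]) for a in spec.axes)
    rate = np.full(shape, np.nan)
    locking = np.full(shape, np.nan)
    counts = np.full(shape, np.nan)
    failures: list = []
    n_sim = 0
    if spec.cache_dir is not None:
        spec.cache_dir.mkdir(parents=True, exist_ok=True)

    for idx in np.ndindex(shape):
        config = spec.base
        for (name, values), i in zip(spec.axes, idx):
            config = apply_parameter(config, name, values[i])
        key = config.content_hash()
        cached = None
        if spec.cache_dir is not None:
            p = _cell_cache_path(spec.cache_dir, key)
            if p.exists():
                cached = json.loads(p.read_text())
        if cached is None:
            try:
                trace = simulate(config)
                train = detect_spikes(trace, spec.detection)
                r = mean_firing_rate(train)
                n = train.n
            except SimulationError as exc:
                log.warning("cell %s (%s) failed: %s", idx, key[:12], exc)
                failures.append({"index": list(idx), "config_hash": key,
                                 "error": str(exc)})
                continue
            n_sim += 1
            cached = {"rate_hz": r, "n_spikes": n}
            if spec.cache_dir is not None:
                _cell_cache_path(spec.cache_dir, key).write_text(
                    json.dumps(cached))
        rate[idx] = cached["rate_hz"]
        counts[idx] = cached["n_spikes"]
        f = config.stimulus.f if config.stimulus is not None else None
        if f is not None and f > 0:
            locking[idx] = rate[idx] / f

    return SweepResult(
        axis_names=tuple(a[0] for a in spec.axes),
        axis_values=tuple(np.array(a[1]) for a in spec.axes),
        rate=rate, locking=locking, counts=counts, failures=failures,
        base_hash=spec.base.content_hash(),
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        n_simulated=n_sim)


def mean_rate_over_axis(result: SweepResult, axis: str) -> np.ndarray:
    """Mean firing rate along the named axis, missing cells excluded.

    For a (VK x frequency) sweep, averaging over ``frequency`` yields one
    mean rate per VK value.
    """
    ax = result.axis_index(axis)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(result.rate, axis=ax)
    if np.isnan(means).any():
        warnings.warn("some rows have no valid cells; their mean is NaN",
                      stacklevel=2)
    return means


def locking_jump_threshold(result: SweepResult, level: float = 2.0):
    """Smallest swept amplitude whose locking ratio exceeds ``level``.

    Returns a scalar for a single-axis amplitude sweep, or an array with
    one threshold per value of the other axis for two-axis sweeps; NaN
    where the level is never exceeded.
    """
    ax = result.axis_index("amplitude")
    amps = result.axis_values[ax]
    ratios = np.moveaxis(result.locking, ax, 0)   # amplitude first
    flat = ratios.reshape(len(amps), -1)
    out = np.full(flat.shape[1], np.nan)
    for j in range(flat.shape[1]):
        above = np.where(flat[:, j] > level)[0]
        if above.size:
            out[j] = amps[above[0]]
    if result.rate.ndim == 1:
        return float(out[0])
    return out.reshape([n for i, n in enumerate(result.rate.shape) if i != ax])


# ---------------------------------------------------------------------------
# surface persistence: long-format CSV + JSON manifest

_SURFACE_COLUMNS = ("rate_hz", "locking_ratio", "n_spikes")


def _manifest_path(path: Path) -> Path:
    return path.with_name(path.name + ".manifest.json")


def export_surface(result: SweepResult, path: str | Path) -> None:
    """Write a long-format surface CSV plus a run manifest alongside it."""
    path = Path(path)
    idx_grids = np.meshgrid(*result.axis_values, indexing="ij") \
        if result.axis_values else []
    cols: dict = {}
    for name, grid in zip(result.axis_names, idx_grids):
        cols[name] = grid.ravel()
    cols["rate_hz"] = result.rate.ravel()
    cols["locking_ratio"] = result.locking.ravel()
    cols["n_spikes"] = result.counts.ravel()
    pd.DataFrame(cols).to_csv(path, index=False)
    manifest = {
        "axis_names": list(result.axis_names),
        "axis_values": [list(map(float, v)) for v in result.axis_values],
        "base_hash": result.base_hash,
        "created": result.created,
        "n_cells": int(result.rate.size),
        "failures": result.failures,
    }
    _manifest_path(path).write_text(json.dumps(manifest, indent=1))


def load_surface(path: str | Path) -> SweepResult:
    """Round-trip a surface written by :func:`export_surface`."""
    path = Path(path)
    mpath = _manifest_path(path)
    if not mpath.exists():
        raise FileNotFoundError(f"missing run manifest {mpath}")
    manifest = json.loads(mpath.read_text())
    df = pd.read_csv(path)
    names = tuple(manifest["axis_names"])
    for col in names + _SURFACE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    values = tuple(np.array(v, dtype=float) for v in manifest["axis_values"])
    shape = tuple(len(v) for v in values)
    n = int(np.prod(shape)) if shape else 0
    if len(df) != n:
        raise ValueError(f"{path}: {len(df)} rows, grid implies {n}")
    return SweepResult(
        axis_names=names, axis_values=values,
        rate=df["rate_hz"].to_numpy().reshape(shape),
        locking=df["locking_ratio"].to_numpy().reshape(shape),
        counts=df["n_spikes"].to_numpy().reshape(shape),
        failures=manifest.get("failures", []),
        base_hash=manifest.get("base_hash", ""),
        created=manifest.get("created", ""))


# ---------------------------------------------------------------------------
# configuration files (structured key: value text, used by the CLI)

def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a nested plain dict (YAML-friendly).

    Sections: ``params`` (field overrides of the neuron parameter set),
    ``circuit`` ({Rout: MOhm} or {Ko: mM} or {r: ratio}, or null),
    ``stimulus`` ({amplitude: mV, frequency: Hz}, or null), ``solver``
    (t_end, sample_dt, burn_in, rel_tol, abs_tol, max_step), and
    ``synapse_mode``.
    """
    from .model import NeuronParameters

    d = dict(d or {})
    params = NeuronParameters(**(d.get("params") or {}))
    circ_d = d.get("circuit")
    circuit = None
    if circ_d:
        if "Rout" in circ_d:
            circuit = CircuitParameters.from_rout(
                circ_d["Rout"], RDSin=circ_d.get("RDSin"),
                gc=params.gc, area=params.area)
        elif "Ko" in circ_d:
            circuit = CircuitParameters.from_potassium(
                circ_d["Ko"], RDSin=circ_d.get("RDSin"),
                gc=params.gc, area=params.area)
        elif "r" in circ_d:
            circuit = CircuitParameters.from_ratio(
                circ_d["r"], RDSin=circ_d.get("RDSin"),
                gc=params.gc, area=params.area)
        else:
            raise ValueError("circuit section needs one of Rout, Ko, r")
    stim_d = d.get("stimulus")
    stimulus = None
    if stim_d:
        stimulus = FieldStimulus(A=float(stim_d["amplitude"]),
                                 f=float(stim_d["frequency"]))
    solver = dict(d.get("solver") or {})
    return SimulationConfig(params=params, circuit=circuit, stimulus=stimulus,
                            synapse_mode=d.get("synapse_mode", "self"),
                            **solver)


def sweep_from_dict(d: dict, cache_dir: str | Path | None = None) -> SweepSpec:
    """Build a SweepSpec from a plain dict with an ``axes`` list."""
    axes = tuple((a["parameter"], tuple(a["values"])) for a in d["axes"])
    base = config_from_dict({k: v for k, v in d.items() if k != "axes"})
    det = DetectionConfig(**(d.get("detection") or {}))
    return SweepSpec(axes=axes, base=base, detection=det,
                     cache_dir=Path(cache_dir) if cache_dir else None)
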