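"""Spike detection, firing-rate and phase-locking statistics.

Action potentials are detected on the somatic voltage as local maxima
whose height and prominence are fixed fractions of the analysis window's
voltage range (so detection is insensitive to the model-frame offset),
with a 3 ms minimum inter-peak interval so a single spike is never counted
twice.  The mean firing rate is the spike count divided by the window
length; the phase-locking ratio is that rate divided by the applied field
frequency (ratio ~ 1 means 1:1 entrainment).

A synthetic-trace generator with known ground-truth spike times lets the
analysis layer be tested independently of the biophysical simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .simulate import Trace

__all__ = [
    "DetectionConfig",
    "SpikeTrain",
    "detect_spikes",
    "mean_firing_rate",
    "phase_locking_ratio",
    "make_synthetic_trace",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Adaptive peak-detection settings.

    ``threshold_fraction`` and ``prominence_fraction`` are fractions of the
    window's voltage range (max - min); ``min_interval_ms`` is the minimum
    spacing between accepted peaks (the higher peak of a closer pair wins).
    """

    min_interval_ms: float = 3.0
    prominence_fraction: float = 0.25
    threshold_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_interval_ms <= 0.0:
            raise ValueError("min_interval_ms must be positive")
        for name in ("prominence_fraction", "threshold_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {v}")


@dataclass
class SpikeTrain:
    """Strictly increasing spike times (ms) within a half-open window [start, end)."""

    times: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        start, end = self.window
        if end <= start:
            raise ValueError(f"empty or inverted window {self.window}")
        if self.times.size:
            if not (np.diff(self.times) > 0).all():
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < start or self.times[-1] >= end:
                raise ValueError("spike times must lie within the window")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def duration_ms(self) -> float:
        return self.window[1] - self.window[0]


def detect_spikes(trace: Trace, cfg: DetectionConfig = DetectionConfig(),
                  window: tuple[float, float] | None = None) -> SpikeTrain:
    """Detect somatic spikes within ``window`` (defaults to [burn_in, t_end)).

    A flat signal yields an empty train; an empty window is an error.
    The returned train always satisfies the minimum-interval constraint.
    """
    if window is None:
        if trace.config is not None:
            window = (trace.config.burn_in, trace.config.t_end)
        else:
            window = (float(trace.t[0]), float(trace.t[-1]) + trace.dt)
    start, end = window
    mask = (trace.t >= start) & (trace.t < end)
    if not mask.any():
        raise ValueError(f"window {window} contains no samples "
                         f"(trace spans {trace.span})")
    t = trace.t[mask]
    v = trace.Vs[mask]
    vrange = float(v.max() - v.min())
    if vrange == 0.0:
        return SpikeTrain(times=np.empty(0), window=window)
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    distance = max(1, int(math.ceil(cfg.min_interval_ms / dt)))
    idx, _ = find_peaks(
        v,
        height=float(v.min()) + cfg.threshold_fraction * vrange,
        prominence=cfg.prominence_fraction * vrange,
        distance=distance)
    times = t[idx]
    if times.size > 1:
        assert (np.diff(times) >= cfg.min_interval_ms - dt).all()
    return SpikeTrain(times=times, window=window)


def mean_firing_rate(train: SpikeTrain) -> float:
    """Spike count divided by window length, in Hz."""
    return train.n / train.duration_ms * 1000.0


def phase_locking_ratio(firing_rate: float, field_frequency: float) -> float:
    """Firing rate / field frequency; ~1 marks the 1:1 entrainment regime."""
    if field_frequency <= 0.0:
        raise ValueError(f"field frequency must be positive, got {field_frequency}")
    return firing_rate / field_frequency


def make_synthetic_trace(spike_times, baseline: float = 0.0,
                         amplitude: float = 100.0, width_ms: float = 2.0,
                         noise_amplitude: float = 0.0, seed: int = 0,
                         t_end: float | None = None,
                         dt: float = 0.05) -> Trace:
    """Build a trace of stereotyped spike templates on a flat baseline.

    Each spike is a Gaussian bump of the given amplitude and ~``width_ms``
    footprint centred on its ground-truth time; seeded white noise of the
    given amplitude (standard deviation, mV) is added on top.  The true
    spike times are stored in ``trace.meta['true_spike_times']``.  Spike
    times closer than ``width_ms`` are rejected: overlapping templates make
    the ground truth ambiguous.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    if spike_times.size > 1 and (np.diff(spike_times) < width_ms).any():
        raise ValueError(
            f"spike times closer than the template width {width_ms} ms "
            "give ambiguous ground truth")
    if t_end is None:
        t_end = (float(spike_times[-1]) + 10.0 * width_ms) if spike_times.size else 100.0
    t = np.arange(0.0, t_end + dt / 2, dt)
    v = np.full_like(t, baseline)
    sigma = width_ms / 6.0  # +-3 sigma footprint ~ width_ms
    for ts in spike_times:
        v += amplitude * np.exp(-0.5 * ((t - ts) / sigma) ** 2)
    if noise_amplitude > 0.0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_amplitude, size=t.shape)
    return Trace(t=t, Vs=v, Vd=np.full_like(t, baseline),
                 VDSout=np.zeros_like(t),
                 meta={"true_spike_times": spike_times, "seed": seed})
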