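"""Synthetic nanopore traces with known ground truth.

The generator composes the physical ingredients of a resistive-pulse
measurement in acquisition order: an open-pore baseline, ideal
rectangular blockade pulses (the physical translocation is treated as
instantaneous entry/exit), optional RC charging of the pore capacitance,
the acquisition chain's low-pass filter, additive white Gaussian noise,
and optional decimation to the recorded sampling rate.  Every pulse's
true onset, width, depth and excluded current are returned alongside the
trace so recovery can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import Trace
from .filters import FilterSpec, apply_filter

__all__ = [
    "Pulse",
    "SimConfig",
    "ideal_pulse_train",
    "synthesize",
    "required_cutoff",
]


def required_cutoff(width: float, level: float = 0.99) -> float:
    """Lowest Gaussian -3 dB cutoff at which an ideal pulse keeps its height.

    A rectangle of width ``w`` through a Gaussian filter of cutoff ``fc``
    peaks at ``erf(pi * w * fc / sqrt(2 ln 2))`` of its true depth; the
    cutoff at which the peak reaches ``level`` is therefore

        fc* = sqrt(2 ln 2) * erfinv(level) / (pi * w).

    This is the simulator-side ground truth for the per-event required
    sampling frequency: filters below ``fc*`` dilate the pulse, filters
    above preserve its amplitude.
    """
    from scipy.special import erfinv

    if width <= 0:
        raise ValueError("width must be positive")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    return float(np.sqrt(2.0 * np.log(2.0)) * erfinv(level) / (np.pi * width))


@dataclass(frozen=True)
class Pulse:
    """One rectangular blockade: onset (s), width (s), depth (pA, positive)."""

    onset: float
    width: float
    depth: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("pulse width must be positive")


@dataclass
class SimConfig:
    """Full specification of a synthetic trace."""

    fs: float                      # virtual sampling frequency, Hz
    duration: float                # trace length, s
    i_open: float = 100.0          # open-pore current, pA
    noise_sd: float = 0.0          # white Gaussian noise SD, pA
    rc_tau: float = 0.0            # RC charging time constant, s (0 = off)
    acq_filter: FilterSpec | None = None
    pulses: list[Pulse] = field(default_factory=list)
    seed: int = 0
    decimate_to: float | None = None  # target fs after filtering, Hz

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.noise_sd < 0 or self.rc_tau < 0:
            raise ValueError("noise_sd and rc_tau must be >= 0")
        self.pulses = [p if isinstance(p, Pulse) else Pulse(*p) for p in self.pulses]
        for p in self.pulses:
            if p.onset < 0 or p.onset + p.width > self.duration:
                raise ValueError(f"pulse {p} outside [0, {self.duration}]")


def ideal_pulse_train(config: SimConfig) -> Trace:
    """Noiseless, unfiltered baseline-plus-rectangles trace.

    Pulses must not overlap.  Each pulse depresses the half-open sample
    interval [round(onset*fs), round((onset+width)*fs)).
    """
    n = int(round(config.fs * config.duration))
    x = np.full(n, float(config.i_open))
    prev_end = -np.inf
    for p in sorted(config.pulses, key=lambda p: p.onset):
        if p.onset < prev_end:
            raise ValueError("overlapping pulses are not supported")
        prev_end = p.onset + p.width
        i0 = int(round(p.onset * config.fs))
        i1 = int(round((p.onset + p.width) * config.fs))
        x[i0:i1] -= p.depth
    return Trace(x, config.fs)


def _rc_charge(x: np.ndarray, fs: float, tau: float) -> np.ndarray:
    """One-pole RC response (exact zero-order-hold discretization)."""
    a = np.exp(-1.0 / (fs * tau))
    from scipy.signal import lfilter

    y, _ = lfilter([1.0 - a], [1.0, -a], x, zi=[a * x[0]])
    return y


def synthesize(config: SimConfig) -> tuple[Trace, pd.DataFrame]:
    """Generate a trace and its ground-truth table.

    Pipeline: ideal pulses -> RC charging (if rc_tau > 0) -> acquisition
    filter -> additive Gaussian noise (seeded) -> decimation (plain
    subsampling, modelling the ADC).  The table lists per pulse the true
    onset, width, depth, dwell time and excluded current.
    """
    trace = ideal_pulse_train(config)
    if config.rc_tau > 0:
        trace = Trace(_rc_charge(trace.samples, trace.fs, config.rc_tau), trace.fs)
    trace = apply_filter(trace, config.acq_filter)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        trace = Trace(
            trace.samples + rng.normal(0.0, config.noise_sd, trace.samples.size),
            trace.fs,
            trace.t0,
        )
    if config.decimate_to is not None:
        if config.acq_filter is None:
            warnings.warn(
                "decimating an unfiltered trace aliases noise and fast edges",
                stacklevel=2,
            )
        step = int(round(config.fs / config.decimate_to))
        if step < 1:
            raise ValueError("decimate_to exceeds the simulation fs")
        trace = Trace(trace.samples[::step], config.fs / step, trace.t0)

    truth = pd.DataFrame(
        {
            "onset": [p.onset for p in config.pulses],
            "width": [p.width for p in config.pulses],
            "depth": [p.depth for p in config.pulses],
            "dwell_time": [p.width for p in config.pulses],
            "i_ex": [p.depth / config.i_open for p in config.pulses],
            "area": [p.width * p.depth for p in config.pulses],
        }
    )
    return trace, truth
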