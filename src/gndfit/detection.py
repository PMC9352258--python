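"""Trace container and threshold-based event localization.

Localization answers only "when does an event occur"; every amplitude
used downstream comes from the five-parameter fit, never from the
localizer.  The localizer is a robust threshold search: a rolling-median
baseline with a MAD noise estimate, windows opened at a ``k * sd``
excursion and closed when the signal re-enters one standard deviation of
the baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trace", "EventWindow", "estimate_baseline", "detect_events"]

_MAD_TO_SD = 1.4826  # consistency factor for Gaussian noise


@dataclass
class Trace:
    """Uniformly sampled single-channel current recording.

    samples : current in pA; fs : sampling frequency in Hz; t0 : start
    time in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace must be a 1-D array of at least 2 samples")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def slice(self, start: int, end: int) -> "Trace":
        """Half-open sample slice as a new Trace with adjusted t0."""
        return Trace(self.samples[start:end].copy(), self.fs, self.t0 + start / self.fs)


@dataclass(frozen=True)
class EventWindow:
    """Half-open sample interval [start, end) of a candidate blockade."""

    start: int
    end: int
    baseline_mean: float = 0.0
    baseline_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid window [{self.start}, {self.end})")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")

    @property
    def n(self) -> int:
        return self.end - self.start


def estimate_baseline(
    trace: Trace, window: int = 10_000
) -> tuple[float, float]:
    """Robust open-pore level and noise SD of a trace.

    The level is the median of a rolling median (window ``window``
    samples), which short blockades barely perturb; the noise SD is
    1.4826 x MAD of the residual around the rolling median.  Traces
    shorter than the window fall back to a global median with a warning.
    """
    x = trace.samples
    if x.size < window:
        warnings.warn(
            f"trace shorter than baseline window ({x.size} < {window}); "
            "using global median",
            stacklevel=2,
        )
        rolling = np.full_like(x, np.median(x))
    else:
        rolling = (
            pd.Series(x)
            .rolling(window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
    resid = x - rolling
    return float(np.median(rolling)), float(_MAD_TO_SD * np.median(np.abs(resid)))


def detect_events(
    trace: Trace,
    threshold_k: float = 5.0,
    merge_gap: int = 10,
    baseline_window: int = 10_000,
    direction: str = "down",
) -> list[EventWindow]:
    """Localize candidate blockades by robust threshold crossing.

    A window opens where the current crosses ``baseline -/+ k * sd`` in
    the blockade direction and closes when the signal re-enters within
    one SD of the baseline; windows separated by fewer than ``merge_gap``
    samples are merged.  Returns ordered, disjoint windows carrying the
    baseline statistics they were detected against.
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    mean, sd = estimate_baseline(trace, window=baseline_window)
    x = trace.samples if direction == "down" else -trace.samples
    m = mean if direction == "down" else -mean

    deep = x < m - threshold_k * sd
    if not deep.any() or sd == 0:
        return []
    away = x < m - sd  # outside the 1-sd re-entry band

    # contiguous runs of `away` that contain at least one `deep` sample
    edges = np.diff(away.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if away[0]:
        starts = np.r_[0, starts]
    if away[-1]:
        ends = np.r_[ends, x.size]

    windows: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if deep[s:e].any():
            if windows and s - windows[-1][1] < merge_gap:
                windows[-1] = (windows[-1][0], e)
            else:
                windows.append((s, e))
    return [
        EventWindow(s, e, baseline_mean=mean, baseline_sd=sd) for s, e in windows
    ]
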