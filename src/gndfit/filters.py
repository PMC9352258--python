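"""Acquisition-chain and preprocessing low-pass filters.

Two filters cover the two roles in a nanopore pipeline:

* a zero-phase digital Gaussian filter (preprocessing / characterization
  filtering, as applied in software after acquisition), and
* a causal 4-pole Bessel filter (the analog anti-alias filter of
  patch-clamp amplifiers), simulated as a continuous-time linear system
  on the trace's own time grid so that pulse dilation — area-preserving
  broadening with amplitude loss — is reproduced faithfully.

Cutoffs are -3 dB frequencies throughout, the patch-clamp convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .detection import Trace

__all__ = ["FilterSpec", "gaussian_lowpass", "bessel4_lowpass", "apply_filter"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter: kind in {"gaussian", "bessel4"}, cutoff at -3 dB (Hz)."""

    kind: str
    cutoff: float

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "bessel4"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if not self.cutoff > 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")

    def __str__(self) -> str:
        return f"{self.kind}:{self.cutoff:g}"

    @classmethod
    def parse(cls, text: str) -> "FilterSpec":
        """Parse 'kind:cutoff_hz', e.g. 'gaussian:5e3'."""
        kind, _, cut = text.partition(":")
        return cls(kind, float(cut))


def gaussian_lowpass(trace: Trace, cutoff: float) -> Trace:
    """Zero-phase Gaussian low-pass with -3 dB point at ``cutoff``.

    The kernel SD in time is ``sqrt(ln 2) / (2 pi cutoff)``, which places
    the half-power point of the Gaussian transfer function
    ``exp(-2 pi^2 sd_t^2 f^2)`` exactly at ``cutoff``.  DC gain is
    exactly 1; edges are handled by reflection.
    """
    if not cutoff < trace.fs / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below Nyquist ({trace.fs / 2} Hz)"
        )
    sd_samples = np.sqrt(np.log(2.0)) / (2.0 * np.pi * cutoff) * trace.fs
    y = ndimage.gaussian_filter1d(trace.samples, sd_samples, mode="reflect")
    return Trace(y, trace.fs, trace.t0)


def bessel4_lowpass(trace: Trace, cutoff: float, method: str = "lsim") -> Trace:
    """Causal 4th-order Bessel low-pass, -3 dB at ``cutoff``.

    method="lsim" simulates the analog transfer function on the trace's
    time grid (requires fs >= 20 x cutoff, the densely-sampled regime an
    analog filter model is valid in); method="digital" uses the bilinear
    transform for speed.  Phase delay is preserved, as in hardware.
    """
    if trace.fs < 20.0 * cutoff:
        raise ValueError(
            f"fs={trace.fs} Hz undersamples a {cutoff} Hz analog Bessel "
            "(need fs >= 20 x cutoff); use the Gaussian filter instead"
        )
    x = trace.samples
    # simulate relative to the first sample so a step-like DC offset does
    # not ring at the start
    x0 = x[0]
    if method == "lsim":
        b, a = signal.bessel(4, 2.0 * np.pi * cutoff, "low", analog=True, norm="mag")
        t = np.arange(x.size) / trace.fs
        _, y, _ = signal.lsim((b, a), x - x0, t)
    elif method == "digital":
        sos = signal.bessel(4, cutoff, "low", fs=trace.fs, output="sos", norm="mag")
        y = signal.sosfilt(sos, x - x0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return Trace(y + x0, trace.fs, trace.t0)


def apply_filter(trace: Trace, spec: FilterSpec | None) -> Trace:
    if spec is None:
        return trace
    if spec.kind == "gaussian":
        return gaussian_lowpass(trace, spec.cutoff)
    return bessel4_lowpass(trace, spec.cutoff)
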