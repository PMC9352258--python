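"""Bounded least-squares fitting of the five-parameter event model.

The fit runs on a padded segment around each detected window so the
open-pore level is constrained by genuine baseline on both sides.  The
scale and shape parameters are optimized in log space for conditioning;
the shape exponent is bounded to [1, beta_max] and fits pinned at a
bound are flagged.  Everything is deterministic: identical input and
configuration give a bit-identical result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .detection import EventWindow, Trace
from .gndf import BETA_MAX_DEFAULT, GNDFParams, GNDFShape, kernel

__all__ = ["FitConfig", "FitResult", "NoEventError", "initial_guess", "fit_event"]


class NoEventError(ValueError):
    """The window shows no excursion distinguishable from the noise floor."""


@dataclass(frozen=True)
class FitConfig:
    beta_max: float = BETA_MAX_DEFAULT
    max_iter: int = 500            # max residual evaluations per fit
    padding_factor: float = 5.0    # padding on each side, x window width
    noise_floor_k: float = 3.0     # |dI_B| below k*sd counts as non-event
    direction: str = "down"        # blockades decrease |current|


@dataclass(frozen=True)
class FitResult:
    params: GNDFParams
    rmse: float
    converged: bool
    n_iter: int
    at_bound: frozenset[str]
    window: EventWindow
    is_event: bool = True  # False: fitted depth below the noise floor

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


def _padded_segment(trace: Trace, window: EventWindow, config: FitConfig):
    pad = max(8, int(round(config.padding_factor * window.n)))
    s0 = max(0, window.start - pad)
    s1 = min(len(trace), window.end + pad)
    return s0, s1


def initial_guess(
    trace: Trace, window: EventWindow, config: FitConfig = FitConfig()
) -> GNDFParams:
    """Moment-style starting point from the raw segment.

    Open-pore level from the median of the padding samples, depth and
    localization from the extremum inside the window, scale from half the
    above-half-depth width, shape starting Gaussian (beta = 2).  Raises
    :class:`NoEventError` when the excursion does not clear the noise
    floor.
    """
    s0, s1 = _padded_segment(trace, window, config)
    x = trace.samples
    pad_samples = np.r_[x[s0 : window.start], x[window.end : s1]]
    i_open = float(np.median(pad_samples)) if pad_samples.size else float(np.median(x[s0:s1]))

    seg = x[window.start : window.end]
    idx = int(np.argmin(seg)) if config.direction == "down" else int(np.argmax(seg))
    di_b = float(seg[idx] - i_open)
    noise_floor = config.noise_floor_k * window.baseline_sd
    if abs(di_b) <= noise_floor:
        raise NoEventError(
            f"no event signature: depth {abs(di_b):.3g} pA within the noise "
            f"floor ({noise_floor:.3g} pA)"
        )
    mu = trace.t0 + (window.start + idx) / trace.fs

    half = i_open + di_b / 2.0
    deep = seg < half if config.direction == "down" else seg > half
    width_s = max(int(deep.sum()), 1) / trace.fs
    sigma = max(width_s / 2.0, 0.5 / trace.fs)
    return GNDFParams(i_open, di_b, mu, sigma, 2.0, beta_max=config.beta_max)


def fit_event(
    trace: Trace, window: EventWindow, config: FitConfig = FitConfig()
) -> FitResult:
    """Least-squares fit of the event model on the padded segment.

    Parameter vector (I_O, dI_B, mu, ln sigma, ln beta), trust-region
    reflective with bounds: mu inside the padded segment, beta in
    [1, beta_max], sigma between a tenth of a sample and the segment
    span.  Non-convergence yields ``converged=False``, not an exception;
    a fitted depth below the noise floor is flagged ``is_event=False``.
    """
    s0, s1 = _padded_segment(trace, window, config)
    if s1 - s0 < 8:
        raise ValueError(f"segment too short to fit ({s1 - s0} samples)")
    t = trace.t0 + np.arange(s0, s1) / trace.fs
    y = trace.samples[s0:s1]

    try:
        guess = initial_guess(trace, window, config)
    except NoEventError:
        # fit anyway (null-input contract): neutral sub-floor guess
        i_open = float(np.median(y))
        idx = int(np.argmin(y)) if config.direction == "down" else int(np.argmax(y))
        depth = float(y[idx] - i_open) or (-1e-12 if config.direction == "down" else 1e-12)
        guess = GNDFParams(
            i_open, depth, float(t[idx]), max(window.n, 2) / (2 * trace.fs), 2.0,
            beta_max=config.beta_max,
        )

    dt_s = 1.0 / trace.fs
    lo = np.array([-np.inf, -np.inf, t[0], np.log(0.1 * dt_s), 0.0])
    hi = np.array([np.inf, np.inf, t[-1], np.log(t[-1] - t[0] + dt_s), np.log(config.beta_max)])
    x0 = np.array(
        [
            guess.i_open,
            guess.di_b,
            np.clip(guess.mu, lo[2], hi[2]),
            np.clip(np.log(guess.sigma), lo[3], hi[3]),
            np.log(guess.beta),
        ]
    )

    def residual(theta: np.ndarray) -> np.ndarray:
        i_open, di_b, mu, ls, lb = theta
        shape = GNDFShape(mu, np.exp(ls), max(np.exp(lb), 1.0))
        return i_open + di_b * kernel(t, shape) - y

    res = least_squares(
        residual, x0, bounds=(lo, hi), method="trf", max_nfev=config.max_iter
    )
    i_open, di_b, mu, ls, lb = res.x
    params = GNDFParams(
        float(i_open), float(di_b), float(mu), float(np.exp(ls)),
        float(min(np.exp(lb), config.beta_max)), beta_max=config.beta_max,
    )

    tol = 1e-8
    names = ("i_open", "di_b", "mu", "log_sigma", "log_beta")
    at_bound = frozenset(
        n
        for n, v, l, h in zip(names, res.x, lo, hi)
        if (np.isfinite(l) and v - l < tol * max(1, abs(l)))
        or (np.isfinite(h) and h - v < tol * max(1, abs(h)))
    )
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    is_event = abs(params.di_b) > config.noise_floor_k * window.baseline_sd
    return FitResult(
        params=params,
        rmse=rmse,
        converged=bool(res.success and res.status > 0),
        n_iter=int(res.nfev),
        at_bound=at_bound,
        window=window,
        is_event=is_event,
    )
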