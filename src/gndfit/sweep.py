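"""Characterization pipeline and low-pass filter recommendation.

The pipeline follows the two-filter strategy of nanopore analysis:
events are *localized* once on a heavily filtered copy of the trace
(default 5 kHz Gaussian, where threshold detection is reliable) and
*characterized* — fitted and featurized — on a lightly filtered copy, so
that localization smoothing never biases the fitted amplitudes.

``recommend_filter`` sweeps characterization cutoffs and brackets the
usable range: below the events' own required sampling frequency the
median back-mapped dwell time is elongated and the median F_s,event
tracks the filter instead of the event; above it both stabilize, until
baseline noise starts eating into the fitted depth (under-filtering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import Trace, detect_events
from .features import P_OVERLAP_DEFAULT, P_THRESHOLD_DEFAULT, compute_features
from .filters import FilterSpec, gaussian_lowpass
from .fitting import FitConfig, fit_event
from .store import EventRecord

__all__ = ["PipelineConfig", "characterize_trace", "recommend_filter"]

LOCALIZATION_CUTOFF_DEFAULT = 5_000.0  # Hz


@dataclass
class PipelineConfig:
    localization_cutoff: float = LOCALIZATION_CUTOFF_DEFAULT
    threshold_k: float = 5.0
    merge_gap: int = 10
    baseline_window: int = 10_000
    direction: str = "down"
    p_threshold: float = P_THRESHOLD_DEFAULT
    overlap_p_max: float = P_OVERLAP_DEFAULT
    fs_mode: str = "cdf"
    fit: FitConfig = FitConfig()


def characterize_trace(
    trace: Trace,
    trace_id: str = "trace",
    characterization_filter: FilterSpec | None = None,
    config: PipelineConfig | None = None,
    windows=None,
) -> list[EventRecord]:
    """Detect (on a 5 kHz-filtered copy), fit and featurize all events.

    ``windows`` may be supplied to reuse one localization across several
    characterization filters.
    """
    config = config or PipelineConfig()
    if windows is None:
        loc = trace
        if config.localization_cutoff < trace.fs / 2:
            loc = gaussian_lowpass(trace, config.localization_cutoff)
        windows = detect_events(
            loc,
            threshold_k=config.threshold_k,
            merge_gap=config.merge_gap,
            baseline_window=config.baseline_window,
            direction=config.direction,
        )
    char = trace
    if characterization_filter is not None:
        from .filters import apply_filter

        char = apply_filter(trace, characterization_filter)

    records = []
    for w in windows:
        rec = EventRecord(
            trace_id=trace_id,
            t_start=trace.t0 + w.start / trace.fs,
            t_end=trace.t0 + w.end / trace.fs,
            baseline_mean=w.baseline_mean,
            baseline_sd=w.baseline_sd,
            localization_filter=FilterSpec("gaussian", config.localization_cutoff),
            characterization_filter=characterization_filter,
        )
        try:
            fit = fit_event(char, w, config.fit)
        except ValueError:
            records.append(rec)
            continue
        rec.fit = fit
        if fit.converged:
            rec.features = compute_features(
                fit.params,
                w,
                fs=trace.fs,
                t0=trace.t0,
                p=config.p_threshold,
                overlap_p_max=config.overlap_p_max,
                fs_mode=config.fs_mode,
                beta_max=config.fit.beta_max,
            )
        records.append(rec)
    return records


def _summary_row(records: list[EventRecord]) -> dict:
    feats = [r.features for r in records if r.features is not None and r.fit.is_event]
    fits = [r.fit for r in records if r.fit is not None and r.fit.converged and r.fit.is_event]
    fs_vals = [f.fs_event for f in feats if f.fs_event is not None]
    return {
        "n_valid": len(feats),
        "median_fs_event": float(np.median(fs_vals)) if fs_vals else np.nan,
        "median_dwell": float(np.median([f.dwell_time for f in feats])) if feats else np.nan,
        "median_i_ex": float(np.median([f.i_ex for f in feats])) if feats else np.nan,
        "median_abs_di_b": float(np.median([abs(f.params.di_b) for f in fits])) if fits else np.nan,
        "frac_overlap_valid": float(np.mean([f.overlap_valid for f in feats])) if feats else np.nan,
    }


def recommend_filter(
    trace: Trace,
    cutoffs,
    config: PipelineConfig | None = None,
    rel_tol: float = 0.10,
    min_events: int = 5,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Bracket the useful characterization-filter range from the data.

    Localizes once, characterizes at every cutoff, and reports per cutoff
    the median F_s,event, dwell time, excluded current, fitted depth and
    the fraction of events whose plateau validates.  The lower bound is
    the smallest cutoff whose median F_s,event is stable (changes less
    than ``rel_tol``) against the next cutoff up; the upper bound is the
    largest cutoff before the median fitted depth starts decreasing as
    baseline noise bleeds into the fits.  Cutoffs with fewer than
    ``min_events`` valid events are flagged unreliable and excluded from
    bound selection.
    """
    cutoffs = sorted(float(c) for c in cutoffs)
    if len(cutoffs) < 3:
        raise ValueError("need at least 3 cutoffs to bracket a range")
    config = config or PipelineConfig()

    loc = gaussian_lowpass(trace, config.localization_cutoff)
    windows = detect_events(
        loc,
        threshold_k=config.threshold_k,
        merge_gap=config.merge_gap,
        baseline_window=config.baseline_window,
        direction=config.direction,
    )

    rows = []
    for cutoff in cutoffs:
        recs = characterize_trace(
            trace,
            characterization_filter=FilterSpec("gaussian", cutoff),
            config=config,
            windows=windows,
        )
        row = {"cutoff": cutoff, **_summary_row(recs)}
        row["reliable"] = row["n_valid"] >= min_events
        rows.append(row)
    table = pd.DataFrame(rows)

    ok = table[table["reliable"]].reset_index(drop=True)
    if len(ok) < 2:
        warnings.warn("too few reliable cutoffs to bracket a range", stacklevel=2)
        return (np.nan, np.nan), table

    lower = ok["cutoff"].iloc[-1]
    for i in range(len(ok) - 1):
        a, b = ok["median_fs_event"].iloc[i], ok["median_fs_event"].iloc[i + 1]
        if np.isfinite(a) and np.isfinite(b) and abs(a - b) < rel_tol * abs(b):
            lower = ok["cutoff"].iloc[i]
            break
    upper = ok["cutoff"].iloc[int(np.nanargmax(ok["median_abs_di_b"].to_numpy()))]
    if upper < lower:
        warnings.warn(
            "fitted depth peaks below the stability cutoff; range is empty",
            stacklevel=2,
        )
    return (float(lower), float(upper)), table
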