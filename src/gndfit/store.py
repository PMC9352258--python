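"""SQLite event store.

Detections, fitted parameters and derived features live in three
normalized tables keyed by ``event_id``, so a detection persists even
when its fit failed and fits can be audited against the raw detections.
A ``meta`` table snapshots the configuration, code version and filters
used.  Re-running a trace replaces rows by ``(trace_id, t_start)``.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .features import EventFeatures
from .filters import FilterSpec
from .fitting import FitResult

__all__ = ["EventRecord", "store_events", "read_events", "export_csv"]

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS detections (
    event_id INTEGER PRIMARY KEY,
    trace_id TEXT NOT NULL,
    t_start REAL NOT NULL,
    t_end REAL NOT NULL,
    baseline_mean REAL,
    baseline_sd REAL,
    UNIQUE (trace_id, t_start)
);
CREATE TABLE IF NOT EXISTS fits (
    event_id INTEGER PRIMARY KEY REFERENCES detections(event_id),
    i_open REAL, di_b REAL, mu REAL, sigma REAL, beta REAL,
    rmse REAL, converged INTEGER, is_event INTEGER, at_bound TEXT
);
CREATE TABLE IF NOT EXISTS features (
    event_id INTEGER PRIMARY KEY REFERENCES detections(event_id),
    dwell_time REAL, i_ex REAL, fs_event REAL,
    loc_valid INTEGER, overlap_valid INTEGER, p_threshold REAL
);
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
"""


@dataclass
class EventRecord:
    """One detected event with its fit and features (either may be absent)."""

    trace_id: str
    t_start: float
    t_end: float
    baseline_mean: float = 0.0
    baseline_sd: float = 0.0
    fit: FitResult | None = None
    features: EventFeatures | None = None
    localization_filter: FilterSpec | None = None
    characterization_filter: FilterSpec | None = None
    event_id: int | None = None

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be before t_end")


def _connect(path) -> sqlite3.Connection:
    con = sqlite3.connect(str(path))
    con.executescript(_SCHEMA)
    row = con.execute("SELECT value FROM meta WHERE key='schema_version'").fetchone()
    if row is None:
        con.execute(
            "INSERT INTO meta VALUES ('schema_version', ?)", (str(SCHEMA_VERSION),)
        )
    elif int(row[0]) != SCHEMA_VERSION:
        con.close()
        raise ValueError(
            f"store schema version {row[0]} != {SCHEMA_VERSION}; "
            "re-export events and rebuild the store with this version"
        )
    return con


def store_events(
    records: list[EventRecord], path, config: dict | None = None
) -> int:
    """Write records (idempotently, replacing by trace_id + t_start)."""
    from . import __version__

    con = _connect(path)
    try:
        with con:
            meta = {
                "code_version": __version__,
                "config": json.dumps(config or {}, default=str),
            }
            for rec in records:
                if rec.localization_filter:
                    meta["localization_filter"] = str(rec.localization_filter)
                if rec.characterization_filter:
                    meta["characterization_filter"] = str(rec.characterization_filter)
            for k, v in meta.items():
                con.execute("INSERT OR REPLACE INTO meta VALUES (?, ?)", (k, v))

            for rec in records:
                old = con.execute(
                    "SELECT event_id FROM detections WHERE trace_id=? AND t_start=?",
                    (rec.trace_id, rec.t_start),
                ).fetchone()
                if old is not None:
                    for table in ("features", "fits", "detections"):
                        con.execute(
                            f"DELETE FROM {table} WHERE event_id=?", (old[0],)
                        )
                cur = con.execute(
                    "INSERT INTO detections (trace_id, t_start, t_end, "
                    "baseline_mean, baseline_sd) VALUES (?, ?, ?, ?, ?)",
                    (
                        rec.trace_id,
                        rec.t_start,
                        rec.t_end,
                        rec.baseline_mean,
                        rec.baseline_sd,
                    ),
                )
                rec.event_id = cur.lastrowid
                if rec.fit is not None:
                    p = rec.fit.params
                    con.execute(
                        "INSERT INTO fits VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                        (
                            rec.event_id,
                            p.i_open,
                            p.di_b,
                            p.mu,
                            p.sigma,
                            p.beta,
                            rec.fit.rmse,
                            int(rec.fit.converged),
                            int(rec.fit.is_event),
                            ",".join(sorted(rec.fit.at_bound)),
                        ),
                    )
                if rec.features is not None:
                    f = rec.features
                    con.execute(
                        "INSERT INTO features VALUES (?, ?, ?, ?, ?, ?, ?)",
                        (
                            rec.event_id,
                            f.dwell_time,
                            f.i_ex,
                            f.fs_event,
                            int(f.loc_valid),
                            int(f.overlap_valid),
                            f.p_threshold,
                        ),
                    )
        return len(records)
    finally:
        con.close()


def read_events(path) -> pd.DataFrame:
    """All events as one flat table (left-joined on detections)."""
    if not Path(path).exists():
        raise FileNotFoundError(f"event store not found: {path}")
    con = _connect(path)
    try:
        return pd.read_sql_query(
            "SELECT d.*, f.i_open, f.di_b, f.mu, f.sigma, f.beta, f.rmse, "
            "f.converged, f.is_event, f.at_bound, "
            "x.dwell_time, x.i_ex, x.fs_event, x.loc_valid, x.overlap_valid, "
            "x.p_threshold "
            "FROM detections d "
            "LEFT JOIN fits f USING (event_id) "
            "LEFT JOIN features x USING (event_id) "
            "ORDER BY d.trace_id, d.t_start",
            con,
        )
    finally:
        con.close()


def export_csv(path, out) -> Path:
    """Dump the joined event table to CSV; returns the output path."""
    out = Path(out)
    read_events(path).to_csv(out, index=False)
    return out
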