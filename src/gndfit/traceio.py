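"""Trace readers and writers: CSV, NPY (+ JSON sidecar) and optional ABF.

CSV dialect: either a ``time_s,current_pA`` two-column file (the sampling
frequency is recovered from the time column, which must be uniform) or a
``current_pA`` single column preceded by a ``# fs_hz=...`` header comment.
NPY traces carry their metadata in a ``.json`` sidecar next to the array.
Axon Binary Files are read through ``pyabf`` when it is installed;
without it the reader raises a clear error rather than crashing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import Trace

__all__ = ["read_trace", "write_trace"]

_UNIFORMITY_RTOL = 1e-6


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".csv", ".txt"):
        return "csv"
    if suffix == ".npy":
        return "npy"
    if suffix == ".abf":
        return "abf"
    raise ValueError(f"cannot infer trace format from {path.name!r}")


def read_trace(path, fmt: str | None = None) -> Trace:
    """Read a current trace from CSV, NPY or ABF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    fmt = fmt or _infer_format(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "npy":
        return _read_npy(path)
    if fmt == "abf":
        return _read_abf(path)
    raise ValueError(f"unsupported trace format {fmt!r}")


def _read_csv(path: Path) -> Trace:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if val:
                    header[key.strip()] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        df = pd.read_csv(fh)
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(float)
        dt = np.diff(t)
        if dt.size and not np.allclose(dt, dt[0], rtol=_UNIFORMITY_RTOL, atol=0):
            raise ValueError(f"{path}: time_s column is not uniformly sampled")
        fs = 1.0 / float(np.median(dt))
        t0 = float(t[0])
    elif "fs_hz" in header:
        fs = header["fs_hz"]
        t0 = header.get("t0_s", 0.0)
    else:
        raise ValueError(
            f"{path}: sampling frequency unknown — provide a 'time_s' column "
            "or an '# fs_hz=...' header line"
        )
    if "current_pA" not in df.columns:
        raise ValueError(f"{path}: missing 'current_pA' column")
    return Trace(df["current_pA"].to_numpy(float), fs, t0)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_npy(path: Path) -> Trace:
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ValueError(
            f"{path}: missing JSON sidecar {sidecar.name} with the required "
            "'fs_hz' field"
        )
    meta = json.loads(sidecar.read_text())
    if "fs_hz" not in meta:
        raise ValueError(f"{sidecar}: missing required 'fs_hz' field")
    return Trace(np.load(path), float(meta["fs_hz"]), float(meta.get("t0_s", 0.0)))


def _read_abf(path: Path) -> Trace:
    try:
        import pyabf  # optional dependency
    except ImportError as exc:
        raise ImportError(
            "reading Axon Binary Files requires the optional 'pyabf' package "
            "(pip install gndfit[abf])"
        ) from exc
    abf = pyabf.ABF(str(path))
    abf.setSweep(0)
    return Trace(np.asarray(abf.sweepY, float), float(abf.dataRate), 0.0)


def write_trace(trace: Trace, path, fmt: str | None = None) -> Path:
    """Write a trace to CSV (with fs header) or NPY (with JSON sidecar)."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# fs_hz={trace.fs!r}\n# t0_s={trace.t0!r}\n")
            fh.write("current_pA\n")
            np.savetxt(fh, trace.samples, fmt="%.6f")
    elif fmt == "npy":
        np.save(path, trace.samples)
        _sidecar(path).write_text(
            json.dumps({"fs_hz": trace.fs, "t0_s": trace.t0})
        )
    else:
        raise ValueError(f"unsupported output format {fmt!r}")
    return path
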