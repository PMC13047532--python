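"""Trace file I/O.

Traces travel as a CSV (columns ``time_s,o2_um``; UTF-8, '.' decimal;
oxygen in micromolar at the file boundary, converted to molar in
memory) plus a YAML sidecar ``<name>.meta.yaml`` holding the
injection times, compound and chain parameters.  Reading validates
the OxTrace invariants and rejects malformed files with the offending
line; writing then reading is lossless to 1e-12 relative on the
numeric columns and exact on metadata.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import yaml

from lipoxkin.oximetry_sim import OxTrace


class TraceFormatError(ValueError):
    """A trace file violates the CSV dialect or the trace invariants."""


def sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.yaml") if p.suffix != ".csv" \
        else p.with_name(p.stem + ".meta.yaml")


def write_trace(trace: OxTrace, path: str | Path) -> Path:
    """Write the trace CSV and its metadata sidecar; returns the CSV
    path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "o2_um"])
        for t, o2 in zip(trace.times, trace.o2):
            w.writerow([f"{t:.6f}", f"{o2 * 1e6:.9f}"])
    meta = {
        "t_init_s": float(trace.t_init),
        "t_aox_s": None if trace.t_aox is None else float(trace.t_aox),
        **{k: v for k, v in trace.meta.items()},
    }
    with open(sidecar_path(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_trace(path: str | Path) -> OxTrace:
    """Read a trace CSV + sidecar back into an OxTrace.

    Raises TraceFormatError naming the offending line for a missing
    header, unparsable numbers, non-monotone times or negative O2.
    """
    path = Path(path)
    times: list[float] = []
    o2: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TraceFormatError(f"{path}: empty file") from None
        if [h.strip() for h in header[:2]] != ["time_s", "o2_um"]:
            raise TraceFormatError(
                f"{path}: line 1: expected header 'time_s,o2_um', "
                f"got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                t, v = float(row[0]), float(row[1])
            except (ValueError, IndexError):
                raise TraceFormatError(
                    f"{path}: line {lineno}: cannot parse {row!r}"
                ) from None
            if times and t <= times[-1]:
                raise TraceFormatError(
                    f"{path}: line {lineno}: time {t} not increasing"
                )
            if v < 0:
                raise TraceFormatError(
                    f"{path}: line {lineno}: negative O2 {v}"
                )
            times.append(t)
            o2.append(v * 1e-6)

    side = sidecar_path(path)
    if not side.exists():
        raise TraceFormatError(f"{side}: sidecar metadata file missing")
    with open(side, encoding="utf-8") as fh:
        meta = yaml.safe_load(fh) or {}
    t_init = meta.pop("t_init_s", 0.0)
    t_aox = meta.pop("t_aox_s", None)
    try:
        return OxTrace(np.asarray(times), np.asarray(o2),
                       t_init=float(t_init),
                       t_aox=None if t_aox is None else float(t_aox),
                       meta=meta)
    except ValueError as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc
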