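"""Plain-text I/O: two-column signal CSV, cohort manifests, feature tables,
rankings, and key=value config files.

Signal CSV dialect: header ``time_s,amplitude``, comma separator, dot
decimal, uniform time stamps.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import WaveformSignal
from .errors import ParseError

SIGNAL_HEADER = ("time_s", "amplitude")
_REL_DT_TOL = 1e-6


def write_signal_csv(signal: WaveformSignal, path) -> None:
    """Write a signal as two-column CSV (time to 1 us, amplitude to 10 sig figs)."""
    t = signal.times()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SIGNAL_HEADER)
        for ti, xi in zip(t, signal.samples):
            writer.writerow([f"{ti:.6f}", f"{xi:.10g}"])


def read_signal_csv(path, record_id: str | None = None) -> WaveformSignal:
    """Read a two-column signal CSV; rejects nonuniform time stamps."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if tuple(h.strip() for h in header) != SIGNAL_HEADER:
            raise ParseError(f"{path}: line 1: expected header 'time_s,amplitude', got {header}")
        times, values = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                times.append(float(row[0]))
                values.append(float(row[1]))
            except (ValueError, IndexError):
                raise ParseError(f"{path}: line {lineno}: malformed row {row}") from None
    if len(times) < 2:
        raise ParseError(f"{path}: need at least 2 samples")
    t = np.asarray(times)
    dt = np.diff(t)
    if np.any(dt <= 0) or np.max(np.abs(dt - dt[0])) > _REL_DT_TOL * max(dt[0], 1e-12):
        bad = int(np.argmax(np.abs(dt - dt[0]))) + 3  # +2 header/0-base, +1 second point
        raise ParseError(f"{path}: line {bad}: nonuniform time stamps (expected step {dt[0]:g} s)")
    return WaveformSignal(np.asarray(values), 1.0 / dt[0], record_id=record_id or path.stem)


def write_manifest_csv(rows, path) -> None:
    """Write a cohort manifest: record_id,label per row."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "label"])
        writer.writerows(rows)


def write_beats_csv(record_id: str, peak_times, path) -> None:
    """Write detected beat times: record_id,peak_time_s per row."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "peak_time_s"])
        for t in peak_times:
            writer.writerow([record_id, f"{t:.6f}"])


def write_feature_table_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="record_id")


def read_feature_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="record_id")


def write_report_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_config_file(path) -> dict[str, str]:
    """Parse a plain ``key = value`` config file ('#' starts a comment)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}: line {lineno}: expected 'key = value', got {raw!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
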