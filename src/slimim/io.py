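"""Plain-text I/O: traces, reference tables, tidy outputs.

Traces travel as delimited text (comma or tab, sniffed on read) with
unit-bearing column names and the acquisition metadata embedded as a
commented JSON header line, so a trace file round-trips losslessly and
stays greppable.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .calibration import ReferencePoint
from .synthetic import IMTrace

__all__ = ["write_trace", "read_trace", "read_reference_table", "write_table"]

_META_PREFIX = "# meta: "


def write_trace(trace: IMTrace, path: str | Path, sep: str = ",") -> None:
    """Write a trace as delimited text with a ``# meta:`` JSON header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_META_PREFIX + json.dumps(trace.metadata, default=float) + "\n")
        fh.write(sep.join(["time_ms", "intensity"]) + "\n")
        for t, y in zip(trace.time_ms, trace.intensity):
            fh.write(f"{t:.6g}{sep}{y:.8g}\n")


def read_trace(path: str | Path) -> IMTrace:
    """Read a delimited-text trace; delimiter is sniffed, metadata optional."""
    path = Path(path)
    meta: dict = {}
    lines = []
    for line in path.read_text().splitlines():
        if line.startswith(_META_PREFIX):
            meta = json.loads(line[len(_META_PREFIX):])
        elif line.startswith("#") or not line.strip():
            continue
        else:
            lines.append(line)
    if not lines:
        raise ValueError(f"no data rows in {path}")
    sep = csv.Sniffer().sniff(lines[1] if len(lines) > 1 else lines[0], delimiters=",\t; ").delimiter
    df = pd.read_csv(_io.StringIO("\n".join(lines)), sep=sep)
    cols = {c.lower().strip(): c for c in df.columns}
    tcol = next((cols[c] for c in cols if c.startswith("time")), df.columns[0])
    icol = next((cols[c] for c in cols if c.startswith("intens") or c.startswith("count")),
                df.columns[1])
    return IMTrace(time_ms=df[tcol].to_numpy(float), intensity=df[icol].to_numpy(float),
                   metadata=meta)


def read_reference_table(path: str | Path) -> list[ReferencePoint]:
    """Read a calibrant table (label, mz, z, arrival_time_ms, ccs_ref).

    Delimiter is sniffed; column names are matched case-insensitively and
    ``ccs_ref``/``ccs`` are both accepted.
    """
    text = Path(path).read_text()
    data_lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    sep = csv.Sniffer().sniff(data_lines[1], delimiters=",\t;").delimiter
    df = pd.read_csv(_io.StringIO("\n".join(data_lines)), sep=sep)
    df.columns = [c.lower().strip() for c in df.columns]
    ccs_col = "ccs_ref" if "ccs_ref" in df.columns else "ccs"
    return [
        ReferencePoint(
            label=str(r.get("label", f"ion{i}")),
            mz=float(r["mz"]), z=int(r.get("z", 1)),
            arrival_time_ms=float(r["arrival_time_ms"]),
            ccs_ref=float(r[ccs_col]),
        )
        for i, r in df.iterrows()
    ]


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a tidy table as delimited text (no index)."""
    df.to_csv(path, sep=sep, index=False)
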