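"""Tabular output with bit-stable formatting.

Floats are rendered with 6 significant digits via a fixed format so that
re-running an identical analysis writes byte-identical files.
"""

from __future__ import annotations

import csv
import json
import os
from typing import Mapping, Sequence


def _fmt(value):
    if isinstance(value, bool) or value is None:
        return value
    if isinstance(value, float):
        return format(value, ".6g")
    return value


def write_table(records: Sequence[Mapping], path: str | os.PathLike,
                format: str = "csv",
                columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records as CSV or JSON-lines.

    ``columns`` pins the header order (and is required for an empty record
    set in CSV mode, since there is nothing to infer it from).
    """
    if format not in ("csv", "jsonl"):
        raise ValueError(f"unsupported table format {format!r}")
    if columns is None:
        if records:
            columns = list(records[0].keys())
        elif format == "csv":
            raise ValueError("empty record set needs explicit columns")
        else:
            columns = []
    for i, rec in enumerate(records):
        if set(rec.keys()) != set(columns):
            raise ValueError(f"record {i} columns {sorted(rec)} != {sorted(columns)}")
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(columns)
            for rec in records:
                writer.writerow([_fmt(rec[c]) for c in columns])
    else:
        with open(path, "w") as fh:
            for rec in records:
                fh.write(json.dumps({c: _fmt(rec[c]) for c in columns}, sort_keys=False))
                fh.write("\n")


def read_table(path: str | os.PathLike, format: str = "csv") -> list[dict]:
    """Round-trip reader used by tests and the report command."""
    if format == "csv":
        with open(path, newline="") as fh:
            return [dict(row) for row in csv.DictReader(fh)]
    if format == "jsonl":
        with open(path) as fh:
            return [json.loads(line) for line in fh if line.strip()]
    raise ValueError(f"unsupported table format {format!r}")
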