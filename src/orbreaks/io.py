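"""Case-table CSV I/O, schema validation, and plain-text configuration."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synthetic import CSV_COLUMNS

TIMESTAMP_FMT = "%Y-%m-%dT%H:%M"


def write_cases(cases: pd.DataFrame, path: str | Path) -> None:
    """Write a case table with the canonical header and ISO-8601 minutes."""
    out = cases.copy()
    out["surgery_start"] = out["surgery_start"].dt.strftime(TIMESTAMP_FMT)
    out["surgery_end"] = out["surgery_end"].dt.strftime(TIMESTAMP_FMT)
    out.to_csv(path, index=False, columns=CSV_COLUMNS, lineterminator="\n")


def read_cases(path: str | Path) -> pd.DataFrame:
    """Read and validate a case table; schema errors name the CSV line.

    Checks: exact header, positive integer room, parseable ISO timestamps,
    and surgery_end strictly after surgery_start.  Line numbers are
    1-based including the header line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if header != ",".join(CSV_COLUMNS):
        raise ValueError(f"{path}: line 1: header must be "
                         f"{','.join(CSV_COLUMNS)!r}, got {header!r}")
    df = pd.read_csv(path, dtype={"facility": str, "code": str, "service": str,
                                  "date": str})
    if df.empty:
        df["room"] = df.get("room", pd.Series(dtype=int))
        df["surgery_start"] = pd.to_datetime(df["surgery_start"])
        df["surgery_end"] = pd.to_datetime(df["surgery_end"])
        return df

    def _fail(mask: pd.Series, message: str) -> None:
        if mask.any():
            line = int(mask.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: line {line}: {message}")

    room = pd.to_numeric(df["room"], errors="coerce")
    _fail(room.isna() | (room != room.round()) | (room < 1),
          "room must be a positive integer")
    df["room"] = room.astype(int)
    for col in ("surgery_start", "surgery_end"):
        parsed = pd.to_datetime(df[col], format=TIMESTAMP_FMT, errors="coerce")
        _fail(parsed.isna(), f"{col} must be an ISO-8601 YYYY-MM-DDTHH:MM timestamp")
        df[col] = parsed
    _fail(df["surgery_end"] <= df["surgery_start"],
          "surgery_end must be after surgery_start")
    _fail(pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce").isna(),
          "date must be an ISO calendar date")
    return df


def parse_config(path: str | Path) -> dict[str, str]:
    """Parse a plain ``key = value`` text config; '#' starts a comment."""
    cfg: dict[str, str] = {}
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {i}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        cfg[key.strip()] = value.strip()
    return cfg


def write_metadata(path: str | Path, **fields) -> None:
    """Machine-readable run metadata (seed, parameters) as JSON."""
    Path(path).write_text(json.dumps(fields, indent=2, sort_keys=True,
                                     default=str) + "\n")
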