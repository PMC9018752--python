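"""Table I/O with validation, atomic writes and run provenance."""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import pandas as pd

__all__ = [
    "read_table",
    "atomic_write_csv",
    "atomic_write_many",
    "write_run_info",
    "TIMESERIES_COLUMNS",
    "PLATEMAP_COLUMNS",
    "LIBRARY_COLUMNS",
]

TIMESERIES_COLUMNS = ("plate", "well", "time_h", "confluence_pct", "gfp_mean_gcu")
PLATEMAP_COLUMNS = ("plate", "well", "role", "compound_id")
LIBRARY_COLUMNS = ("compound_id", "category")


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a CSV, reporting the offending file (and line) on failure."""
    path = Path(path)
    try:
        df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    except FileNotFoundError:
        raise FileNotFoundError(f"input file not found: {path}") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing} "
                         f"(found {list(df.columns)})")
    return df


def atomic_write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a CSV via a temp file + rename so readers never see partials."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def atomic_write_many(tables: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write several tables; on any failure remove the ones already written."""
    outdir = Path(outdir)
    written: list[Path] = []
    try:
        for name, df in tables.items():
            written.append(atomic_write_csv(df, outdir / name))
    except BaseException:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return written


def write_run_info(outdir: str | Path, *, seed: int, command: str,
                   config_dict: dict | None = None) -> Path:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    info = {
        "package": "cox2screen",
        "version": __version__,
        "command": command,
        "seed": int(seed),
        "config": config_dict or {},
    }
    path = outdir / "run_info.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(info, indent=2, default=str))
    os.replace(tmp, path)
    return path
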