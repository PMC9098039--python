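"""Delimited-table I/O with fixed schemas.

All tables are comma-separated UTF-8 text with a header row. The trials
schema is fixed; feature and response columns are recognised optional
extensions. Round-tripping a table through disk reproduces integers
bit-exactly and reals to within 1e-12.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import yaml

from .design import TRIAL_COLUMNS
from .exceptions import EmptyInputError, SchemaError
from .features import FEATURE_COLUMNS

#: Columns a trials table may carry beyond the fixed schema.
OPTIONAL_COLUMNS = (*FEATURE_COLUMNS, "allocator_type", "feeling", "punishment",
                    "predicted", "response_scale")


def write_tables(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a trials/responses table as CSV (UTF-8, header, one trial per line)."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cannot write table missing required column(s): {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, encoding="utf-8")


def load_tables(path: str | os.PathLike) -> pd.DataFrame:
    """Load a trials/responses table, validating the schema.

    Raises :class:`SchemaError` naming the offending column for unknown
    or missing columns, and :class:`EmptyInputError` for an empty file.
    """
    try:
        table = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty input file")
    if table.empty:
        raise EmptyInputError(f"{path}: table has no rows")
    for col in TRIAL_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    known = set(TRIAL_COLUMNS) | set(OPTIONAL_COLUMNS)
    for col in table.columns:
        if col not in known:
            raise SchemaError(f"{path}: unknown column {col!r}")
    for col in ("collect_feeling", "collect_punishment"):
        table[col] = table[col].astype(bool)
    return table


def write_config(config: dict, path: str | os.PathLike) -> None:
    """Echo a run configuration verbatim into a YAML sidecar."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def load_config(path: str | os.PathLike) -> dict:
    with open(path, encoding="utf-8") as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return out
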