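"""Readers and writers for the pipeline's tabular and JSON artifacts.

CSV dialect: comma-separated, UTF-8, '.' decimal, mandatory header, no index
column.  Positions are printed with 12 significant digits so tables
round-trip without measurable loss.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .design import TRIAL_COLUMNS
from .groupstats import GroupResult
from .observers import PARTICIPANT_COLUMNS

__all__ = [
    "SchemaError",
    "write_trials",
    "read_trials",
    "write_participants",
    "read_participants",
    "write_metrics",
    "read_metrics",
    "write_results",
    "read_results",
    "write_manifest",
    "file_sha256",
]

_FLOAT_FMT = "%.12g"


class SchemaError(ValueError):
    """A table does not match its expected schema."""


def _check_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    if list(df.columns) != list(expected):
        raise SchemaError(
            f"{what}: expected columns {expected}, got {list(df.columns)}"
        )


def write_trials(df: pd.DataFrame, path) -> None:
    _check_columns(df, TRIAL_COLUMNS, "trial table")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, TRIAL_COLUMNS, f"trial table {path}")
    numeric = [c for c in TRIAL_COLUMNS if c.startswith("splash_")] + [
        "mu_L",
        "coin_pos",
        "response",
    ]
    for col in numeric + ["block_index", "trial_index"]:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = int(bad[0]) if len(bad) else -1
            raise SchemaError(f"trial table {path}: non-numeric value in column {col}, row {row}")
    return df


def write_participants(df: pd.DataFrame, path) -> None:
    _check_columns(df, PARTICIPANT_COLUMNS, "participant table")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, PARTICIPANT_COLUMNS, f"participant table {path}")
    return df


def write_metrics(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant_id" not in df.columns or "excluded" not in df.columns:
        raise SchemaError(f"metrics table {path}: missing participant_id/excluded columns")
    df["exclusion_reason"] = df["exclusion_reason"].fillna("")
    return df


def write_results(results: list[GroupResult], path, extra: dict | None = None) -> None:
    payload = {"results": [r.to_dict() for r in results]}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, seed: int, config: dict, files: dict[str, str]) -> None:
    """Record seed, resolved configuration (with its hash) and output hashes."""
    canonical = json.dumps(config, sort_keys=True)
    manifest = {
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "files": files,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
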