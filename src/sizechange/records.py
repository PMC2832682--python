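"""Versioned CSV I/O for trial-record tables.

Records are plain RFC-4180 CSV, one row per trial, with a ``schema_version``
column; the reader rejects unknown versions and reports schema violations
with row numbers.  The writer/reader round trip is exact (floats serialize
via ``repr``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .design import CueCondition

__all__ = ["SCHEMA_VERSION", "SchemaError", "write_records", "read_records"]

SCHEMA_VERSION = 1

_COMMON = [
    "trial_id",
    "experiment",
    "condition",
    "size_rate_mm_s",
    "initial_diameter_mm",
    "initial_distance_mm",
    "duration_s",
    "osc_amplitude_mm",
    "osc_freq_hz",
    "seed",
]
_EXP1 = _COMMON + [
    "pedestal_mm_s",
    "satellite_mm_s",
    "distance_rate_mm_s",
    "direction_group",
]
_EXP2 = _COMMON + ["standard_mm_s", "offset_mm_s", "comparison_mm_s", "standard_first"]

_EXP1_RESPONSES = {"inflating", "deflating"}
_EXP2_RESPONSES = {"1st", "2nd"}


class SchemaError(ValueError):
    """A record table violates the CSV schema."""


def write_records(records: pd.DataFrame, path) -> None:
    """Write a trial-record table as versioned CSV."""
    out = records.copy()
    if "schema_version" not in out.columns:
        out.insert(0, "schema_version", SCHEMA_VERSION)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_records(path, experiment: int | None = None) -> pd.DataFrame:
    """Read and validate a trial-record CSV.

    Raises :class:`SchemaError` naming missing columns, unknown schema
    versions, and invalid values with their row numbers.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "schema_version" not in df.columns:
        raise SchemaError("missing required column: schema_version")
    versions = set(df["schema_version"].unique())
    if versions - {SCHEMA_VERSION}:
        raise SchemaError(
            f"unknown schema version(s) {sorted(versions - {SCHEMA_VERSION})}; "
            f"this reader supports version {SCHEMA_VERSION}"
        )
    if experiment is None:
        if "experiment" not in df.columns:
            raise SchemaError("missing required column: experiment")
        exps = set(df["experiment"].unique())
        if len(exps) != 1:
            raise SchemaError(f"mixed experiments in one file: {sorted(exps)}")
        experiment = int(exps.pop())
    required = _EXP1 if experiment == 1 else _EXP2
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    bad_cond = [
        i
        for i, c in enumerate(df["condition"])
        if not _is_valid_condition(c)
    ]
    if bad_cond:
        raise SchemaError(f"invalid condition label at row(s): {bad_cond[:10]}")
    if "response" in df.columns:
        valid = _EXP1_RESPONSES if experiment == 1 else _EXP2_RESPONSES
        bad = [i for i, r in enumerate(df["response"]) if r not in valid]
        if bad:
            raise SchemaError(
                f"invalid response value at row(s): {bad[:10]} "
                f"(expected one of {sorted(valid)})"
            )
    return df


def _is_valid_condition(label) -> bool:
    try:
        CueCondition.parse(str(label))
        return True
    except ValueError:
        return False
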