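"""Cohort CSV readers/writers and provenance blocks.

Dialect: comma-separated, dot decimal, UTF-8, header required
(``patient_id,diameter_cm``); trailing blank lines are ignored.  Every run
writes a ``provenance.json`` next to its outputs with the full parameter
echo, seed and package version, so the run can be reproduced exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "CohortFormatError",
    "CohortReadResult",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_provenance",
]

COHORT_COLUMNS = ["patient_id", "diameter_cm"]


class CohortFormatError(ValueError):
    pass


@dataclass(frozen=True)
class CohortReadResult:
    """Validated cohort table plus per-row errors (1-based file row numbers,
    counting the header as row 1)."""

    table: pd.DataFrame
    row_errors: list


def read_cohort_csv(path: str | Path) -> CohortReadResult:
    """Read and validate a cohort CSV.

    Structural problems (missing header columns, duplicate patient ids) raise
    :class:`CohortFormatError`; malformed data rows (non-numeric or negative
    diameters) are collected into ``row_errors`` and the run continues with
    the valid rows.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype={"patient_id": str}, skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise CohortFormatError(f"{path}: file is empty or has no header") from exc
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required column(s) {', '.join(missing)} "
                                f"(header must contain {','.join(COHORT_COLUMNS)})")
    dup = raw["patient_id"][raw["patient_id"].duplicated()].unique()
    if len(dup):
        raise CohortFormatError(f"{path}: duplicate patient_id values: {', '.join(map(str, dup[:5]))}")

    diam = pd.to_numeric(raw["diameter_cm"], errors="coerce")
    bad = diam.isna() | (diam < 0)
    row_errors = [
        (int(i) + 2, f"row {int(i) + 2}: invalid diameter {raw['diameter_cm'].iloc[i]!r} "
                     f"for patient {raw['patient_id'].iloc[i]!r}")
        for i in raw.index[bad]
    ]
    table = raw.loc[~bad, COHORT_COLUMNS].copy()
    table["diameter_cm"] = diam[~bad]
    return CohortReadResult(table=table.reset_index(drop=True), row_errors=row_errors)


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table; diameters keep full precision (round-trip safe)."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise CohortFormatError(f"cannot write cohort: missing column(s) {', '.join(missing)}")
    table[COHORT_COLUMNS].to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def write_provenance(outdir: str | Path, parameter_echo: dict, seed: int | None,
                     command: str | None = None) -> Path:
    """Write the provenance block for a run directory."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    block = {
        "package": "preresist",
        "version": __version__,
        "command": command,
        "seed": seed,
        "parameters": parameter_echo,
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(block, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path
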