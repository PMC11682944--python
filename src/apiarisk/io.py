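"""CSV readers/writers and schema validation for residue and toxicity tables.

Column names carry units (``concentration_ug_per_kg``) so that files remain
self-describing and unit drift is caught at the schema check rather than in
a downstream computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd

from .synthetic import RESIDUE_COLUMNS, TOXICITY_COLUMNS

__all__ = [
    "read_residues",
    "write_residues",
    "read_toxicity",
    "write_toxicity",
    "ValidationReport",
    "validate_inputs",
]

PathLike = Union[str, Path]

_RESIDUE_DTYPES = {
    "site_id": str,
    "proximity": str,
    "year": str,
    "time_point": str,
    "matrix": str,
    "compound": str,
    "censoring": str,
}


def read_residues(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=_RESIDUE_DTYPES)
    missing = set(RESIDUE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: residue table missing columns {sorted(missing)}")
    return df[RESIDUE_COLUMNS]


def write_residues(df: pd.DataFrame, path: PathLike) -> None:
    df[RESIDUE_COLUMNS].to_csv(path, index=False)


def read_toxicity(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"compound": str, "source_note": str})
    missing = set(TOXICITY_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: toxicity table missing columns {sorted(missing)}")
    if "source_note" not in df.columns:
        df["source_note"] = ""
    return df[TOXICITY_COLUMNS]


def write_toxicity(df: pd.DataFrame, path: PathLike) -> None:
    df[TOXICITY_COLUMNS].to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Fatal errors and non-fatal warnings from an input schema check."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


_VALID_PROXIMITY = {"near", "far"}
_VALID_MATRIX = {"pollen", "nectar"}
_VALID_CENSORING = {"detected", "below_loq", "below_lod"}


def validate_inputs(residues_path: PathLike, toxicity_path: PathLike) -> ValidationReport:
    """Schema-check a residue and a toxicity CSV without computing anything.

    Fatal: missing columns, invalid enum values, negative concentrations,
    duplicate (site, year, time point, matrix, compound) records,
    non-positive toxicity endpoints.  Warning: detected compounds absent
    from the toxicity table (they would be skipped, not crash).
    """
    report = ValidationReport()

    try:
        residues = read_residues(residues_path)
    except (OSError, ValueError) as exc:
        report.errors.append(str(exc))
        residues = None
    try:
        tox = read_toxicity(toxicity_path)
    except (OSError, ValueError) as exc:
        report.errors.append(str(exc))
        tox = None

    if residues is not None:
        for column, valid in [
            ("proximity", _VALID_PROXIMITY),
            ("matrix", _VALID_MATRIX),
            ("censoring", _VALID_CENSORING),
        ]:
            bad = set(residues[column].unique()) - valid
            if bad:
                report.errors.append(f"residues: invalid {column} values {sorted(bad)}")
        negative = residues.index[residues["concentration_ug_per_kg"] < 0]
        for idx in negative[:5]:
            report.errors.append(f"residues: negative concentration at row {idx}")
        keys = ["site_id", "year", "time_point", "matrix", "compound"]
        dups = residues[residues.duplicated(subset=keys, keep=False)]
        if not dups.empty:
            first = dups.iloc[0][keys].to_dict()
            report.errors.append(f"residues: duplicate matrix records, first at {first}")
        zero_but_flagged = residues[
            (residues["censoring"] == "below_lod") & (residues["concentration_ug_per_kg"] != 0)
        ]
        if not zero_but_flagged.empty:
            report.errors.append(
                f"residues: {len(zero_but_flagged)} below_lod rows with nonzero concentration"
            )

    if tox is not None:
        for col in TOXICITY_COLUMNS[1:4]:
            bad = tox[tox[col].notna() & (tox[col] <= 0)]
            if not bad.empty:
                report.errors.append(
                    f"toxicity: non-positive {col} for {sorted(bad['compound'])}"
                )
        no_endpoint = tox[tox[TOXICITY_COLUMNS[1:4]].isna().all(axis=1)]
        if not no_endpoint.empty:
            report.warnings.append(
                f"toxicity: no endpoint for {sorted(no_endpoint['compound'])}"
            )

    if residues is not None and tox is not None:
        detected = set(
            residues.loc[residues["censoring"].isin(["detected", "below_loq"]), "compound"]
        )
        uncovered = sorted(detected - set(tox["compound"]))
        if uncovered:
            report.warnings.append(
                f"detected compounds absent from toxicity table (will be skipped): {uncovered}"
            )

    return report
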