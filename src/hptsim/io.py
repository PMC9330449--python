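"""Tabular I/O: patient tables, trajectories, curves (one flat CSV dialect).

All CSV artifacts are comma-separated, dot-decimal, UTF-8 with a header row.
Writers can embed provenance (config hash, seed) as ``# key=value`` comment
lines, which readers skip.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .anthropometry import PatientProfile, Sex

__all__ = ["read_patients_csv", "write_csv", "read_csv"]


def read_patients_csv(path: "str | Path") -> list[PatientProfile]:
    """Parse a patient table with columns sex, height_m, weight_kg[, hematocrit].

    Sex accepts m/f/male/female, case-insensitive.  Malformed rows raise a
    line-numbered error.
    """
    df = pd.read_csv(path, comment="#")
    required = {"sex", "height_m", "weight_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    patients = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            hct = row.get("hematocrit")
            hct = None if hct is None or pd.isna(hct) else float(hct)
            patients.append(
                PatientProfile(
                    sex=Sex.parse(row["sex"]),
                    height=float(row["height_m"]),
                    weight=float(row["weight_kg"]),
                    hematocrit=hct,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
    return patients


def write_csv(df: pd.DataFrame, path: "str | Path", provenance: dict | None = None) -> None:
    """Write a table with optional ``# key=value`` provenance header lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def read_csv(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
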