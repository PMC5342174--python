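"""Readers and writers for the tab-separated study bundle.

The on-disk layout mirrors the supplementary-table convention of
peptidomic cohort studies: a cohort classification table (sample id,
centre, case/control, time-to-event, event flag, clinical covariates),
a sample x peptide amplitude matrix with 0 encoding "not detected", a
peptide catalogue (peptide id, mass in Da, mean CE migration time in
minutes), and per-sample peak-list files.  All files are UTF-8 TSV
with a header row; missing values are empty cells.  JSON reports are
pretty-printed with sorted keys so that re-runs diff cleanly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from acspredict.errors import ValidationError
from acspredict.peptidome import RawProfile

__all__ = [
    "Bundle",
    "read_bundle",
    "read_catalog",
    "read_cohort",
    "read_matrix",
    "read_profiles",
    "write_bundle",
    "write_json_report",
    "write_matrix",
    "write_profiles",
]

_COHORT_REQUIRED = ["centre", "is_case", "time_years", "event"]
_CATALOG_REQUIRED = ["mass_da", "cemt_min", "is_housekeeping"]


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="sample_id")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r} in {path}")
    vals = df.to_numpy()
    if np.any(~np.isfinite(vals)) or np.any(vals < 0):
        bad = np.argwhere(~(np.isfinite(vals) & (vals >= 0)))[0]
        raise ValidationError(
            f"negative or non-finite amplitude at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r} in {path}")
    return df


def _read_table(path, index_col: str, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if index_col not in df.columns:
        raise ValidationError(f"missing column {index_col!r} in {path}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s) {missing} in {path}")
    df = df.set_index(index_col)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate id {dup!r} in {path}")
    return df


def read_cohort(path) -> pd.DataFrame:
    return _read_table(path, "sample_id", _COHORT_REQUIRED)


def read_catalog(path) -> pd.DataFrame:
    df = _read_table(path, "peptide_id", _CATALOG_REQUIRED)
    if (df["mass_da"] <= 0).any():
        raise ValidationError(f"non-positive peptide mass in {path}")
    for col in ("is_housekeeping", "is_true_biomarker"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_profiles(profiles: list[RawProfile], directory) -> list[Path]:
    """One TSV per sample: mass_da, cemt_min, amplitude."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in profiles:
        path = directory / f"{p.sample_id}.tsv"
        pd.DataFrame({
            "mass_da": p.mass_da,
            "cemt_min": p.cemt_min,
            "amplitude": p.amplitude,
        }).to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_profiles(directory) -> list[RawProfile]:
    directory = Path(directory)
    profiles = []
    for path in sorted(directory.glob("*.tsv")):
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in ("mass_da", "cemt_min", "amplitude")
                   if c not in df.columns]
        if missing:
            raise ValidationError(f"missing column(s) {missing} in {path}")
        profiles.append(RawProfile(
            sample_id=path.stem,
            mass_da=df["mass_da"].to_numpy(),
            cemt_min=df["cemt_min"].to_numpy(),
            amplitude=df["amplitude"].to_numpy(),
        ))
    return profiles


@dataclass
class Bundle:
    """Cross-validated in-memory study bundle."""

    cohort: pd.DataFrame
    matrix: pd.DataFrame
    catalog: pd.DataFrame


def _cross_validate(cohort: pd.DataFrame, matrix: pd.DataFrame,
                    catalog: pd.DataFrame) -> None:
    orphan = matrix.index.difference(cohort.index)
    if len(orphan):
        raise ValidationError(
            f"matrix sample id {orphan[0]!r} absent from the cohort table")
    orphan = cohort.index.difference(matrix.index)
    if len(orphan):
        raise ValidationError(
            f"cohort sample id {orphan[0]!r} absent from the matrix")
    unknown = matrix.columns.difference(catalog.index)
    if len(unknown):
        raise ValidationError(
            f"matrix peptide id {unknown[0]!r} absent from the catalogue")


def read_bundle(cohort_path, matrix_path, catalog_path) -> Bundle:
    """Load and cross-validate the three study tables."""
    cohort = read_cohort(cohort_path)
    matrix = read_matrix(matrix_path)
    catalog = read_catalog(catalog_path)
    _cross_validate(cohort, matrix, catalog)
    return Bundle(cohort=cohort, matrix=matrix.loc[cohort.index],
                  catalog=catalog)


def write_bundle(directory, cohort: pd.DataFrame, matrix: pd.DataFrame,
                 catalog: pd.DataFrame,
                 truth: pd.DataFrame | None = None) -> dict:
    """Write the bundle TSVs (plus an optional JSON truth file)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": directory / "cohort.tsv",
        "matrix": directory / "matrix.tsv",
        "catalog": directory / "catalog.tsv",
    }
    cohort.to_csv(paths["cohort"], sep="\t", index_label="sample_id")
    write_matrix(matrix, paths["matrix"])
    catalog.to_csv(paths["catalog"], sep="\t", index_label="peptide_id")
    if truth is not None:
        paths["truth"] = directory / "truth.json"
        payload = truth.replace([np.inf, -np.inf], None).to_dict(
            orient="index")
        paths["truth"].write_text(
            json.dumps(payload, sort_keys=True, indent=2))
    return {k: str(v) for k, v in paths.items()}


def write_json_report(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    raise TypeError(f"not JSON serializable: {type(obj)}")
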