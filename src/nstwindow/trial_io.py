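"""Tabular I/O for the trial's five table schemas plus ground truth.

All tables are long-format UTF-8 CSV with "." decimals, one row per
measurement.  Readers validate the schema and report malformed rows by row
number and field; writers emit exactly the schema the readers accept, so
write -> read is the identity.

Below-LOD handling is split in two: the *flag* (``below_lod``) travels with
the data, while the *substitution* (:func:`apply_lod_policy`) is an explicit,
idempotent analysis step — half-LOD substitution by default, the common
residue-chemistry convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig, REGIONS, LOD_POLICIES
from .simulate import GroundTruth, RESIDUE_COLUMNS

__all__ = [
    "SchemaError",
    "read_residues", "write_residues",
    "read_ratings", "write_ratings",
    "read_stand", "write_stand",
    "read_yield", "write_yield",
    "read_weather", "write_weather",
    "read_ground_truth", "write_ground_truth",
    "apply_lod_policy",
]


class SchemaError(ValueError):
    """A table failed validation; the message names the row and field."""


KNOWN_TREATMENTS = ("naked", "fungicide", "low", "high")

_SIMPLE_SCHEMAS = {
    "ratings": (["year", "treatment", "block", "rating"], "rating"),
    "stand": (["year", "treatment", "block", "plants_per_ha"], "plants_per_ha"),
    "yield": (["year", "treatment", "block", "yield_kg_ha"], "yield_kg_ha"),
}


def _check_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s) {missing}")


def _bad_rows(mask: pd.Series) -> str:
    # 1-based data row numbers (header not counted), first few only.
    rows = (np.flatnonzero(mask.to_numpy()) + 1)[:5].tolist()
    return ", ".join(map(str, rows))


def read_residues(
    path: str | Path,
    lod: float | None = None,
    extra_treatments: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Read the long-format residue table.

    If ``lod`` is given, the ``below_lod`` flag is (re)derived as
    ``conc < lod``; otherwise a ``below_lod`` column in the file is kept
    (defaulting to False).
    """
    df = pd.read_csv(path, dtype={"year": str, "block": str},
                     float_precision="round_trip")
    _check_columns(df, [c for c in RESIDUE_COLUMNS if c not in ("below_lod",)],
                   "residues")

    if not pd.api.types.is_integer_dtype(df["dpp"]):
        bad = pd.to_numeric(df["dpp"], errors="coerce")
        frac = bad.isna() | (bad != bad.round())
        if frac.any():
            raise SchemaError(f"residues: non-integer dpp at row(s) {_bad_rows(frac)}")
        df["dpp"] = bad.astype(int)
    if (df["dpp"] < 0).any():
        raise SchemaError(
            f"residues: negative dpp at row(s) {_bad_rows(df['dpp'] < 0)}"
        )
    neg = df["conc"] < 0
    if neg.any():
        raise SchemaError(f"residues: negative conc at row(s) {_bad_rows(neg)}")
    allowed_trt = set(KNOWN_TREATMENTS) | set(extra_treatments)
    bad_trt = ~df["treatment"].isin(allowed_trt)
    if bad_trt.any():
        raise SchemaError(
            f"residues: unknown treatment at row(s) {_bad_rows(bad_trt)}"
        )
    bad_reg = ~df["region"].isin(REGIONS)
    if bad_reg.any():
        raise SchemaError(f"residues: unknown region at row(s) {_bad_rows(bad_reg)}")
    bad_comp = (df["completeness"] < 0) | (df["completeness"] > 1)
    if bad_comp.any():
        raise SchemaError(
            f"residues: completeness outside [0,1] at row(s) {_bad_rows(bad_comp)}"
        )

    if lod is not None:
        df["below_lod"] = df["conc"] < lod
    elif "below_lod" not in df.columns:
        df["below_lod"] = False
    else:
        df["below_lod"] = df["below_lod"].astype(bool)
    return df[RESIDUE_COLUMNS]


def write_residues(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, RESIDUE_COLUMNS, "residues")
    df[RESIDUE_COLUMNS].to_csv(path, index=False)


def _read_simple(path: str | Path, name: str) -> pd.DataFrame:
    cols, value_col = _SIMPLE_SCHEMAS[name]
    df = pd.read_csv(path, dtype={"year": str, "block": str},
                     float_precision="round_trip")
    _check_columns(df, cols, name)
    if df[value_col].isna().any():
        raise SchemaError(
            f"{name}: missing {value_col} at row(s) {_bad_rows(df[value_col].isna())}"
        )
    if (df[value_col] < 0).any():
        raise SchemaError(
            f"{name}: negative {value_col} at row(s) {_bad_rows(df[value_col] < 0)}"
        )
    return df[cols]


def _write_simple(df: pd.DataFrame, path: str | Path, name: str) -> None:
    cols, _ = _SIMPLE_SCHEMAS[name]
    _check_columns(df, cols, name)
    df[cols].to_csv(path, index=False)


def read_ratings(path):
    return _read_simple(path, "ratings")


def write_ratings(df, path):
    _write_simple(df, path, "ratings")


def read_stand(path):
    return _read_simple(path, "stand")


def write_stand(df, path):
    _write_simple(df, path, "stand")


def read_yield(path):
    return _read_simple(path, "yield")


def write_yield(df, path):
    _write_simple(df, path, "yield")


def read_weather(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"date": str}, float_precision="round_trip")
    _check_columns(df, ["date", "tmin", "tmax"], "weather")
    bad = df["tmin"] > df["tmax"]
    if bad.any():
        raise SchemaError(f"weather: tmin > tmax at row(s) {_bad_rows(bad)}")
    return df[["date", "tmin", "tmax"]]


def write_weather(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, ["date", "tmin", "tmax"], "weather")
    df[["date", "tmin", "tmax"]].to_csv(path, index=False)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path, "r", encoding="utf-8") as fh:
        return GroundTruth.from_dict(json.load(fh))


def apply_lod_policy(
    samples: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Substitute (or drop) below-LOD residue records per the configured policy.

    ``half_lod`` sets censored concentrations to LOD/2, ``zero`` to 0, and
    ``drop`` removes the records.  Records at or above the LOD are untouched,
    which makes the operation idempotent: substituted values keep their
    ``below_lod`` flag, so re-application finds nothing new to change.
    """
    if config.lod_policy not in LOD_POLICIES:
        raise ValueError(f"unknown lod_policy {config.lod_policy!r}")
    out = samples.copy()
    below = out["below_lod"].astype(bool)
    if config.lod_policy == "drop":
        return out.loc[~below].reset_index(drop=True)
    out.loc[below, "conc"] = config.lod / 2.0 if config.lod_policy == "half_lod" else 0.0
    return out
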