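"""CSV reader/writer layer with schema and referential-integrity validation.

Three tidy UTF-8 tables describe one experiment ('.' decimal separator,
header row, empty string for missing values):

* ``units.csv`` — unit_id, block, location, salinity, density, n_initial
* ``growth.csv`` — unit_id, day, mean_total_length_mm
* ``metamorphs.csv`` — unit_id, individual_id, survived,
  day_at_metamorphosis, total_length_mm
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import (DENSITIES, LOCATIONS, N_BLOCKS, SALINITIES,
                       ExperimentalUnit, SyntheticDataset, TreatmentCell)

logger = logging.getLogger(__name__)

UNITS_CSV = "units.csv"
GROWTH_CSV = "growth.csv"
METAMORPHS_CSV = "metamorphs.csv"


class DataValidationError(ValueError):
    """A CSV failed schema or integrity validation; names file/row/column."""

    def __init__(self, file: str, row: int | None, column: str | None,
                 message: str):
        loc = file
        if row is not None:
            loc += f", row {row}"
        if column is not None:
            loc += f", column {column!r}"
        super().__init__(f"{loc}: {message}")
        self.file, self.row, self.column = file, row, column


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write the three CSVs; missing endpoint fields become empty strings."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    units = dataset.units_frame
    paths["units"] = out / UNITS_CSV
    units.to_csv(paths["units"], index=False)

    paths["growth"] = out / GROWTH_CSV
    dataset.growth.to_csv(paths["growth"], index=False)

    meta = dataset.metamorphs.copy()
    day = meta["day_at_metamorphosis"]
    meta["day_at_metamorphosis"] = [
        "" if pd.isna(v) else str(int(v)) for v in day]
    paths["metamorphs"] = out / METAMORPHS_CSV
    meta.to_csv(paths["metamorphs"], index=False, na_rep="")
    logger.info("wrote dataset to %s", out)
    return paths


def _require_columns(df: pd.DataFrame, cols: list[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataValidationError(fname, None, missing[0],
                                  f"missing required column(s) {missing}")


def _check_levels(df, column, allowed, fname):
    for i, v in enumerate(df[column]):
        if v not in allowed:
            raise DataValidationError(
                fname, i + 2, column,
                f"value {v!r} not in allowed levels {sorted(map(str, allowed))}")


def read_dataset(data_dir) -> SyntheticDataset:
    """Read and validate a dataset directory; rejects schema violations and
    orphan unit_ids with the offending file, row and column named."""
    d = Path(data_dir)
    for fname in (UNITS_CSV, GROWTH_CSV, METAMORPHS_CSV):
        if not (d / fname).exists():
            raise FileNotFoundError(f"missing input file: {d / fname}")

    units = pd.read_csv(d / UNITS_CSV, float_precision="round_trip")
    _require_columns(units, ["unit_id", "block", "location", "salinity",
                             "density", "n_initial"], UNITS_CSV)
    _check_levels(units, "location", set(LOCATIONS), UNITS_CSV)
    _check_levels(units, "salinity", set(SALINITIES), UNITS_CSV)
    _check_levels(units, "density", set(DENSITIES), UNITS_CSV)
    _check_levels(units, "block", set(range(1, N_BLOCKS + 1)), UNITS_CSV)
    if units["unit_id"].duplicated().any():
        row = int(units.index[units["unit_id"].duplicated()][0]) + 2
        raise DataValidationError(UNITS_CSV, row, "unit_id", "duplicate unit_id")
    for i, (den, n0) in enumerate(zip(units["density"], units["n_initial"])):
        if int(n0) != int(den):
            raise DataValidationError(
                UNITS_CSV, i + 2, "n_initial",
                f"n_initial ({n0}) must equal the density level ({den})")

    unit_objs = [
        ExperimentalUnit(r.unit_id, int(r.block),
                         TreatmentCell(r.location, r.salinity, int(r.density)),
                         int(r.n_initial))
        for r in units.itertuples()
    ]
    known = set(units["unit_id"])

    growth = pd.read_csv(d / GROWTH_CSV, float_precision="round_trip")
    _require_columns(growth, ["unit_id", "day", "mean_total_length_mm"],
                     GROWTH_CSV)
    for i, uid in enumerate(growth["unit_id"]):
        if uid not in known:
            raise DataValidationError(GROWTH_CSV, i + 2, "unit_id",
                                      f"unknown unit_id {uid!r}")
    for i, day in enumerate(growth["day"]):
        if not float(day).is_integer() or day < 0:
            raise DataValidationError(GROWTH_CSV, i + 2, "day",
                                      f"day must be a non-negative integer, got {day!r}")
    growth["day"] = growth["day"].astype(int)
    if growth["mean_total_length_mm"].isna().any():
        row = int(growth.index[growth["mean_total_length_mm"].isna()][0]) + 2
        raise DataValidationError(GROWTH_CSV, row, "mean_total_length_mm",
                                  "missing length")

    meta = pd.read_csv(d / METAMORPHS_CSV, float_precision="round_trip")
    _require_columns(meta, ["unit_id", "individual_id", "survived",
                            "day_at_metamorphosis", "total_length_mm"],
                     METAMORPHS_CSV)
    for i, uid in enumerate(meta["unit_id"]):
        if uid not in known:
            raise DataValidationError(METAMORPHS_CSV, i + 2, "unit_id",
                                      f"unknown unit_id {uid!r}")
    surv = meta["survived"]
    if surv.dtype != bool:
        mapping = {"true": True, "false": False}
        vals = []
        for i, v in enumerate(surv):
            key = str(v).strip().lower()
            if key not in mapping:
                raise DataValidationError(METAMORPHS_CSV, i + 2, "survived",
                                          f"not a boolean: {v!r}")
            vals.append(mapping[key])
        meta["survived"] = vals
    for i, r in enumerate(meta.itertuples()):
        has_day = pd.notna(r.day_at_metamorphosis)
        has_len = pd.notna(r.total_length_mm)
        if r.survived and not (has_day and has_len):
            raise DataValidationError(
                METAMORPHS_CSV, i + 2, "day_at_metamorphosis",
                "survivor lacks metamorphosis day or length")
        if not r.survived and (has_day or has_len):
            raise DataValidationError(
                METAMORPHS_CSV, i + 2, "day_at_metamorphosis",
                "non-survivor carries endpoint values")
    meta["day_at_metamorphosis"] = pd.to_numeric(meta["day_at_metamorphosis"])
    meta["total_length_mm"] = pd.to_numeric(meta["total_length_mm"])

    counts = meta.groupby("unit_id").size()
    for r in units.itertuples():
        if counts.get(r.unit_id, 0) != int(r.n_initial):
            raise DataValidationError(
                METAMORPHS_CSV, None, "unit_id",
                f"unit {r.unit_id!r} has {counts.get(r.unit_id, 0)} metamorph "
                f"records, expected n_initial={r.n_initial}")

    return SyntheticDataset(units=unit_objs, growth=growth, metamorphs=meta)
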