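"""Reading and writing the package's plain-text table formats.

Native format is TSV (CSV accepted by extension). A four-vessel table has id
columns ``participant_id`` and ``vessel``; a longitudinal table has
``participant_id``, ``visit``, ``ga_weeks`` and the clinical covariates. All
remaining columns are numeric protein values; the literal string ``NA``
marks missingness.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

FOUR_VESSEL_KEYS = ["participant_id", "vessel"]
LONGITUDINAL_KEYS = ["participant_id", "visit"]
LONGITUDINAL_REQUIRED = ["participant_id", "visit", "ga_weeks"]

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "write_json",
    "config_hash",
]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(path, kind: str = "four_vessel") -> pd.DataFrame:
    """Read a protein expression table and validate its structure.

    ``kind`` is ``"four_vessel"`` (keyed by participant × vessel) or
    ``"longitudinal"`` (keyed by participant × visit, with ``ga_weeks``).
    Protein columns are coerced to float; a non-numeric protein cell or a
    duplicated key raises :class:`DataError` naming the coordinates.
    """
    path = Path(path)
    if kind == "four_vessel":
        keys, required = FOUR_VESSEL_KEYS, FOUR_VESSEL_KEYS
    elif kind == "longitudinal":
        keys, required = LONGITUDINAL_KEYS, LONGITUDINAL_REQUIRED
    else:
        raise DataError(f"unknown table kind {kind!r}")

    table = pd.read_csv(path, sep=_sep(path), na_values=["NA"], keep_default_na=True)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise DataError(f"{path.name}: missing required column(s) {missing}")

    dup = table.duplicated(subset=keys)
    if dup.any():
        key = tuple(table.loc[dup.idxmax(), keys])
        raise DataError(f"{path.name}: duplicate key {key} over columns {keys}")

    id_like = {"participant_id", "vessel", "visit", "ga_weeks",
               "age_years", "bmi", "nulliparity"}
    protein_cols = [c for c in table.columns if c not in id_like]
    for col in protein_cols:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise DataError(
                f"{path.name}: non-numeric protein value at row {row}, "
                f"column {col!r}: {table.at[row, col]!r}"
            )
        table[col] = coerced.astype(float)
    return table


def write_expression_table(table: pd.DataFrame, path) -> None:
    """Write a table as TSV (or CSV by extension) with ``NA`` for missing cells."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=_sep(path), index=False, na_rep="NA")


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
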