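"""Compound descriptor tables: data model and CSV I/O.

A :class:`CompoundRecord` holds one molecule's IAM retention descriptor,
its calculated molecular descriptors and optional reference log BCF
values (the EPI Suite estimate and, where available, the in-vivo
measurement).  A :class:`CompoundTable` is an ordered collection with
unique ids, round-trippable to CSV.

CSV dialect: comma separator, period decimal mark, UTF-8, mandatory
header.  Missing values are written as empty cells and read from empty
cells or ``NA``.  Header aliases are resolved only through an explicit
``column_map`` — no fuzzy matching, so similarly named descriptors
(``DipH`` vs ``DipS``) can never be silently confused.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import COUNT_DESCRIPTORS, DESCRIPTOR_NAMES, TABLE_COLUMNS

logger = logging.getLogger(__name__)

_NA_STRINGS = {"", "NA"}


@dataclass
class CompoundRecord:
    """One compound: retention, descriptors and reference BCF values.

    ``descriptors`` maps canonical descriptor names to values; only the
    16 registered descriptor names are accepted.  ``sum_correction_factors``
    is the ΣF_i term of the Meylan/US-EPA screening models (default 0;
    correction factors are supplied by the user, not computed here).
    """

    id: str
    name: str | None = None
    log_kw_iam: float | None = None
    descriptors: dict[str, float] = field(default_factory=dict)
    molar_volume: float | None = None
    ionic: bool | None = None
    sum_correction_factors: float = 0.0
    log_bcf_epi: float | None = None
    log_bcf_vivo: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be a non-empty string")
        for key, value in self.descriptors.items():
            if key not in DESCRIPTOR_NAMES:
                raise ValueError(
                    f"unknown descriptor {key!r}; canonical names: "
                    f"{', '.join(DESCRIPTOR_NAMES)}"
                )
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            _check_descriptor_value(self.id, key, float(value))

    def descriptor(self, key: str) -> float:
        """Return a descriptor value, raising a named error when absent."""
        value = self.descriptors.get(key)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise KeyError(f"compound {self.id!r} is missing descriptor {key!r}")
        return float(value)


def _check_descriptor_value(cid: str, key: str, value: float) -> None:
    # structural constraints are hard errors; physical-range checks on
    # Mw/TPSA happen once per table at the CSV entry point instead, so
    # simulated tables with abstract (standardised) scales stay usable
    if key == "F_Csp3" and not (0.0 <= value <= 1.0):
        raise ValueError(f"compound {cid!r}: F_Csp3 = {value} outside [0, 1]")
    if key in COUNT_DESCRIPTORS:
        if value < 0 or value != int(value):
            raise ValueError(
                f"compound {cid!r}: {key} = {value} must be a non-negative integer"
            )


@dataclass
class CompoundTable:
    """Ordered collection of :class:`CompoundRecord` with unique ids."""

    records: list[CompoundRecord]
    descriptor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        seen: set[str] = set()
        for cid in ids:
            if cid in seen:
                raise ValueError(f"duplicate compound id {cid!r}")
            seen.add(cid)
        if not self.descriptor_names:
            present: list[str] = []
            for name in DESCRIPTOR_NAMES:
                if any(name in r.descriptors for r in self.records):
                    present.append(name)
            self.descriptor_names = present

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterable[CompoundRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, name: str) -> np.ndarray:
        """A named column as a float array (NaN for missing values)."""
        out = np.full(len(self.records), np.nan)
        for i, rec in enumerate(self.records):
            if name in DESCRIPTOR_NAMES:
                value = rec.descriptors.get(name)
            elif name == "sum_F":
                value = rec.sum_correction_factors
            else:
                value = getattr(rec, name)
            if value is not None:
                out[i] = float(value)
        return out

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        """Stack named columns into an (n, p) array."""
        return np.column_stack([self.column(n) for n in names])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the full canonical column set."""
        rows = []
        for rec in self.records:
            row: dict[str, object] = {
                "id": rec.id,
                "name": rec.name,
                "log_kw_iam": rec.log_kw_iam,
                "molar_volume": rec.molar_volume,
                "ionic": rec.ionic,
                "sum_F": rec.sum_correction_factors,
                "log_bcf_epi": rec.log_bcf_epi,
                "log_bcf_vivo": rec.log_bcf_vivo,
            }
            for d in DESCRIPTOR_NAMES:
                row[d] = rec.descriptors.get(d)
            rows.append(row)
        frame = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
        return frame


def _parse_float(cell: object, *, cid: str, col: str) -> float | None:
    if cell is None:
        return None
    text = str(cell).strip()
    if text in _NA_STRINGS or text.lower() == "nan":
        return None
    try:
        return float(text)
    except ValueError:
        logger.warning(
            "compound %r: unparseable value %r in column %r treated as missing",
            cid,
            text,
            col,
        )
        return None


def _parse_bool(cell: object, *, cid: str) -> bool | None:
    if cell is None:
        return None
    text = str(cell).strip()
    if text in _NA_STRINGS or text.lower() == "nan":
        return None
    low = text.lower()
    if low in {"true", "1", "yes"}:
        return True
    if low in {"false", "0", "no"}:
        return False
    logger.warning("compound %r: unparseable ionic flag %r treated as missing", cid, text)
    return None


def read_compound_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> CompoundTable:
    """Read a compound descriptor CSV.

    Parameters
    ----------
    path
        UTF-8 CSV file with a header row containing at least an ``id``
        column.
    column_map
        Optional mapping from the file's header names to canonical
        column names, e.g. ``{"PSA": "TPSA"}``.

    Unparseable numeric cells become missing values (with a logged
    warning), never silent zeros.  Row order is preserved.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if column_map:
        unknown_targets = set(column_map.values()) - set(TABLE_COLUMNS)
        if unknown_targets:
            raise ValueError(
                f"column_map targets not in the canonical registry: "
                f"{sorted(unknown_targets)}"
            )
        frame = frame.rename(columns=dict(column_map))
    if "id" not in frame.columns:
        raise ValueError(f"{path}: header is missing the required 'id' column")

    records: list[CompoundRecord] = []
    present = [c for c in frame.columns if c in TABLE_COLUMNS]
    for _, row in frame.iterrows():
        cid = str(row["id"]).strip()
        descriptors: dict[str, float] = {}
        kwargs: dict[str, object] = {}
        for col in present:
            if col == "id":
                continue
            cell = row[col]
            if col == "name":
                text = str(cell).strip()
                kwargs["name"] = text if text not in _NA_STRINGS else None
            elif col == "ionic":
                kwargs["ionic"] = _parse_bool(cell, cid=cid)
            elif col in DESCRIPTOR_NAMES:
                value = _parse_float(cell, cid=cid, col=col)
                if value is not None:
                    descriptors[col] = value
            else:
                value = _parse_float(cell, cid=cid, col=col)
                if col == "sum_F":
                    kwargs["sum_correction_factors"] = 0.0 if value is None else value
                elif value is not None:
                    kwargs[col] = value
        records.append(CompoundRecord(id=cid, descriptors=descriptors, **kwargs))

    descriptor_names = [c for c in frame.columns if c in DESCRIPTOR_NAMES]
    table = CompoundTable(records=records, descriptor_names=descriptor_names)
    # physical-range screening, once per table
    for col, bad in (("Mw", lambda v: v <= 0), ("TPSA", lambda v: v < 0)):
        if col in descriptor_names:
            values = table.column(col)
            n_bad = int(np.sum(bad(values[~np.isnan(values)])))
            if n_bad:
                logger.warning(
                    "%s: %d record(s) with out-of-range %s", path, n_bad, col
                )
    return table


def write_compound_table(table: CompoundTable, path: str | Path) -> None:
    """Write a compound table as canonical-header CSV (missing → empty cell)."""
    frame = table.to_frame()
    # booleans as True/False text, everything else via repr-exact floats
    frame.to_csv(path, index=False, na_rep="", encoding="utf-8")
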