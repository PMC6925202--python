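"""Read, write, translate and filter SMLM localization tables.

A localization table is a :class:`pandas.DataFrame` with the canonical columns

======== ======================================================
frame    acquisition frame index (int)
x, y     emitter position in nm (float)
photons  photon count of the emission burst (float, >= 0)
uncertainty  lateral localization precision in nm (float)
channel  label / channel name (str; empty when the dialect has none)
======== ======================================================

Two on-disk dialects are supported, mirroring common vendor and open-source
exports:

* ``nstorm_txt`` — tab-separated with vendor-style headers
  (``Channel Name``, ``X``, ``Y``, ``Photons``,
  ``Lateral Localization Accuracy``, ``Frame``).
* ``thunderstorm_csv`` — comma-separated with headers
  ``frame,x [nm],y [nm],intensity [photon],uncertainty [nm]``.

Both store coordinates in nm, so translation between them is lossless for the
shared fields. Extra columns are preserved as opaque payload when a file is
round-tripped within one dialect, and dropped on translation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_COLUMNS",
    "DIALECTS",
    "Dialect",
    "LocalizationTable",
    "empty_table",
    "filter_photons",
    "read_localizations",
    "translate",
    "write_localizations",
]

#: canonical column order of an in-memory localization table
CANONICAL_COLUMNS = ["frame", "x", "y", "photons", "uncertainty", "channel"]

#: columns guaranteed lossless across dialect translation
SHARED_COLUMNS = ["frame", "x", "y", "photons", "uncertainty"]

LocalizationTable = pd.DataFrame


@dataclass(frozen=True)
class Dialect:
    """A delimited-text localization file convention.

    ``columns`` maps canonical field names to the file's header names, in the
    column order the file uses. All supported dialects store x/y in nm.
    """

    name: str
    delimiter: str
    columns: Mapping[str, str]

    @property
    def file_headers(self) -> list[str]:
        return list(self.columns.values())


DIALECTS: dict[str, Dialect] = {
    "nstorm_txt": Dialect(
        name="nstorm_txt",
        delimiter="\t",
        columns={
            "channel": "Channel Name",
            "x": "X",
            "y": "Y",
            "photons": "Photons",
            "uncertainty": "Lateral Localization Accuracy",
            "frame": "Frame",
        },
    ),
    "thunderstorm_csv": Dialect(
        name="thunderstorm_csv",
        delimiter=",",
        columns={
            "frame": "frame",
            "x": "x [nm]",
            "y": "y [nm]",
            "photons": "intensity [photon]",
            "uncertainty": "uncertainty [nm]",
        },
    ),
}


def _resolve_dialect(dialect: Union[str, Dialect]) -> Dialect:
    if isinstance(dialect, Dialect):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise ParameterError(
            f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
        ) from None


def empty_table() -> LocalizationTable:
    """An empty localization table with canonical columns."""
    return pd.DataFrame(
        {
            "frame": pd.Series(dtype=int),
            "x": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
            "photons": pd.Series(dtype=float),
            "uncertainty": pd.Series(dtype=float),
            "channel": pd.Series(dtype=str),
        }
    )


def validate_table(table: LocalizationTable) -> None:
    """Check the canonical-table invariants, raising :class:`FormatError`."""
    missing = [c for c in CANONICAL_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"localization table missing columns: {missing}")
    if len(table) == 0:
        return
    for col in ("x", "y"):
        if not np.all(np.isfinite(table[col].to_numpy(dtype=float))):
            raise FormatError(f"non-finite values in column {col!r}")
    if np.any(table["photons"].to_numpy(dtype=float) < 0):
        raise FormatError("negative photon counts")


def read_localizations(
    path: Union[str, Path], dialect: Union[str, Dialect]
) -> LocalizationTable:
    """Read a localization file into a canonical table (coordinates in nm).

    Unknown extra columns are kept verbatim after the canonical ones. An empty
    file yields an empty table; a missing required header or a malformed
    numeric cell raises :class:`FormatError` (citing the 1-based data row for
    bad cells).
    """
    d = _resolve_dialect(dialect)
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=d.delimiter, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        logger.info("read 0 localizations from %s (empty file)", path)
        return empty_table()
    raw.columns = [c.strip().strip('"') for c in raw.columns]

    missing = [h for h in d.file_headers if h not in raw.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required {d.name} column(s) {missing}"
        )

    out = pd.DataFrame(index=raw.index)
    numeric_fields = {"frame", "x", "y", "photons", "uncertainty"}
    for canonical, header in d.columns.items():
        col = raw[header]
        if canonical in numeric_fields:
            values = pd.to_numeric(col, errors="coerce")
            bad = values.isna() & col.notna() & (col.str.strip() != "")
            if bad.any():
                row = int(bad.idxmax()) + 1  # 1-based data row
                raise FormatError(
                    f"{path.name}: malformed numeric value {col[bad.idxmax()]!r} "
                    f"in column {header!r} at data row {row}"
                )
            out[canonical] = values.astype(float)
        else:
            out[canonical] = col.astype(str)
    if "channel" not in out.columns:
        out["channel"] = ""
    if len(out) and out["frame"].notna().all():
        out["frame"] = out["frame"].astype(int)
    out = out[CANONICAL_COLUMNS]

    # opaque extra payload, preserved on same-dialect round-trip
    extras = [c for c in raw.columns if c not in d.file_headers]
    for c in extras:
        out[c] = raw[c]

    validate_table(out)
    logger.info("read %d localizations from %s (%s)", len(out), path, d.name)
    return out


def write_localizations(
    table: LocalizationTable, path: Union[str, Path], dialect: Union[str, Dialect]
) -> Path:
    """Write a canonical table to ``path`` in the given dialect.

    Canonical fields are written under the dialect's headers in its column
    order; any extra (non-canonical) columns follow verbatim. An empty table
    produces a header-only file.
    """
    d = _resolve_dialect(dialect)
    path = Path(path)
    validate_table(table) if len(table) else None
    out = pd.DataFrame(index=table.index)
    for canonical, header in d.columns.items():
        if canonical in table.columns:
            out[header] = table[canonical]
        elif canonical == "channel":
            out[header] = ""
        else:
            raise FormatError(f"table lacks canonical column {canonical!r}")
    for c in table.columns:
        if c not in CANONICAL_COLUMNS:
            out[c] = table[c]
    if len(out) == 0:
        out = pd.DataFrame(columns=out.columns)
    out.to_csv(path, sep=d.delimiter, index=False)
    logger.info("wrote %d localizations to %s (%s)", len(table), path, d.name)
    return path


def translate(
    in_path: Union[str, Path],
    out_path: Union[str, Path],
    from_dialect: Union[str, Dialect],
    to_dialect: Union[str, Dialect],
) -> Path:
    """Translate a localization file between dialects (shared fields only)."""
    table = read_localizations(in_path, from_dialect)
    return write_localizations(table[CANONICAL_COLUMNS], out_path, to_dialect)


def filter_photons(
    table: LocalizationTable,
    min_photons: float = 0.0,
    max_photons: float = math.inf,
) -> LocalizationTable:
    """Keep records with ``min_photons <= photons <= max_photons``.

    The interval is closed on both ends. The number of rejected records is
    logged; row order is preserved and the operation is idempotent.
    """
    if min_photons > max_photons:
        raise ParameterError(
            f"min_photons ({min_photons}) > max_photons ({max_photons})"
        )
    p = table["photons"].to_numpy(dtype=float)
    keep = (p >= min_photons) & (p <= max_photons)
    rejected = int((~keep).sum())
    logger.info(
        "filter_photons [%g, %g]: kept %d, rejected %d",
        min_photons, max_photons, int(keep.sum()), rejected,
    )
    return table.loc[keep].copy()
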