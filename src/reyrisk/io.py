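"""Reading and writing element-concentration tables.

The in-memory concentration table is a pandas DataFrame indexed by
``sample_id`` with an optional ``type`` column (``fly`` / ``bottom``) and one
column per element symbol, all concentrations in mg/kg dry weight. Wide CSV
(``sample_id,type,La,Ce,...``) and long CSV
(``sample_id,element,concentration``) are both accepted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import DataError
from .reference_data import KNOWN_ELEMENTS

__all__ = ["read_concentrations", "write_concentrations", "element_columns",
           "check_positive"]


def element_columns(conc: pd.DataFrame) -> list[str]:
    """Columns of ``conc`` that are element symbols, in table order."""
    return [c for c in conc.columns if c in KNOWN_ELEMENTS]


def read_concentrations(path: str | Path) -> pd.DataFrame:
    """Read a wide or long concentration CSV into the standard table layout."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"sample_id", "element", "concentration"} <= cols:
        wide = df.pivot_table(
            index="sample_id", columns="element", values="concentration",
            aggfunc="first", sort=False,
        )
        wide.columns.name = None
        if "type" in cols:
            types = df.groupby("sample_id", sort=False)["type"].first()
            wide.insert(0, "type", types)
        return wide
    if "sample_id" not in cols:
        raise DataError(f"{path}: expected a 'sample_id' column")
    df = df.set_index("sample_id")
    if not element_columns(df):
        raise DataError(f"{path}: no recognised element columns")
    return df


def write_concentrations(conc: pd.DataFrame, path: str | Path) -> None:
    conc.to_csv(path, index=True, index_label="sample_id")


def check_positive(conc: pd.DataFrame, elements: Iterable[str]) -> None:
    """Raise :class:`DataError` naming the first sample/element with a
    nonpositive or missing concentration."""
    for el in elements:
        if el not in conc.columns:
            raise DataError(f"element {el!r} is missing from the table")
        col = pd.to_numeric(conc[el], errors="coerce")
        bad = col.isna() | (col <= 0)
        if bad.any():
            sample = conc.index[bad.to_numpy().nonzero()[0][0]]
            raise DataError(
                f"nonpositive or missing concentration for element {el!r} "
                f"in sample {sample!r}"
            )
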