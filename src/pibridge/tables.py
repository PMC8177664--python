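"""Tabular containers for acquisition data.

The canonical on-disk form is a long CSV with one row per injection per
analyte. In memory two views are used:

* :class:`PeakTable` — the long acquisition ledger (raw peak areas plus the
  internal-standard area of each injection, with role/batch/study metadata).
* :class:`ParTable` — a wide matrix of peak-area ratios (PAR = analyte area /
  IS area), injections as rows and analytes as columns, with an aligned
  metadata frame. All quantitative statistics in this package operate on PAR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

ROLES = (
    "system_suitability",
    "sample",
    "LQC",
    "HQC",
    "calibrator",
    "dilution",
    "population",
)

LONG_COLUMNS = (
    "injection_index",
    "sample_id",
    "role",
    "batch_id",
    "study_id",
    "analyte",
    "area",
    "is_area",
)

META_COLUMNS = (
    "injection_index",
    "sample_id",
    "role",
    "batch_id",
    "study_id",
    "nominal_dilution",
    "nominal_conc",
)


@dataclass
class PeakTable:
    """Long-format acquisition ledger.

    ``data`` has one row per (injection, analyte) with columns
    ``injection_index, sample_id, role, batch_id, study_id, analyte, area,
    is_area`` and optional ``nominal_dilution`` / ``nominal_conc``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        missing = set(LONG_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"peak table missing required columns: {sorted(missing)}")
        bad_roles = set(df["role"].unique()) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles in peak table: {sorted(bad_roles)}")
        if (df["is_area"] <= 0).any():
            raise ValueError("is_area must be strictly positive for every row")
        if (df["area"] < 0).any():
            raise ValueError("peak areas must be non-negative")
        dup = df.duplicated(subset=["study_id", "batch_id", "injection_index", "analyte"])
        if dup.any():
            raise ValueError(
                "duplicate (injection, analyte) pairs in peak table: "
                f"{df.loc[dup, ['injection_index', 'analyte']].head().to_dict('records')}"
            )

    @property
    def analytes(self) -> list[str]:
        return sorted(self.data["analyte"].unique())

    def par_table(self) -> "ParTable":
        """Pivot to the wide PAR view (area / is_area per analyte)."""
        df = self.data.copy()
        df["par"] = df["area"] / df["is_area"]
        key = ["study_id", "batch_id", "injection_index"]
        wide = df.pivot_table(index=key, columns="analyte", values="par", aggfunc="first")
        meta_cols = [c for c in META_COLUMNS if c in df.columns]
        meta = df.drop_duplicates(subset=key).set_index(key)[
            [c for c in meta_cols if c not in key]
        ]
        meta = meta.loc[wide.index].reset_index()
        wide = wide.reset_index(drop=True)
        wide.columns.name = None
        return ParTable(meta=meta, par=wide)


@dataclass
class ParTable:
    """Wide peak-area-ratio matrix with aligned injection metadata.

    ``meta`` and ``par`` share a positional RangeIndex; ``par`` columns are
    analyte names.
    """

    meta: pd.DataFrame
    par: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.meta) != len(self.par):
            raise ValueError("meta and par must have the same number of rows")
        self.meta = self.meta.reset_index(drop=True)
        self.par = self.par.reset_index(drop=True)

    @property
    def species(self) -> list[str]:
        return list(self.par.columns)

    @property
    def n_injections(self) -> int:
        return len(self.meta)

    def copy(self) -> "ParTable":
        return ParTable(meta=self.meta.copy(), par=self.par.copy())

    def subset(self, mask: np.ndarray | pd.Series) -> "ParTable":
        mask = np.asarray(mask)
        return ParTable(meta=self.meta.loc[mask].copy(), par=self.par.loc[mask].copy())

    def rows_with_role(self, *roles: str) -> "ParTable":
        return self.subset(self.meta["role"].isin(roles).to_numpy())

    def batch_ids(self) -> list[str]:
        return list(dict.fromkeys(self.meta["batch_id"]))

    def with_par(self, par: pd.DataFrame) -> "ParTable":
        return ParTable(meta=self.meta.copy(), par=par.reset_index(drop=True))


def concat_par_tables(tables: Iterable[ParTable]) -> ParTable:
    """Stack several ParTables (e.g. two studies) into one for joint fitting."""
    tables = list(tables)
    meta = pd.concat([t.meta for t in tables], ignore_index=True)
    par = pd.concat([t.par for t in tables], ignore_index=True)
    return ParTable(meta=meta, par=par)


def qc_pairs(meta: pd.DataFrame) -> pd.DataFrame:
    """Pair adjacent LQC/HQC injections within each batch.

    Returns a frame with columns ``study_id, batch_id, pair, lqc_row,
    hqc_row`` where the row values are positional indices into the table.
    QC pairs are acquired back-to-back (L then H), so pairing is by order of
    appearance within the batch.
    """
    rows = []
    for (study, batch), grp in meta.groupby(["study_id", "batch_id"], sort=False):
        grp = grp.sort_values("injection_index")
        lqc = grp.index[grp["role"] == "LQC"].tolist()
        hqc = grp.index[grp["role"] == "HQC"].tolist()
        if len(lqc) != len(hqc):
            raise ValueError(
                f"unpaired QCs in batch {batch!r}: {len(lqc)} LQC vs {len(hqc)} HQC"
            )
        for k, (lo, hi) in enumerate(zip(lqc, hqc)):
            rows.append(
                {"study_id": study, "batch_id": batch, "pair": k, "lqc_row": lo, "hqc_row": hi}
            )
    return pd.DataFrame(rows, columns=["study_id", "batch_id", "pair", "lqc_row", "hqc_row"])
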