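"""Reading, validating, filtering and writing ligand-receptor inference tables.

The on-disk contract is a delimited text table (CSV by default, UTF-8, one
header row) with one row per (source cell type, target cell type, ligand,
receptor) interaction in one biological state, carrying a mean-expression
magnitude (``lr_mean``) and two per-method p-values — the consensus output
schema of LIANA-style aggregation (CellPhoneDB-style and CellChat-style
p-values side by side).

In memory a state table is a :class:`pandas.DataFrame` with the canonical
columns below; :class:`InteractionRecord` is the row-level view.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_COLUMN_MAP

logger = logging.getLogger(__name__)

#: Canonical in-memory column order for a state table.
CANONICAL_COLUMNS = [
    "source",
    "target",
    "ligand",
    "receptor",
    "lr_mean",
    "pval_cellphone",
    "pval_cellchat",
    "state",
]

#: Columns forming the unique interaction key within one state.
KEY_COLUMNS = ["source", "target", "ligand", "receptor"]

_NUMERIC_ROLES = ["lr_mean", "pval_cellphone", "pval_cellchat"]


class SchemaError(ValueError):
    """The input table does not match the expected schema."""


@dataclass(frozen=True)
class InteractionRecord:
    """One ligand-receptor inference row for one state.

    ``ligand`` and ``receptor`` may be multi-subunit complex names
    (subunits joined by the configured separator).
    """

    source_cell_type: str
    target_cell_type: str
    ligand: str
    receptor: str
    lr_mean: float
    pval_method_a: float
    pval_method_b: float
    state_label: str


def records_to_frame(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    rows = [
        (
            r.source_cell_type,
            r.target_cell_type,
            r.ligand,
            r.receptor,
            r.lr_mean,
            r.pval_method_a,
            r.pval_method_b,
            r.state_label,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[InteractionRecord]:
    return [
        InteractionRecord(
            source_cell_type=row.source,
            target_cell_type=row.target,
            ligand=row.ligand,
            receptor=row.receptor,
            lr_mean=float(row.lr_mean),
            pval_method_a=float(row.pval_cellphone),
            pval_method_b=float(row.pval_cellchat),
            state_label=row.state,
        )
        for row in df.itertuples(index=False)
    ]


def validate_interactions(df: pd.DataFrame) -> pd.DataFrame:
    """Check value ranges of a canonical state table; returns it unchanged."""
    if (df["lr_mean"] < 0).any():
        bad = df.index[df["lr_mean"] < 0][0]
        raise SchemaError(f"negative lr_mean at row {bad}")
    for col in ("pval_cellphone", "pval_cellchat"):
        out = (df[col] < 0) | (df[col] > 1)
        if out.any():
            bad = df.index[out][0]
            raise SchemaError(f"{col} outside [0, 1] at row {bad}")
    return df


def _deduplicate(df: pd.DataFrame) -> pd.DataFrame:
    # Duplicate (source, target, ligand, receptor) keys within one state are
    # collapsed deterministically: min pval_cellphone, then min pval_cellchat,
    # then first occurrence in file order.
    n_before = len(df)
    order = np.arange(n_before)
    ranked = (
        df.assign(_order=order)
        .sort_values(
            ["pval_cellphone", "pval_cellchat", "_order"], kind="stable"
        )
        .drop_duplicates(KEY_COLUMNS, keep="first")
        .sort_values("_order", kind="stable")
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    if len(ranked) < n_before:
        logger.info(
            "collapsed %d duplicate interaction keys (kept min p-value rows)",
            n_before - len(ranked),
        )
    return ranked


def read_interaction_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    state_label: str = "",
    sep: str = ",",
) -> pd.DataFrame:
    """Read one state's ligand-receptor inference table.

    Parameters
    ----------
    path:
        Delimited text file with one header row.
    column_map:
        Schema-role -> column-name mapping; defaults to LIANA consensus
        output names (``source``, ``target``, ``ligand_complex``,
        ``receptor_complex``, ``lr_means``, ``cellphone_pvals``,
        ``cellchat_pvals``).
    state_label:
        Label recorded in the ``state`` column (e.g. ``"3m"``).
    sep:
        Field separator.

    Returns
    -------
    pandas.DataFrame
        Canonical state table (see :data:`CANONICAL_COLUMNS`), duplicate
        keys collapsed.

    Raises
    ------
    SchemaError
        A mapped column is missing (the message names the schema role), or
        a numeric field fails to parse (the message carries the file line
        number, header = line 1).
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for role, col in column_map.items():
        if col not in raw.columns:
            raise SchemaError(
                f"input table {path} lacks column '{col}' for role '{role}'"
            )
    df = pd.DataFrame(
        {role: raw[col] for role, col in column_map.items()}
    )
    for role in _NUMERIC_ROLES:
        parsed = pd.to_numeric(df[role], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            # +2: one for the header line, one for 0-based positions.
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise SchemaError(
                f"unparseable value {df[role].iloc[line - 2]!r} for role "
                f"'{role}' at line {line} of {path}"
            )
        df[role] = parsed.astype(float)
    df["state"] = state_label
    df = df[CANONICAL_COLUMNS]
    validate_interactions(df)
    df = _deduplicate(df)
    logger.info("read %d interactions from %s (state %r)", len(df), path,
                state_label)
    return df


def double_pvalue_filter(
    df: pd.DataFrame, threshold: float = 0.05
) -> pd.DataFrame:
    """Keep interactions significant under *both* inference methods.

    A row is retained iff ``pval_cellphone < threshold`` **and**
    ``pval_cellchat < threshold`` (strict inequalities, so boundary values
    are dropped).  Idempotent; the retained set does not depend on row
    order; an empty result is valid.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    keep = (df["pval_cellphone"] < threshold) & (
        df["pval_cellchat"] < threshold
    )
    out = df.loc[keep].reset_index(drop=True)
    logger.info(
        "double p-value filter (< %g): %d of %d interactions retained",
        threshold, len(out), len(df),
    )
    return out


def write_results(
    table: pd.DataFrame, path: str | Path, format: str = "csv"
) -> None:
    """Write a result table as CSV or a JSON array of row objects.

    The written file round-trips: reading it back reproduces the table
    field for field.  An empty table yields a header-only CSV or ``[]``.
    """
    path = Path(path)
    if format == "csv":
        table.to_csv(path, index=False)
    elif format == "json":
        payload = table.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path: str | Path, format: str = "csv") -> pd.DataFrame:
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path)
    if format == "json":
        return pd.DataFrame(json.loads(path.read_text(encoding="utf-8")))
    raise ValueError(f"unknown format {format!r}")
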