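"""Readers and writers for the tabular formats the pipeline touches.

Three input dialects are supported:

* two-channel microarray spot tables (TSV/CSV, one row per spot, with
  configurable column names defaulting to the GEO two-channel convention);
* plain expression matrices (genes in rows, samples in columns) with a
  companion sample-metadata table;
* the GEO series-matrix text dialect (metadata lines prefixed with ``!``,
  a delimited value block between ``!series_matrix_table_begin`` /
  ``!series_matrix_table_end`` markers) — read-only, for user-downloaded
  accession files.

Output is a tab-separated per-dataset summary table mirroring the layout of
a tumor-vs-normal diversity comparison: one row per dataset (pairing
status, PPS, Q, T, group mean diversities, P value) plus a final mean-T row.

Parsing never silently drops rows: every reader logs
``kept + rejected = total`` when it discards anything.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import (
    SPOT_COLUMNS,
    VALID_FLAGS,
    ExpressionMatrix,
    validate_spot_table,
)
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Default column-name mapping for spot tables, canonical -> file header.
#: Matches the GEO two-channel convention (CH1I_MEAN etc.).
DEFAULT_SPOT_DIALECT: dict[str, str] = {
    "spot_id": "ID",
    "gene_id": "GENE_ID",
    "ch1i_mean": "CH1I_MEAN",
    "ch1b_median": "CH1B_MEDIAN",
    "ch2i_mean": "CH2I_MEAN",
    "ch2b_median": "CH2B_MEDIAN",
    "flag": "FLAG",
}

_NUMERIC_SPOT_FIELDS = ["ch1i_mean", "ch1b_median", "ch2i_mean", "ch2b_median"]


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_two_channel_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a two-channel spot table into canonical form.

    Parameters
    ----------
    path
        TSV or CSV file with one row per spot.
    dialect
        Mapping from canonical field names (``ch1i_mean`` ...) to the column
        headers used in the file. Unspecified fields fall back to the GEO
        defaults in :data:`DEFAULT_SPOT_DIALECT`.

    Returns
    -------
    pandas.DataFrame
        Columns ``spot_id, gene_id, ch1i_mean, ch1b_median, ch2i_mean,
        ch2b_median, flag`` with flag coerced to int. Rows whose numeric
        fields do not parse are rejected and counted in the log.

    Raises
    ------
    FormatError
        If a mapped column is absent (the message names it) or a flag value
        is outside {0, -50, -100} (the message gives the row number).
    """
    path = Path(path)
    mapping = dict(DEFAULT_SPOT_DIALECT)
    if dialect:
        mapping.update(dialect)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    raw.columns = [str(c).strip() for c in raw.columns]
    for field, column in mapping.items():
        if column not in raw.columns:
            raise FormatError(
                f"{path.name}: required column {column!r} (field {field!r}) not found"
            )
    table = pd.DataFrame(
        {field: raw[column] for field, column in mapping.items()}
    )
    n_in = len(table)
    for field in _NUMERIC_SPOT_FIELDS:
        table[field] = pd.to_numeric(table[field], errors="coerce")
    flag_num = pd.to_numeric(table["flag"], errors="coerce")
    ok = table[_NUMERIC_SPOT_FIELDS].notna().all(axis=1) & flag_num.notna()
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning(
            "%s: rejected %d of %d rows with unparseable numeric fields "
            "(kept %d)", path.name, n_rejected, n_in, n_in - n_rejected
        )
    table = table[ok].copy()
    flag_num = flag_num[ok]
    bad_flag = ~flag_num.isin(list(VALID_FLAGS))
    if bad_flag.any():
        row = int(bad_flag.idxmax())
        raise FormatError(
            f"{path.name}: flag value {flag_num[row]!r} at data row {row + 1} "
            f"not in {sorted(VALID_FLAGS)}"
        )
    table["flag"] = flag_num.astype(int)
    table = table.reset_index(drop=True)[SPOT_COLUMNS]
    return validate_spot_table(table)


def read_expression_matrix(
    path: str | Path, metadata_path: str | Path
) -> ExpressionMatrix:
    """Read a genes-in-rows matrix plus its sample metadata.

    The matrix file has gene ids in the first column and one column per
    sample; empty cells become missing values (NaN). The metadata file must
    carry ``sample_id`` and ``group`` columns (``pair_id`` and
    ``source_dataset`` optional) and must describe every sample column.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    values = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values = values.apply(pd.to_numeric, errors="coerce")

    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path), dtype=str)
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise FormatError(
            f"{metadata_path.name}: metadata needs 'sample_id' and 'group' columns"
        )
    meta = meta.set_index("sample_id")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].tolist()
        raise ValidationError(f"duplicate sample_id(s) in metadata: {dups}")
    absent = [s for s in values.columns if s not in meta.index]
    if absent:
        raise ValidationError(
            f"sample(s) {absent} present in matrix but absent from metadata"
        )
    group = meta.loc[values.columns, "group"]
    pair_id = None
    if "pair_id" in meta.columns and meta["pair_id"].notna().any():
        pair_id = meta.loc[values.columns, "pair_id"]
    source = ""
    if "source_dataset" in meta.columns and meta["source_dataset"].notna().any():
        source = str(meta["source_dataset"].dropna().iloc[0])
    matrix = ExpressionMatrix(
        values=values, group=group, pair_id=pair_id, source_dataset=source
    )
    return matrix.validate()


_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def read_series_matrix(path: str | Path) -> ExpressionMatrix:
    """Parse a GEO series-matrix text file into an ExpressionMatrix.

    Only the value block is interpreted; group labels and pairing are left
    unset for the caller to supply. If any metadata line mentions a log2
    scale, the returned matrix carries ``scale_hint="log2"`` so the caller
    can apply the inverse transform.
    """
    path = Path(path)
    meta_lines: list[str] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = False
    for line in path.read_text().splitlines():
        if line.strip() == _TABLE_BEGIN:
            in_table, saw_begin = True, True
            continue
        if line.strip() == _TABLE_END:
            in_table = False
            continue
        (table_lines if in_table else meta_lines).append(line)
    if not saw_begin:
        raise FormatError(
            f"{path.name}: no {_TABLE_BEGIN!r} marker; not a series-matrix file"
        )
    if not table_lines:
        raise FormatError(f"{path.name}: empty series-matrix value block")

    def _cells(line: str) -> list[str]:
        return [c.strip().strip('"') for c in line.split("\t")]

    header = _cells(table_lines[0])
    records = [_cells(line) for line in table_lines[1:] if line.strip()]
    frame = pd.DataFrame(records, columns=header).set_index(header[0])
    frame.index = frame.index.astype(str)
    frame = frame.apply(pd.to_numeric, errors="coerce")

    scale_hint = None
    meta_blob = "\n".join(meta_lines).lower()
    if re.search(r"log2|log_2|log 2", meta_blob):
        scale_hint = "log2"
    matrix = ExpressionMatrix(values=frame, scale_hint=scale_hint)
    return matrix.validate(require_groups=False)


# ---------------------------------------------------------------------------
# summary output

#: Column order of the per-dataset summary table.
SUMMARY_COLUMNS = [
    "dataset",
    "data_structure",
    "pps_pct",
    "Q",
    "T_pct",
    "mean_normal",
    "mean_tumor",
    "p_value",
]


def write_summary_table(rows: Iterable[Mapping], path: str | Path) -> pd.DataFrame:
    """Write per-dataset summary rows plus a final mean-T row as TSV.

    Each row carries a dataset id, pairing status, PPS (or NA), the positive
    pair count Q, T (the proportion of positive pairs, percent), group mean
    diversities and the one-sided P value. The trailing ``Mean`` row holds
    the arithmetic mean of the T column. Returns the frame written.
    """
    frame = pd.DataFrame(list(rows))
    for col in SUMMARY_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    frame = frame[SUMMARY_COLUMNS]
    if len(frame):
        mean_row = {c: np.nan for c in SUMMARY_COLUMNS}
        mean_row["dataset"] = "Mean"
        mean_row["T_pct"] = float(np.mean(frame["T_pct"].astype(float)))
        frame = pd.concat([frame, pd.DataFrame([mean_row])], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")
    return frame


def read_summary_table(path: str | Path) -> pd.DataFrame:
    """Re-parse a summary TSV written by :func:`write_summary_table`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write an ExpressionMatrix (and optionally its metadata) as TSV."""
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    if metadata_path is not None:
        meta = pd.DataFrame({"sample_id": matrix.sample_ids})
        meta["group"] = matrix.group.to_numpy() if matrix.group is not None else ""
        if matrix.pair_id is not None:
            meta["pair_id"] = matrix.pair_id.to_numpy()
        if matrix.source_dataset:
            meta["source_dataset"] = matrix.source_dataset
        meta.to_csv(metadata_path, sep="\t", index=False)
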