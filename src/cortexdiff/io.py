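"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats: tab-separated expression matrices (plain TSV or the GEO
series-matrix dialect, whose comment lines start with ``!`` and whose data
table sits between ``!series_matrix_table_begin`` / ``!series_matrix_table_end``
markers), TSV sample sheets, GMT gene-set collections and TSV qPCR tables.

All tables are UTF-8, tab-separated with Unix newlines; floating-point output
uses 6 significant digits so written fixtures are stable across platforms.
Expression values are assumed to be already log2-transformed and normalised;
a heuristic warning fires when the value range suggests linear-scale input.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleSheet,
    ValidationError,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

_GEO_BEGIN = "!series_matrix_table_begin"
_GEO_END = "!series_matrix_table_end"


def _extract_table_lines(path: Path, dialect: str) -> str:
    text = Path(path).read_text(encoding="utf-8")
    if dialect == "tsv":
        return text
    if dialect != "geo":
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'geo'")
    lines: list[str] = []
    inside = False
    for line in text.splitlines():
        low = line.strip().lower()
        if low == _GEO_BEGIN:
            inside = True
            continue
        if low == _GEO_END:
            inside = False
            continue
        if line.startswith("!"):
            continue
        if inside:
            # GEO series-matrix tables quote identifiers
            lines.append(line.replace('"', ""))
    if not lines:
        raise ValidationError(
            f"no table found between {_GEO_BEGIN}/{_GEO_END} markers in {path}"
        )
    return "\n".join(lines) + "\n"


def read_expression_tsv(
    path: str | Path,
    dialect: str = "tsv",
    missing: str = "reject",
    assume_log2: bool = True,
) -> ExpressionMatrix:
    """Load an expression matrix; first column gene ids, header sample ids.

    Parameters
    ----------
    dialect:
        ``"tsv"`` for a plain table, ``"geo"`` for the GEO series-matrix
        encoding (``!``-prefixed comment lines, quoted ids, table markers).
    missing:
        ``"reject"`` (default) fails on any missing cell; ``"drop-gene"``
        removes genes with missing values and logs how many were dropped.
    assume_log2:
        When true, warn if the value range suggests linear-scale input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = _extract_table_lines(path, dialect)
    raw = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)

    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id in {path.name}: {dup!r}")

    values = raw.apply(pd.to_numeric, errors="coerce")
    coerced_na = values.isna() & raw.notna() & (raw != "")
    if coerced_na.to_numpy().any():
        gi, si = np.argwhere(coerced_na.to_numpy())[0]
        raise ValidationError(
            f"non-numeric cell in {path.name} at gene {raw.index[gi]!r}, "
            f"sample {raw.columns[si]!r}: {raw.iat[gi, si]!r}"
        )

    if values.isna().to_numpy().any():
        if missing == "reject":
            gi, si = np.argwhere(values.isna().to_numpy())[0]
            raise ValidationError(
                f"missing value in {path.name} at gene {values.index[gi]!r}, "
                f"sample {values.columns[si]!r} (missing policy 'reject')"
            )
        elif missing == "drop-gene":
            keep = ~values.isna().any(axis=1)
            logger.info("dropping %d genes with missing values", int((~keep).sum()))
            values = values.loc[keep]
        else:
            raise ValueError(f"unknown missing policy {missing!r}")

    matrix = ExpressionMatrix(values)
    if assume_log2:
        matrix.check_log2_scale()
    logger.info(
        "loaded expression matrix %s: %d genes x %d samples",
        path.name, matrix.n_genes, matrix.n_samples,
    )
    return matrix


def write_expression_tsv(
    matrix: ExpressionMatrix, path: str | Path, float_format: str = FLOAT_FORMAT
) -> None:
    df = matrix.data.copy()
    df.index.name = df.index.name or "gene_id"
    df.to_csv(path, sep="\t", float_format=float_format, lineterminator="\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Load and validate a TSV sample sheet (sample_id, group, case_id, ...)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    sheet = SampleSheet(df)
    logger.info("loaded sample sheet %s: group sizes %s", path.name, sheet.group_sizes())
    return sheet


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Load a GMT file: per line a set name, a description, then member ids."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path.name}:{lineno}: GMT line needs at least 3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValidationError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise ValidationError(f"{path.name}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Load a qPCR Ct table: sample_id, group, target, ct_target, ct_reference."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "target", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"qPCR table missing columns: {sorted(missing)}")
    for col in ("ct_target", "ct_reference"):
        ct = pd.to_numeric(df[col], errors="coerce")
        if ct.isna().any():
            raise ValidationError(f"non-numeric or missing {col} values")
        if ((ct <= 0) | (ct > 45)).any():
            raise ValidationError(f"{col} values must lie in (0, 45] cycles")
        df[col] = ct
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a results table as TSV with the package's float conventions."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")
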