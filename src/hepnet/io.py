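"""Reading and writing the pipeline's plain-text formats.

Canonical matrix format is TSV (first column gene id, header row of sample
ids); GCT 1.2 is accepted for interoperability. Gene-set collections and
two-subset prognostic signatures travel as GMT. Gene identifiers are opaque
case-sensitive strings; no symbol/accession mapping is attempted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gct",
    "read_gmt",
    "write_gmt",
]

logger = logging.getLogger(__name__)

# fixed float formatting so identical matrices serialize byte-identically
_FLOAT_FMT = "%.10g"


def read_expression_tsv(path, cohort_id: str | None = None) -> ExpressionMatrix:
    """Read a gene-by-sample TSV matrix.

    First column holds gene ids, header holds sample ids. Duplicate gene ids
    and non-numeric cells are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids: {dups}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from exc
    return ExpressionMatrix(df, cohort_id or path.stem)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> Path:
    """Write a matrix as TSV with stable float formatting (round-trip exact
    to 10 significant digits)."""
    path = Path(path)
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    return path


def read_gct(path, cohort_id: str | None = None) -> ExpressionMatrix:
    """Read a GCT 1.2 file (2-line header, Name/Description columns)."""
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ValueError(f"{path}: expected GCT 1.2 header, got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ValueError(f"{path}: malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t")
    if body.shape[0] != n_rows or body.shape[1] - 2 != n_cols:
        raise ValueError(
            f"{path}: declared dimensions {n_rows}x{n_cols} do not match body "
            f"{body.shape[0]}x{body.shape[1] - 2}"
        )
    name_col = body.columns[0]
    body[name_col] = body[name_col].astype(str)
    if body[name_col].duplicated().any():
        dups = body.loc[body[name_col].duplicated(), name_col].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids: {dups}")
    df = body.set_index(name_col).drop(columns=[body.columns[1]])
    df.index.name = None
    df.columns = df.columns.astype(str)
    df = df.astype(float)
    return ExpressionMatrix(df, cohort_id or path.stem)


def write_gct(matrix: ExpressionMatrix, path, description: str = "na") -> Path:
    path = Path(path)
    df = matrix.values
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        out = df.copy()
        out.insert(0, "Description", description)
        out.index.name = "Name"
        out.to_csv(fh, sep="\t", float_format=_FLOAT_FMT)
    return path


def read_gmt(path) -> list[tuple[str, str, list[str]]]:
    """Read a GMT gene-set collection.

    Returns (name, description, members) triples in file order. Duplicated
    members within a set are dropped (order-preserving) with a logged count;
    a line with fewer than three fields is an error; an empty file yields an
    empty list.
    """
    path = Path(path)
    sets: list[tuple[str, str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            members = [g for g in fields[2:] if g]
            seen: dict[str, None] = {}
            for g in members:
                seen.setdefault(g, None)
            deduped = list(seen)
            if len(deduped) < len(members):
                logger.warning(
                    "GMT set %s: dropped %d duplicated member(s)",
                    name,
                    len(members) - len(deduped),
                )
            sets.append((name, desc, deduped))
    return sets


def write_gmt(sets, path) -> Path:
    """Write (name, description, members) triples as GMT."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, desc, members in sets:
            fh.write("\t".join([name, desc, *members]) + "\n")
    return path
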