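"""Readers and writers for the standard input formats.

Dependency and expression matrices travel as CSV/TSV with a header row of
cell-line identifiers and gene symbols in the first column (a transposed
orientation is available via ``genes_in_rows=False``). Gene sets use the
MSigDB GMT dialect. Corpus annotations are gene2pubmed-style TSV with
``publication_id`` and ``gene_id`` columns.
"""

from __future__ import annotations

import csv
import logging
import os

import numpy as np
import pandas as pd

from .containers import (
    CorpusAnnotation,
    DependencyMatrix,
    ExpressionMatrix,
    GeneSetCollection,
)

logger = logging.getLogger(__name__)

#: Accepted missing-value sentinels (case-insensitive) on read.
MISSING_SENTINELS = {"", "na", "nan"}


def _infer_delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if os.fspath(path).lower().endswith((".tsv", ".txt")) else ","


def _parse_cell(raw: str, path: str, line_no: int) -> float:
    if raw.strip().lower() in MISSING_SENTINELS:
        return np.nan
    try:
        return float(raw)
    except ValueError as exc:
        raise ValueError(
            f"{path}:{line_no}: cannot parse value {raw!r} as a number"
        ) from exc


def _read_matrix_frame(
    path: str, delimiter: str | None, genes_in_rows: bool
) -> pd.DataFrame:
    delim = _infer_delimiter(path, delimiter)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        columns = header[1:]
        width = len(header)
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width:
                raise ValueError(
                    f"{path}:{line_no}: ragged row with {len(row)} fields, "
                    f"expected {width}"
                )
            row_ids.append(row[0])
            rows.append([_parse_cell(v, path, line_no) for v in row[1:]])
    frame = pd.DataFrame(rows, columns=columns)
    frame.index = row_ids
    if not genes_in_rows:
        frame = frame.T
    return frame


def read_dependency_matrix(
    path: str,
    delimiter: str | None = None,
    genes_in_rows: bool = True,
    provenance: str | None = None,
) -> DependencyMatrix:
    """Read a gene × cell-line dependency-score matrix from CSV/TSV.

    Empty fields, ``NA`` and ``NaN`` (case-insensitive) parse as missing.
    Row and column order are preserved from the file. Duplicate gene
    symbols and ragged rows are hard errors.
    """
    frame = _read_matrix_frame(path, delimiter, genes_in_rows)
    return DependencyMatrix(frame, provenance=provenance or os.fspath(path))


def read_expression_matrix(
    path: str, delimiter: str | None = None, genes_in_rows: bool = True
) -> ExpressionMatrix:
    """Read a gene × cell-line non-negative expression matrix from CSV/TSV."""
    return ExpressionMatrix(_read_matrix_frame(path, delimiter, genes_in_rows))


def write_matrix(
    matrix: DependencyMatrix | ExpressionMatrix,
    path: str,
    delimiter: str | None = None,
) -> None:
    """Write a matrix back to CSV/TSV; missing entries become empty fields."""
    delim = _infer_delimiter(path, delimiter)
    matrix.data.to_csv(path, sep=delim, na_rep="")


def read_gmt(path: str, source_label: str | None = None) -> GeneSetCollection:
    """Read an MSigDB-style GMT gene-set file.

    Each tab-separated line is ``name<TAB>description<TAB>gene...``.
    Duplicate genes within a line are dropped with a warning; a line with
    fewer than three fields or a repeated pathway name is a hard error.
    """
    collection = GeneSetCollection(source_label=source_label or os.fspath(path))
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{line_no}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, gene...)"
                )
            name, description = fields[0], fields[1]
            genes: list[str] = []
            seen: set[str] = set()
            dupes = False
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dupes = True
                    continue
                seen.add(g)
                genes.append(g)
            if dupes:
                logger.warning(
                    "%s:%d: duplicate genes within set %r deduplicated",
                    path,
                    line_no,
                    name,
                )
            if name in collection:
                raise ValueError(f"{path}:{line_no}: duplicate pathway name {name!r}")
            collection.add(name, description, genes)
    return collection


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            genes = collection.genes(name)
            fh.write("\t".join([name, collection.description(name), *genes]) + "\n")


def read_corpus_annotation(path: str) -> CorpusAnnotation:
    """Read a gene2pubmed-style TSV of publication–gene links.

    Requires ``publication_id`` and ``gene_id`` columns (extra columns are
    ignored); duplicate (publication, gene) rows collapse to one membership.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("publication_id", "gene_id"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    memberships: dict[str, set[str]] = {}
    for pub, gene in zip(frame["publication_id"], frame["gene_id"]):
        memberships.setdefault(pub, set()).add(gene)
    return CorpusAnnotation(memberships)


def write_corpus_annotation(corpus: CorpusAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("publication_id\tgene_id\n")
        for pub in corpus.memberships:
            for gene in sorted(corpus.memberships[pub]):
                fh.write(f"{pub}\t{gene}\n")
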