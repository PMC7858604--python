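"""Readers and writers for the plain-text formats used by the pipeline.

Formats: methylome matrix TSV (first column ``probe_id``, remaining columns
sample ids), sample sheet CSV, probe annotation TSV
(``probe_id, chr, pos_1based, gene_symbols``), GMT gene-set libraries, and
JSON records.  All writers round-trip losslessly through their readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError
from .pathways import GeneSetLibrary, normalize_symbol

SAMPLE_COLUMNS = ("sample_id", "subject", "group", "period")
ANNOTATION_COLUMNS = ("probe_id", "chr", "pos_1based", "gene_symbols")

_GROUP_ALIASES = {"swd": "swd", "case": "swd", "cases": "swd",
                  "control": "control", "controls": "control", "ctrl": "control"}
_PERIOD_ALIASES = {"work": "work", "working": "work",
                   "vacation": "vacation", "vac": "vacation"}


def _check_nonempty(path: Path) -> None:
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: file is empty")


def read_matrix(path) -> pd.DataFrame:
    """Read a probes x samples TSV matrix; validates shape and unique ids."""
    path = Path(path)
    _check_nonempty(path)
    n_fields = None
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            count = line.rstrip("\n").count("\t") + 1
            if n_fields is None:
                n_fields = count
            elif count != n_fields:
                raise FormatError(
                    f"{path}: line {lineno} has {count} fields, expected {n_fields}")
    try:
        matrix = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()][0]
        line = int(np.nonzero(matrix.index.duplicated())[0][0]) + 2  # + header
        raise FormatError(f"{path}: duplicate probe id {dup!r} at line {line}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "probe_id"
    matrix.columns = matrix.columns.astype(str)
    return matrix.astype(float)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    path = Path(path)
    out = matrix.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_samples(path) -> pd.DataFrame:
    """Read and validate a sample sheet CSV (normalizes group/period labels)."""
    path = Path(path)
    _check_nonempty(path)
    try:
        sheet = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for column in SAMPLE_COLUMNS:
        if column not in sheet.columns:
            raise SchemaError(f"{path}: missing required column {column!r}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate sample_id {dup!r}")

    def _normalize(column: str, aliases: dict) -> None:
        values = sheet[column].astype(str).str.strip().str.lower()
        unknown = sorted(set(values) - set(aliases))
        if unknown:
            raise SchemaError(f"{path}: invalid {column} values {unknown}")
        sheet[column] = values.map(aliases)

    _normalize("group", _GROUP_ALIASES)
    _normalize("period", _PERIOD_ALIASES)
    return sheet


def write_samples(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def read_annotation(path) -> pd.DataFrame:
    """Read a probe annotation TSV (header optional, 4 columns).

    Columns: ``probe_id, chr, pos_1based, gene_symbols`` with semicolon-
    joined symbols (empty allowed).  Symbols are case-normalized.
    """
    path = Path(path)
    _check_nonempty(path)
    with path.open() as handle:
        first = handle.readline()
    has_header = first.split("\t")[0].strip() == "probe_id"
    try:
        table = pd.read_csv(
            path, sep="\t",
            header=0 if has_header else None,
            names=None if has_header else list(ANNOTATION_COLUMNS),
            dtype={"chr": str},
            keep_default_na=False,
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for column in ANNOTATION_COLUMNS:
        if column not in table.columns:
            raise SchemaError(f"{path}: missing required column {column!r}")
    if table["probe_id"].duplicated().any():
        dup = table.loc[table["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate probe id {dup!r}")
    pos = pd.to_numeric(table["pos_1based"], errors="coerce")
    if pos.isna().any() or (pos <= 0).any():
        raise SchemaError(f"{path}: pos_1based must be positive integers")
    table["pos_1based"] = pos.astype(int)
    table["gene_symbols"] = [
        ";".join(normalize_symbol(s) for s in str(x).split(";") if s.strip())
        for x in table["gene_symbols"]
    ]
    return table[list(ANNOTATION_COLUMNS)]


def write_annotation(table: pd.DataFrame, path) -> None:
    table[list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetLibrary:
    """Read a GMT library: ``name<TAB>description<TAB>gene...`` per line."""
    path = Path(path)
    _check_nonempty(path)
    sets: dict = {}
    descriptions: dict = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "need name, description and at least one gene")
            name = fields[0].strip()
            if name in sets:
                raise FormatError(f"{path}: duplicate term {name!r} at line {lineno}")
            genes = [g for g in fields[2:] if g.strip()]
            if not genes:
                raise FormatError(f"{path}: term {name!r} at line {lineno} has no genes")
            sets[name] = genes
            descriptions[name] = fields[1]
    return GeneSetLibrary.from_dict(sets, descriptions)


def write_gmt(library: GeneSetLibrary, path) -> None:
    with Path(path).open("w") as handle:
        for term in library.terms:
            description = library.descriptions.get(term, "")
            genes = "\t".join(library.sets[term])
            handle.write(f"{term}\t{description}\t{genes}\n")


def write_json(payload: dict, path) -> None:
    with Path(path).open("w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_json(path) -> dict:
    with Path(path).open() as handle:
        return json.load(handle)
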