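"""Readers and writers for the pipeline's tabular inputs and outputs.

All tables are UTF-8 tab-separated with a mandatory header row; column order
is free on input and fixed on output.  Gene/protein identity throughout the
package is the *normalized symbol*: uppercased, whitespace-trimmed.  Interval
columns (gene coordinates, linkage regions) use 0-based half-open coordinates.
Fluid proteome lists are plain text, one identifier per line.

Each schema declares its columns, per-cell parsers and row/table invariants;
:func:`read_table` returns a validated :class:`pandas.DataFrame` and raises
:class:`SchemaError`, :class:`RowError` or :class:`DuplicateKeyError` with
enough context (column name, line number, offending key) to fix the file.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd

__all__ = [
    "LOCUS_TYPES",
    "COMPARTMENTS",
    "SchemaError",
    "RowError",
    "DuplicateKeyError",
    "normalize_symbol",
    "read_table",
    "read_id_list",
    "write_id_list",
    "write_table",
    "apply_symbol_mapping",
    "SCHEMAS",
]

#: Controlled vocabulary for gene locus types.
LOCUS_TYPES = frozenset(
    {
        "protein_coding",
        "pseudogene",
        "ncRNA",
        "antisense",
        "microRNA",
        "orf",
        "hypothetical",
        "uncharacterized",
        "withdrawn",
        "other",
    }
)

#: The eight subcellular compartments used for network layering.
COMPARTMENTS = (
    "plasma_membrane",
    "extracellular",
    "endoplasmic_reticulum",
    "golgi",
    "lysosome",
    "mitochondria",
    "cytoplasm",
    "nucleus",
)


class SchemaError(ValueError):
    """The file's header does not match the requested schema."""


class RowError(ValueError):
    """A cell failed validation; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class DuplicateKeyError(ValueError):
    """A key that must be unique occurred more than once."""


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace and uppercase.

    Idempotent: ``normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)``.
    """
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# cell parsers


def _parse_str(value: str) -> str:
    return str(value).strip()


def _parse_symbol(value: str) -> str:
    out = normalize_symbol(value)
    return out


def _parse_int(value: str) -> int:
    return int(str(value).strip())


def _parse_float(value: str) -> float:
    out = float(str(value).strip())
    if math.isnan(out):
        raise ValueError("NaN not allowed")
    return out


def _parse_optional_float(value: str):
    text = str(value).strip()
    if text in ("", "NA", "nan", "None", "."):
        return None
    return float(text)


@dataclasses.dataclass(frozen=True)
class Schema:
    name: str
    columns: tuple  # (column, parser) pairs in canonical order
    optional: frozenset = frozenset()
    row_check: Callable | None = None
    table_check: Callable | None = None

    @property
    def column_names(self) -> tuple:
        return tuple(c for c, _ in self.columns)


# ---------------------------------------------------------------------------
# row/table invariants


def _check_gene_metadata_row(row: dict) -> None:
    if not row["symbol"]:
        raise ValueError("empty gene symbol")
    if row["locus_type"] not in LOCUS_TYPES:
        raise ValueError(
            f"unknown locus_type {row['locus_type']!r}; expected one of "
            + ", ".join(sorted(LOCUS_TYPES))
        )
    if row["status"] not in ("active", "withdrawn"):
        raise ValueError(f"status must be active|withdrawn, got {row['status']!r}")


def _check_gene_metadata_table(df: pd.DataFrame) -> None:
    dup = df["symbol"][df["symbol"].duplicated()]
    if len(dup):
        raise DuplicateKeyError(f"duplicate gene symbol(s): {sorted(set(dup))}")


def _check_interval_row(row: dict) -> None:
    if row["start_bp"] >= row["end_bp"]:
        raise ValueError(
            f"interval start_bp {row['start_bp']} must be < end_bp {row['end_bp']}"
        )


def _check_linkage_row(row: dict) -> None:
    _check_interval_row(row)
    if row["lod"] is None and row["p_value"] is None:
        raise ValueError("linkage region needs at least one of lod, p_value")
    if row["p_value"] is not None and not (0.0 < row["p_value"] <= 1.0):
        raise ValueError(f"p_value {row['p_value']} outside (0, 1]")


def _check_probe_row(row: dict) -> None:
    if row["fold_change"] <= 0:
        raise ValueError(f"fold_change must be > 0, got {row['fold_change']}")
    if not (0.0 <= row["adjusted_p"] <= 1.0):
        raise ValueError(f"adjusted_p {row['adjusted_p']} outside [0, 1]")
    if row["variance"] < 0:
        raise ValueError(f"variance must be >= 0, got {row['variance']}")


def _check_probe_table(df: pd.DataFrame) -> None:
    key = df[["probe_id", "region"]]
    dup = key[key.duplicated()]
    if len(dup):
        pairs = sorted(set(map(tuple, dup.itertuples(index=False))))
        raise DuplicateKeyError(f"duplicate (probe_id, region) pair(s): {pairs}")


def _check_edge_row(row: dict) -> None:
    if row["evidence_count"] < 1:
        raise ValueError(f"evidence_count must be >= 1, got {row['evidence_count']}")


def _check_edge_table(df: pd.DataFrame) -> None:
    seen = {}
    for i, (a, b) in enumerate(zip(df["protein_a"], df["protein_b"])):
        key = (a, b) if a <= b else (b, a)
        if key in seen:
            raise DuplicateKeyError(
                f"duplicate unordered pair {key} (rows {seen[key] + 1} and {i + 1})"
            )
        seen[key] = i


def _check_snp_row(row: dict) -> None:
    if not (0.0 <= row["weighted_p"] <= 1.0):
        raise ValueError(f"weighted_p {row['weighted_p']} outside [0, 1]")


def _parse_symbol_allow_empty(value: str) -> str:
    return normalize_symbol(value)


SCHEMAS: dict[str, Schema] = {
    s.name: s
    for s in (
        Schema(
            "gene_metadata",
            (
                ("symbol", _parse_symbol),
                ("hgnc_id", _parse_str),
                ("locus_type", _parse_str),
                ("chromosome_band", _parse_str),
                ("status", _parse_str),
            ),
            optional=frozenset({"hgnc_id"}),
            row_check=_check_gene_metadata_row,
            table_check=_check_gene_metadata_table,
        ),
        Schema(
            "gene_coords",
            (
                ("chromosome", _parse_str),
                ("start_bp", _parse_int),
                ("end_bp", _parse_int),
                ("symbol", _parse_symbol),
            ),
            row_check=_check_interval_row,
        ),
        Schema(
            "linkage_regions",
            (
                ("chromosome", _parse_str),
                ("start_bp", _parse_int),
                ("end_bp", _parse_int),
                ("lod", _parse_optional_float),
                ("p_value", _parse_optional_float),
            ),
            row_check=_check_linkage_row,
        ),
        Schema(
            "gene_scores",
            (("symbol", _parse_symbol), ("score", _parse_float)),
            table_check=_check_gene_metadata_table,
        ),
        Schema(
            "snp_assoc",
            (
                ("snp_id", _parse_str),
                ("symbol", _parse_symbol_allow_empty),
                ("weighted_p", _parse_float),
            ),
            row_check=_check_snp_row,
        ),
        Schema(
            "expression_probes",
            (
                ("probe_id", _parse_str),
                ("symbol", _parse_symbol),
                ("fold_change", _parse_float),
                ("adjusted_p", _parse_float),
                ("variance", _parse_float),
                ("region", _parse_str),
            ),
            row_check=_check_probe_row,
            table_check=_check_probe_table,
        ),
        Schema(
            "edges",
            (
                ("protein_a", _parse_symbol),
                ("protein_b", _parse_symbol),
                ("evidence_count", _parse_int),
            ),
            row_check=_check_edge_row,
            table_check=_check_edge_table,
        ),
        Schema(
            "localization",
            (("protein", _parse_symbol), ("compartment", _parse_str)),
        ),
        Schema(
            "annotations",
            (
                ("term_id", _parse_str),
                ("term_name", _parse_str),
                ("namespace", _parse_str),
                ("symbol", _parse_symbol),
            ),
        ),
        Schema(
            "symbol_mapping",
            (("alias", _parse_symbol), ("symbol", _parse_symbol)),
        ),
    )
}


def read_table(path, schema: str, *, log2_fold_change: bool = False) -> pd.DataFrame:
    """Read and validate a TSV table against a named schema.

    Parameters
    ----------
    path
        TSV file with a header row; column order is irrelevant, extra columns
        are rejected only if a required column is missing.
    schema
        One of ``SCHEMAS`` (e.g. ``"edges"``, ``"expression_probes"``).
    log2_fold_change
        For ``expression_probes``: declare the ``fold_change`` column is on
        the log2 scale and convert to linear fold change on load.

    Returns
    -------
    pandas.DataFrame
        Columns in the schema's canonical order, one validated row per input
        row, input row order preserved, symbols normalized.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    sch = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty file, expected a header row")
    header = lines[0].split("\t")
    positions = {}
    for col, _ in sch.columns:
        if col in header:
            positions[col] = header.index(col)
        elif col not in sch.optional:
            raise SchemaError(f"{path}: missing required column {col!r}")

    records: list[dict] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if raw == "":
            continue
        cells = raw.split("\t")
        row: dict = {}
        for col, parser in sch.columns:
            if col not in positions:
                row[col] = None
                continue
            idx = positions[col]
            cell = cells[idx] if idx < len(cells) else ""
            try:
                row[col] = parser(cell)
            except (ValueError, TypeError) as exc:
                raise RowError(f"column {col!r}: cannot parse {cell!r} ({exc})", lineno)
        if log2_fold_change and schema == "expression_probes":
            row["fold_change"] = float(2.0 ** row["fold_change"])
        if sch.row_check is not None:
            try:
                sch.row_check(row)
            except DuplicateKeyError:
                raise
            except ValueError as exc:
                raise RowError(str(exc), lineno)
        records.append(row)

    df = pd.DataFrame.from_records(records, columns=sch.column_names)
    if sch.table_check is not None:
        sch.table_check(df)
    return df


def read_id_list(path) -> set:
    """Read a one-identifier-per-line file into a set of normalized symbols."""
    path = Path(path)
    out = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        sym = normalize_symbol(line)
        if sym:
            out.add(sym)
    return out


def write_id_list(ids: Iterable[str], path) -> None:
    Path(path).write_text(
        "".join(f"{i}\n" for i in sorted(ids)), encoding="utf-8"
    )


def apply_symbol_mapping(df: pd.DataFrame, mapping: pd.DataFrame,
                         column: str = "symbol") -> pd.DataFrame:
    """Rewrite a symbol column through an alias->symbol mapping table.

    Applied before any join so that all tables share one identifier space.
    Symbols without an alias entry pass through unchanged.
    """
    lut = dict(zip(mapping["alias"], mapping["symbol"]))
    out = df.copy()
    out[column] = [lut.get(s, s) for s in out[column]]
    return out


def write_table(obj, path) -> None:
    """Write a pipeline product (or plain DataFrame) as a deterministic TSV.

    Products expose ``to_frame()``; frames are written with the canonical
    column order and the product's own deterministic row order, so repeated
    runs produce byte-identical files and ``read_table`` round-trips them.
    """
    frame = obj.to_frame() if hasattr(obj, "to_frame") else obj
    if not isinstance(frame, pd.DataFrame):
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
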