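"""TSV input/output.

All tables are UTF-8 tab-separated with a header row.  Writers emit a
deterministic column order, fixed 6-significant-digit floats, and a
leading block of ``#`` comment lines recording the package version, the
parameters of the producing command and SHA-256 checksums of its inputs.
Readers skip ``#`` lines, so every emitted file round-trips.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    CONTROL_NONCUTTING,
    TARGETING,
    CountMatrix,
    DataValidationError,
    LibraryMap,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_library",
    "write_library",
    "read_expression",
    "write_expression",
    "read_table",
    "write_table",
    "file_sha256",
    "provenance_header",
]

FLOAT_FORMAT = "%.6g"


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def provenance_header(params: dict | None = None, inputs: dict | None = None) -> list[str]:
    """Comment lines recording version, parameters and input checksums."""
    lines = [f"# nutriscreen {__version__}"]
    for key, val in (params or {}).items():
        lines.append(f"# param {key}={val}")
    for name, path in (inputs or {}).items():
        if path is not None and Path(path).exists():
            lines.append(f"# input {name}={path} sha256={file_sha256(path)}")
    return lines


def write_table(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None,
                index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines or []:
            fh.write(line.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sidecar sample sheet: sample_id, condition, replicate, day, role."""
    df = read_table(path)
    required = {"sample_id", "condition", "replicate", "day", "role"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"sample sheet {path} missing columns: {sorted(missing)}")
    df = df.set_index("sample_id")
    df["condition"] = df["condition"].astype(str)
    df["role"] = df["role"].astype(str)
    df["replicate"] = df["replicate"].astype(int)
    df["day"] = df["day"].astype(float)
    return df


def write_sample_sheet(meta: pd.DataFrame, path: str | Path,
                       header_lines: list[str] | None = None) -> None:
    out = meta.reset_index()
    out = out.rename(columns={out.columns[0]: "sample_id"})
    write_table(out[["sample_id", "condition", "replicate", "day", "role"]], path, header_lines)


def read_counts(path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Load an element×sample count TSV plus its sidecar sample sheet.

    The first column must be ``element_id``; every body cell must be a
    nonnegative integer.  Offending cells are named in the error.
    """
    df = read_table(path)
    if df.columns[0] != "element_id":
        raise DataValidationError(f"{path}: first column must be 'element_id', got {df.columns[0]!r}")
    df = df.set_index("element_id")
    meta = read_sample_sheet(samples_path)
    try:
        return CountMatrix(counts=df, sample_meta=meta)
    except DataValidationError as err:
        raise DataValidationError(f"{path}: {err}") from err


def write_counts(m: CountMatrix, path: str | Path, samples_path: str | Path | None = None,
                 header_lines: list[str] | None = None) -> None:
    out = m.counts.reset_index()
    out = out.rename(columns={out.columns[0]: "element_id"})
    write_table(out, path, header_lines)
    if samples_path is not None:
        write_sample_sheet(m.sample_meta, samples_path, header_lines)


def read_library(path: str | Path) -> LibraryMap:
    """Library TSV with columns element_id, gene, class."""
    df = read_table(path)
    cols = {"element_id", "gene"}
    if not cols <= set(df.columns):
        raise DataValidationError(f"library {path} missing columns: {sorted(cols - set(df.columns))}")
    class_col = "class" if "class" in df.columns else "element_class"
    if class_col not in df.columns:
        raise DataValidationError(f"library {path} missing a 'class' column")
    table = df.set_index("element_id")[["gene", class_col]].rename(columns={class_col: "element_class"})
    return LibraryMap(table=table)


def write_library(lib: LibraryMap, path: str | Path, header_lines: list[str] | None = None) -> None:
    out = lib.table.reset_index()
    out = out.rename(columns={out.columns[0]: "element_id", "element_class": "class"})
    write_table(out[["element_id", "gene", "class"]], path, header_lines)


def read_expression(path: str | Path) -> pd.Series:
    """Expression TSV (gene, log2_fpkm) -> Series of finite values.

    Non-finite entries are treated as missing and dropped.
    """
    df = read_table(path)
    if not {"gene", "log2_fpkm"} <= set(df.columns):
        raise DataValidationError(f"expression table {path} needs columns gene, log2_fpkm")
    expr = df.set_index("gene")["log2_fpkm"].astype(float)
    return expr[np.isfinite(expr)]


def write_expression(expr: pd.Series, path: str | Path,
                     header_lines: list[str] | None = None) -> None:
    out = expr.rename("log2_fpkm").rename_axis("gene").reset_index()
    write_table(out, path, header_lines)


def make_library_table(genes: list[str], elements_per_gene: int,
                       control_groups: dict[str, list[str]] | None = None) -> LibraryMap:
    """Assemble a LibraryMap from gene names and optional control groups."""
    rows = []
    for g in genes:
        for i in range(elements_per_gene):
            rows.append((f"{g}_sg{i + 1}", g, TARGETING))
    for group, elems in (control_groups or {}).items():
        for e in elems:
            rows.append((e, group, CONTROL_NONCUTTING))
    table = pd.DataFrame(rows, columns=["element_id", "gene", "element_class"]).set_index("element_id")
    return LibraryMap(table=table)
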