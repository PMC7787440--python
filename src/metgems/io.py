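"""Tab-separated table reading and writing shared by every subcommand.

The canonical dialect is plain TSV: an optional block of ``#``-prefixed
metadata lines (``# key=value`` tokens), a header row whose first cell names
the row-id column (a leading ``#`` on it is tolerated, as in QIIME/BIOM TSV
exports), then one row per entity.  Floats are written with 7 significant
digits, which bounds the write-read round-trip error at 5e-7 relative.
"""

from __future__ import annotations

import logging
import os
from typing import Mapping

import pandas as pd

log = logging.getLogger(__name__)

# 7 significant digits: bounds the write-read round-trip error at 5e-7 relative
FLOAT_FORMAT = "%.7g"


class TableFormatError(ValueError):
    """Raised for ragged rows, non-numeric cells, or duplicate row ids."""


def _parse_meta(line: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for token in line.lstrip("#").split():
        if "=" in token:
            key, _, value = token.partition("=")
            meta[key] = value
    return meta


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a labeled numeric matrix from TSV.

    Returns a DataFrame whose index holds the first column.  Metadata parsed
    from leading ``# key=value`` comment lines is attached as
    ``df.attrs["meta"]``.  A first line of ``# Constructed from biom file``
    (BIOM TSV export) is skipped.

    Raises
    ------
    TableFormatError
        On ragged rows or non-numeric cells (with the offending line
        number), or on duplicate row ids (with the offending id).
    """
    header: list[str] | None = None
    meta: dict[str, str] = {}
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if header is None and line.startswith("#"):
                # '#ID<TAB>...' is a header; '# ...' or tab-free lines are metadata
                if "\t" in line and not line.startswith("# "):
                    header = line.split("\t")
                    header[0] = header[0].lstrip("#") or "id"
                else:
                    meta.update(_parse_meta(line))
                continue
            if header is None:
                header = line.split("\t")
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise TableFormatError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            try:
                values = [float(v) if v != "" else 0.0 for v in fields[1:]]
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}: line {lineno}: non-numeric cell ({exc})"
                ) from None
            ids.append(fields[0])
            rows.append(values)
    if header is None:
        raise TableFormatError(f"{path}: empty file (no header)")
    seen: set[str] = set()
    for rid in ids:
        if rid in seen:
            raise TableFormatError(f"{path}: duplicate row id {rid!r}")
        seen.add(rid)
    df = pd.DataFrame(rows, index=pd.Index(ids, name=header[0]), columns=header[1:])
    df.attrs["meta"] = meta
    return df


def write_table(
    df: pd.DataFrame,
    path: str | os.PathLike,
    *,
    index_name: str | None = None,
    meta: Mapping[str, object] | None = None,
    float_format: str = FLOAT_FORMAT,
) -> None:
    """Write a labeled matrix to TSV in the canonical dialect.

    ``meta`` is emitted as a single ``# key=value ...`` line before the
    header so that :func:`read_table` round-trips it.
    """
    name = index_name or (df.index.name if df.index.name else "ID")
    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        fh.write("\t".join([str(name)] + [str(c) for c in df.columns]) + "\n")
        for rid, row in df.iterrows():
            cells = [str(rid)]
            for v in row.to_numpy():
                if isinstance(v, str):
                    cells.append(v)
                elif float(v) == int(v) and abs(float(v)) < 1e15:
                    cells.append(str(int(v)))
                else:
                    cells.append(float_format % v)
            fh.write("\t".join(cells) + "\n")


def read_two_column(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a headerless 2+ column TSV as (first, second) string pairs.

    A header line is skipped if its first cell starts with ``#`` or equals a
    common id-column name.  Used for taxonomy maps, route catalogs and
    design tables.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise TableFormatError(
                    f"{path}: line {lineno}: expected >= 2 tab-separated fields"
                )
            pairs.append((fields[0], fields[1]))
    return pairs
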