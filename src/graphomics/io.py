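"""Delimited-text readers and writers.

All on-disk formats are plain TSV so that simulated cohorts round-trip
through the graph-construction loaders:

* expression matrix — features in rows; first column ``feature_id``,
  remaining columns one per sample (header row = sample ids);
* association table — two id columns whose header names the source and
  target node types (e.g. ``mirna<TAB>mrna``);
* labels — two columns, ``sample_id<TAB>label``.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import InputError, ParseError

SEP = "\t"


def write_matrix(path: str | os.PathLike, layer: str, data: pd.DataFrame) -> None:
    """Write a features x samples DataFrame as TSV with a ``feature_id`` index column."""
    out = data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep=SEP, float_format="%.12g")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a features x samples matrix written by :func:`write_matrix`."""
    try:
        df = pd.read_csv(path, sep=SEP, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas raises many subclasses
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate feature id {dup!r}")
    bad = df.columns[~df.apply(lambda c: np.issubdtype(c.dtype, np.number))]
    if len(bad):
        # locate the first offending cell for a line-numbered message
        col = bad[0]
        for i, v in enumerate(df[col]):
            if not isinstance(v, (int, float, np.number)):
                raise ParseError(
                    f"{path}: non-numeric value {v!r} in column {col!r}, line {i + 2}"
                )
        raise ParseError(f"{path}: non-numeric column {col!r}")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return df


def write_edge_table(
    path: str | os.PathLike,
    source_type: str,
    target_type: str,
    pairs: list[tuple[str, str]],
) -> None:
    with open(path, "w") as fh:
        fh.write(f"{source_type}{SEP}{target_type}\n")
        for s, t in pairs:
            fh.write(f"{s}{SEP}{t}\n")


def read_edge_table(path: str | os.PathLike) -> tuple[str, str, list[tuple[str, str]]]:
    """Read a two-column edge table; returns (source_type, target_type, pairs).

    Duplicate pairs are dropped (first occurrence kept); a self pair or a row
    with the wrong column count raises :class:`ParseError` naming the line.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file, expected a typed header")
        head = [c.strip() for c in header.rstrip("\n").split(SEP)]
        if len(head) != 2:
            raise ParseError(f"{path}: line 1: expected 2 header columns, got {len(head)}")
        source_type, target_type = head
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = [c.strip() for c in line.rstrip("\n").split(SEP)]
            if len(cols) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(cols)}"
                )
            s, t = cols
            if s == t:
                raise ParseError(f"{path}: line {lineno}: self pair ({s!r}, {t!r})")
            if (s, t) not in seen:
                seen.add((s, t))
                pairs.append((s, t))
    return source_type, target_type, pairs


def write_labels(path: str | os.PathLike, labels: pd.Series) -> None:
    out = labels.rename("label")
    out.index.name = "sample_id"
    out.to_csv(path, sep=SEP)


def read_labels(path: str | os.PathLike) -> pd.Series:
    try:
        df = pd.read_csv(path, sep=SEP, index_col=0)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] != 1:
        raise ParseError(f"{path}: expected 2 columns (sample_id, label)")
    ser = df.iloc[:, 0].astype(str)
    ser.index = ser.index.astype(str).str.strip()
    if ser.index.has_duplicates:
        dup = ser.index[ser.index.duplicated()][0]
        raise InputError(f"{path}: duplicate sample id {dup!r}")
    return ser
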