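"""Minimal GCT v1.2 reader/writer.

GCT is the tab-separated expression-matrix format used by perturbation
databases: a ``#1.2`` version line, a ``rows\tcols`` dimension line, and
a matrix with ``Name`` and ``Description`` leader columns.
"""

from __future__ import annotations

import os

import pandas as pd


class GctParseError(ValueError):
    pass


def read_gct(path: str | os.PathLike) -> pd.DataFrame:
    """Read a GCT 1.2 file into a DataFrame indexed by row Name.

    The Description column is dropped. Raises :class:`GctParseError` on a
    bad version line or a dimension mismatch.
    """
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise GctParseError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise GctParseError("missing dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"], errors="ignore")
    if df.shape != (n_rows, n_cols):
        raise GctParseError(
            f"dimension line says {(n_rows, n_cols)} but matrix is {df.shape}"
        )
    df.index.name = "Name"
    return df.astype(float)


def write_gct(df: pd.DataFrame, path: str | os.PathLike, descriptions: dict | None = None) -> None:
    """Write a DataFrame (rows = named features, cols = samples) as GCT 1.2."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        cols = "\t".join(str(c) for c in df.columns)
        fh.write(f"Name\tDescription\t{cols}\n")
        for name, row in df.iterrows():
            desc = descriptions.get(name, "na")
            vals = "\t".join(repr(float(v)) for v in row.to_numpy())
            fh.write(f"{name}\t{desc}\t{vals}\n")
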