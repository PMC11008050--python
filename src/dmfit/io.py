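"""Plain-text I/O for matrices, vectors, tables and manifests.

Everything is CSV: the pipeline operates strictly post-parcellation, so no
neuroimaging container formats are needed. Matrix files may carry '#'
comment headers naming the convention; round-trips are exact to better than
1e-12.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_vector",
    "write_vector",
    "read_table",
    "write_table",
    "read_manifest",
]


def read_matrix(path: str | os.PathLike) -> np.ndarray:
    """Read a rectangular numeric CSV matrix; '#' lines are comments.

    Malformed input raises ConfigError naming the offending line.
    """
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            cells = s.split(",")
            try:
                row = [float(c) for c in cells]
            except ValueError as exc:
                raise ConfigError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ConfigError(
                    f"{path}: line {lineno}: ragged row (got {len(row)} cells, expected {width})"
                )
            rows.append(row)
    if not rows:
        raise ConfigError(f"{path}: no numeric data found")
    return np.asarray(rows, dtype=float)


def write_matrix(matrix: np.ndarray, path: str | os.PathLike, header: str | None = None) -> None:
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for row in m:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


def read_vector(path: str | os.PathLike) -> np.ndarray:
    m = read_matrix(path)
    return m.ravel()


def write_vector(vector: np.ndarray, path: str | os.PathLike, header: str | None = None) -> None:
    v = np.asarray(vector, dtype=float).ravel()
    write_matrix(v[:, None], path, header=header)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise ConfigError(f"{path}: cannot parse table ({exc})") from None


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)


def read_manifest(path: str | os.PathLike) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            out[key.strip()] = value.strip()
    return out
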