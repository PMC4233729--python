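"""Expression-table I/O and pre-processing.

The pipeline operates on an ``n x m`` matrix ``X`` of ``n`` genes measured at
``m`` timepoints of a free-running circadian time course.  Before any latent
trend extraction the matrix is standardized in a fixed order — log2 transform,
column centring, column scaling to unit standard deviation, then row centring
and row scaling — so that every gene's transcriptional response has mean 0 and
unit standard deviation.  All moments are population moments (``ddof=0``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression_table", "write_expression_table", "preprocess"]

#: tolerance used when checking the normalized-row contract
_NORM_TOL = 1e-9


@dataclass
class ExpressionMatrix:
    """Genes x timepoints expression values.

    Parameters
    ----------
    gene_ids
        Unique gene (or probe-set) identifiers, one per row.
    time_hours
        Sampling times in hours since subjective dawn, one per column.
    values
        ``n x m`` float array.
    normalized
        True once :func:`preprocess` has been applied; normalized rows have
        mean 0 and population standard deviation 1.
    """

    gene_ids: list[str]
    time_hours: list[float]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.time_hours = [float(t) for t in self.time_hours]
        n, m = self.values.shape
        if n < 2 or m < 3:
            raise ValueError(f"expression matrix must be at least 2 x 3, got {n} x {m}")
        if len(self.gene_ids) != n:
            raise ValueError("gene_ids length does not match row count")
        if len(self.time_hours) != m:
            raise ValueError("time_hours length does not match column count")
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
        if self.normalized:
            mu = self.values.mean(axis=1)
            sd = self.values.std(axis=1)
            if np.abs(mu).max() > _NORM_TOL or np.abs(sd - 1).max() > _NORM_TOL:
                raise ValueError("normalized flag set but rows are not zero-mean / unit-sd")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset(self, gene_ids) -> "ExpressionMatrix":
        """Row-subset preserving the given order (ids must exist)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"gene ids not in matrix: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.time_hours),
                                self.values[rows].copy(), normalized=self.normalized)


def _duplicates(ids) -> set:
    seen, dup = set(), set()
    for g in ids:
        if g in seen:
            dup.add(g)
        seen.add(g)
    return dup


def read_expression_table(path, log_transformed: bool = False) -> ExpressionMatrix:
    """Read a genes x timepoints TSV.

    Layout: header ``gene_id\\t<t0>\\t<t1>...`` with times parseable as float
    hours; first column gene ids; numeric body.  ``log_transformed`` is a
    bookkeeping hint only — no transform is applied here.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected gene_id column plus time columns")
    try:
        times = [float(c) for c in df.columns[1:]]
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric time label in header: {e}") from e
    gene_ids = df.iloc[:, 0].tolist()
    dupes = _duplicates(gene_ids)
    if dupes:
        raise ValueError(f"{path}: duplicate gene ids: {sorted(dupes)}")
    body = np.empty((len(gene_ids), len(times)), dtype=float)
    for j, col in enumerate(df.columns[1:]):
        parsed = pd.to_numeric(df[col], errors="coerce")
        raw = df[col]
        bad = parsed.isna() & ~raw.isna()
        bad |= raw.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric cell {raw.iloc[i]!r} at gene {gene_ids[i]!r}, "
                f"time column {col!r} (row {i + 2})"
            )
        body[:, j] = parsed.to_numpy(dtype=float)
    return ExpressionMatrix(gene_ids, times, body, normalized=False)


def write_expression_table(X: ExpressionMatrix, path) -> None:
    """Write the same TSV dialect :func:`read_expression_table` consumes."""
    df = pd.DataFrame(X.values, columns=[_fmt_time(t) for t in X.time_hours])
    df.insert(0, "gene_id", X.gene_ids)
    df.to_csv(path, sep="\t", index=False)


def _fmt_time(t: float) -> str:
    return f"{t:g}"


def preprocess(X: ExpressionMatrix, apply_log2: bool = True,
               pseudocount: float = 0.0) -> ExpressionMatrix:
    """Standardize an expression matrix for latent-trend extraction.

    Applies, in order: log2 (optional), column centring, column scaling to
    unit SD, row centring, row scaling to unit SD.  Population SD throughout.

    Raises
    ------
    ValueError
        If ``apply_log2`` and any value (plus ``pseudocount``) is <= 0, or if
        any row is constant after the log step (names the offending genes).
    """
    V = X.values.astype(float, copy=True)
    if apply_log2:
        V = V + pseudocount
        if (V <= 0).any():
            bad = [X.gene_ids[i] for i in np.unique(np.nonzero(V <= 0)[0])[:10]]
            raise ValueError(f"log2 of non-positive value; offending genes include {bad}")
        V = np.log2(V)

    row_sd = V.std(axis=1)
    const = np.flatnonzero(row_sd == 0)
    if const.size:
        raise ValueError(
            "constant expression rows cannot be normalized: "
            + ", ".join(X.gene_ids[i] for i in const[:20])
        )

    V = V - V.mean(axis=0, keepdims=True)
    col_sd = V.std(axis=0, keepdims=True)
    if (col_sd == 0).any():
        raise ValueError("constant column after centring")
    V = V / col_sd
    V = V - V.mean(axis=1, keepdims=True)
    row_sd = V.std(axis=1, keepdims=True)
    if (row_sd == 0).any():
        const = np.flatnonzero(row_sd.ravel() == 0)
        raise ValueError(
            "constant expression rows cannot be normalized: "
            + ", ".join(X.gene_ids[i] for i in const[:20])
        )
    V = V / row_sd
    return replace(X, values=V, normalized=True)
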