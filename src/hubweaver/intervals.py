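"""Interval overlap utilities (0-based, half-open coordinates).

Overlap semantics throughout the package: two intervals overlap iff they
share at least one base. Closed windows (e.g. the ±1 kb promoter window,
closed at both endpoints) are converted to half-open form by the caller
before querying.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


def build_trees(
    df: pd.DataFrame,
    chrom_col: str = "chrom",
    start_col: str = "start",
    end_col: str = "end",
) -> dict[str, IntervalTree]:
    """Index intervals of ``df`` per chromosome; payload is the row label."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, chrom, start, end in zip(
        df.index, df[chrom_col], df[start_col], df[end_col]
    ):
        if end > start:  # intervaltree rejects empty intervals
            trees[chrom].addi(int(start), int(end), idx)
    return dict(trees)


def query(trees: dict[str, IntervalTree], chrom: str, start: int, end: int) -> list:
    """Row labels of indexed intervals overlapping [start, end)."""
    tree = trees.get(chrom)
    if tree is None or end <= start:
        return []
    return [iv.data for iv in tree.overlap(start, end)]


def overlaps_any(
    df: pd.DataFrame,
    trees: dict[str, IntervalTree],
    chrom_col: str = "chrom",
    start_col: str = "start",
    end_col: str = "end",
) -> np.ndarray:
    """Boolean vector: does each row of ``df`` overlap any indexed interval."""
    out = np.zeros(len(df), dtype=bool)
    for i, (chrom, start, end) in enumerate(
        zip(df[chrom_col], df[start_col], df[end_col])
    ):
        tree = trees.get(chrom)
        if tree is not None and end > start and tree.overlaps(int(start), int(end)):
            out[i] = True
    return out


def midpoints(df: pd.DataFrame, start_col: str = "start", end_col: str = "end") -> np.ndarray:
    return ((df[start_col].to_numpy() + df[end_col].to_numpy()) // 2).astype(np.int64)
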