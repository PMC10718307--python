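"""Readers and writers for the plain-text genomic formats the package uses.

All coordinates are 0-based, half-open (BED convention). Formats:

* BED6 / narrowPeak for peaks,
* bedGraph for binned or piecewise-constant signal tracks,
* 10+ column BEDPE for loop tables (extra columns carry per-replicate counts
  and are declared in a ``#`` header line),
* TSV for gene tables (chrom, tss, strand, gene_id) and expression matrices,
* sparse triplet text (bin1_id, bin2_id, count) plus a bin table for contact
  matrices; upper triangle on disk, symmetrized on load.

Floats are serialized with ``%.6g`` so repeated writes of the same data are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hubweaver.matrix import ContactMatrix

FLOAT_FMT = "%.6g"

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]
NARROWPEAK_COLS = BED6_COLS + ["signalValue", "pValue", "qValue", "peak"]
BEDPE_BASE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return FLOAT_FMT % x
    return str(x)


def _write_table(df: pd.DataFrame, path, header_cols=None, index=False) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_cols is not None:
            fh.write("#" + "\t".join(header_cols) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=index, float_format=FLOAT_FMT)


# ---------------------------------------------------------------- peaks / BED

def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = BED6_COLS[: df.shape[1]]
    df.columns = names + [f"extra{i}" for i in range(df.shape[1] - len(names))]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED6_COLS if c in df.columns]
    _write_table(df[cols], path)


def read_narrowpeak(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = NARROWPEAK_COLS[: df.shape[1]]
    return df


def write_narrowpeak(peaks: pd.DataFrame, path, signal_col: str = "signalValue") -> None:
    """Write a peak table as 10-column narrowPeak; missing fields filled."""
    out = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"],
            "end": peaks["end"],
            "name": peaks.get("name", "."),
            "score": 0,
            "strand": ".",
            "signalValue": peaks[signal_col] if signal_col in peaks else 0.0,
            "pValue": -1,
            "qValue": -1,
            "peak": -1,
        }
    )
    _write_table(out, path)


# ------------------------------------------------------------------ bedGraph

def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom", "start", "end", "value"]
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    _write_table(df[["chrom", "start", "end", "value"]], path)


# -------------------------------------------------------------------- BEDPE

def read_bedpe(path) -> pd.DataFrame:
    """Read 10+ column BEDPE; extra column names come from the # header."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    names = None
    if first.startswith("#"):
        names = first[1:].strip().split("\t")
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if names is not None and len(names) == df.shape[1]:
        df.columns = names
    else:
        extra = [f"extra{i}" for i in range(df.shape[1] - len(BEDPE_BASE_COLS))]
        df.columns = BEDPE_BASE_COLS + extra
    return df


def write_bedpe(loops: pd.DataFrame, path, count_col: str = "score", extra_cols=()) -> None:
    out = pd.DataFrame(
        {
            "chrom1": loops["chrom1"],
            "start1": loops["start1"],
            "end1": loops["end1"],
            "chrom2": loops["chrom2"],
            "start2": loops["start2"],
            "end2": loops["end2"],
            "name": loops.get("name", "."),
            "score": loops[count_col] if count_col in loops else 0,
            "strand1": ".",
            "strand2": ".",
        }
    )
    for c in extra_cols:
        out[c] = loops[c]
    _write_table(out, path, header_cols=list(out.columns))


# ---------------------------------------------------------- genes, expression

def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom", "tss", "strand", "gene_id"][: df.shape[1]]
    return df


def write_gene_table(genes: pd.DataFrame, path) -> None:
    _write_table(genes[["chrom", "tss", "strand", "gene_id"]], path)


def read_expression(path) -> pd.DataFrame:
    """Gene × sample TSV; first column is the gene id (index)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", float_format=FLOAT_FMT)


# ------------------------------------------------------------ contact matrix

def write_triplet_matrices(
    matrices: dict[str, ContactMatrix], matrix_path, bins_path=None
) -> None:
    """Write per-chromosome matrices as one triplet file + one bin table.

    Bin ids are global and assigned in chromosome order; only the upper
    triangle (including the diagonal) of each matrix is stored, nonzero
    entries only.
    """
    bin_rows = []
    trip_rows = []
    offset = 0
    for chrom in sorted(matrices):
        cm = matrices[chrom]
        n = cm.n_bins
        for i in range(n):
            s = cm.start + i * cm.bin_size
            bin_rows.append((offset + i, chrom, s, s + cm.bin_size))
        iu, ju = np.triu_indices(n)
        vals = cm.matrix[iu, ju]
        nz = vals != 0
        for i, j, v in zip(iu[nz], ju[nz], vals[nz]):
            trip_rows.append((offset + int(i), offset + int(j), v))
        offset += n
    bins = pd.DataFrame(bin_rows, columns=["bin_id", "chrom", "start", "end"])
    trips = pd.DataFrame(trip_rows, columns=["bin1_id", "bin2_id", "count"])
    if bins_path is not None:
        _write_table(bins, bins_path, header_cols=list(bins.columns))
    _write_table(trips, matrix_path, header_cols=list(trips.columns))


def read_triplet_matrices(matrix_path, bins_path) -> dict[str, ContactMatrix]:
    bins = pd.read_csv(
        bins_path, sep="\t", comment="#", header=None,
        names=["bin_id", "chrom", "start", "end"],
    )
    trips = pd.read_csv(
        matrix_path, sep="\t", comment="#", header=None,
        names=["bin1_id", "bin2_id", "count"],
    )
    out: dict[str, ContactMatrix] = {}
    for chrom, sub in bins.groupby("chrom", sort=True):
        sub = sub.sort_values("bin_id")
        ids = sub["bin_id"].to_numpy()
        n = len(ids)
        lo, hi = ids.min(), ids.max()
        sel = trips[(trips["bin1_id"] >= lo) & (trips["bin1_id"] <= hi)]
        mat = np.zeros((n, n))
        i = (sel["bin1_id"] - lo).to_numpy()
        j = (sel["bin2_id"] - lo).to_numpy()
        v = sel["count"].to_numpy(dtype=float)
        mat[i, j] = v
        mat[j, i] = v  # symmetrize; diagonal written once
        bin_size = int(sub["end"].iloc[0] - sub["start"].iloc[0])
        out[chrom] = ContactMatrix(
            chrom=chrom, bin_size=bin_size, matrix=mat, start=int(sub["start"].min())
        )
    return out


# -------------------------------------------------------------------- JSON

def write_json(obj, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with Path(path).open() as fh:
        return json.load(fh)
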