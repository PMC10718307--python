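"""Peak and signal-track operations.

Covers promoter/distal classification of peaks against a TSS index (closed
±1 kb window by default), window-mean signal quantification from bedGraph
tracks, de-novo peak calling from paired-condition signals, and motif-class
annotation of loop anchors against TF peaks and a repeat annotation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from hubweaver import intervals
from hubweaver.defs import MOTIF_NONE, MOTIF_REPEAT, MOTIF_SINGLE

logger = logging.getLogger(__name__)


# ------------------------------------------------------- promoter vs distal

def promoter_windows(genes: pd.DataFrame, window_bp: int = 1000) -> pd.DataFrame:
    """Half-open intervals for the closed ±window promoter region of each TSS."""
    return pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": np.maximum(genes["tss"].to_numpy() - window_bp, 0),
            # closed at both endpoints -> half-open end is tss + window + 1
            "end": genes["tss"].to_numpy() + window_bp + 1,
            "gene_id": genes["gene_id"],
        }
    )


def classify_peak_locations(
    peaks: pd.DataFrame, genes: pd.DataFrame, window_bp: int = 1000
) -> pd.Series:
    """'promoter' iff the peak intersects any closed TSS +/- window; else 'distal'.

    Raises KeyError if a peak lies on a chromosome absent from the gene
    table (unknown chromosome).
    """
    known = set(genes["chrom"])
    missing = set(peaks["chrom"]) - known
    if missing:
        raise KeyError(f"peaks on chromosomes absent from the TSS index: {sorted(missing)}")
    trees = intervals.build_trees(promoter_windows(genes, window_bp))
    is_prom = intervals.overlaps_any(peaks, trees)
    return pd.Series(
        np.where(is_prom, "promoter", "distal"), index=peaks.index, name="location_class"
    )


# ---------------------------------------------------------------- signal

def _coverage_mean(starts, ends, values, a: int, b: int) -> float:
    """Mean coverage of [a, b) given sorted, non-overlapping segments."""
    if b <= a:
        return 0.0
    lo = np.searchsorted(ends, a, side="right")
    hi = np.searchsorted(starts, b, side="left")
    if hi <= lo:
        return 0.0
    s = starts[lo:hi]
    e = ends[lo:hi]
    v = values[lo:hi]
    overlap = np.minimum(e, b) - np.maximum(s, a)
    overlap = np.clip(overlap, 0, None)
    return float((overlap * v).sum() / (b - a))


def quantify_signal(
    track: pd.DataFrame,
    targets: pd.DataFrame,
    window_bp: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> np.ndarray:
    """Mean track coverage in a window centered on each target's midpoint.

    Uncovered bases count as zero. Windows extending beyond the chromosome
    are clipped (and logged) when ``chrom_sizes`` is given. Linear in the
    track: scaling all values by c scales every result by c.
    """
    by_chrom = {}
    for chrom, sub in track.groupby("chrom"):
        sub = sub.sort_values("start")
        by_chrom[chrom] = (
            sub["start"].to_numpy(), sub["end"].to_numpy(), sub["value"].to_numpy(float)
        )
    half = window_bp // 2
    mids = intervals.midpoints(targets)
    out = np.zeros(len(targets))
    clipped = 0
    for i, (chrom, mid) in enumerate(zip(targets["chrom"], mids)):
        a, b = mid - half, mid + half
        if a < 0:
            a, clipped = 0, clipped + 1
        if chrom_sizes is not None and chrom in chrom_sizes and b > chrom_sizes[chrom]:
            b, clipped = chrom_sizes[chrom], clipped + 1
        seg = by_chrom.get(chrom)
        if seg is None:
            continue
        out[i] = _coverage_mean(*seg, a, b)
    if clipped:
        logger.info("quantify_signal: clipped %d window(s) at chromosome edges", clipped)
    return out


def bin_track(track_chrom: pd.DataFrame, n_bins: int, bin_size: int, start: int = 0) -> np.ndarray:
    """Mean track value per fixed-size bin for one chromosome."""
    starts = track_chrom["start"].to_numpy()
    ends = track_chrom["end"].to_numpy()
    values = track_chrom["value"].to_numpy(float)
    order = np.argsort(starts)
    starts, ends, values = starts[order], ends[order], values[order]
    out = np.zeros(n_bins)
    for b in range(n_bins):
        a = start + b * bin_size
        out[b] = _coverage_mean(starts, ends, values, a, a + bin_size)
    return out


# ------------------------------------------------------------- de novo peaks

def call_de_novo_peaks(
    peaks: pd.DataFrame,
    on_col: str,
    off_col: str,
    fold_min: float = 4.0,
    baseline_max: float = 5.0,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Boolean mask of peaks gained after TF depletion.

    A peak qualifies iff its TF-off signal is at least ``fold_min`` times
    the TF-on signal (fold computed as (off + pc) / (on + pc)) and the
    TF-on signal is below ``baseline_max`` relative units.
    """
    on = peaks[on_col].to_numpy(float)
    off = peaks[off_col].to_numpy(float)
    if (on < 0).any() or (off < 0).any():
        raise ValueError("negative signal values")
    fold = (off + pseudocount) / (on + pseudocount)
    return pd.Series((fold >= fold_min) & (on < baseline_max), index=peaks.index, name="de_novo")


# ------------------------------------------------------------ motif classes

def annotate_anchor_class(
    anchors: pd.DataFrame,
    tf_peaks: pd.DataFrame,
    repeat_annotation: pd.DataFrame,
) -> pd.Series:
    """Motif class per anchor: 'repeat' iff the anchor overlaps a TF peak
    that itself overlaps a repeat interval; 'single' iff it overlaps a TF
    peak but no such repeat-class peak; 'none' otherwise."""
    rep_trees = intervals.build_trees(repeat_annotation) if len(repeat_annotation) else {}
    tf = tf_peaks.reset_index(drop=True)
    tf_is_repeat = (
        intervals.overlaps_any(tf, rep_trees) if rep_trees else np.zeros(len(tf), bool)
    )
    tf_trees = intervals.build_trees(tf)
    out = []
    for chrom, start, end in zip(anchors["chrom"], anchors["start"], anchors["end"]):
        hits = intervals.query(tf_trees, chrom, int(start), int(end))
        if not hits:
            out.append(MOTIF_NONE)
        elif any(tf_is_repeat[h] for h in hits):
            out.append(MOTIF_REPEAT)
        else:
            out.append(MOTIF_SINGLE)
    return pd.Series(out, index=anchors.index, name="motif_class")
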