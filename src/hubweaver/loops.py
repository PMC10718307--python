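"""Loop-table operations: reproducibility filtering, size-factor
normalization, anchor/loop classification, connectivity and length
statistics, the shuffled-anchor length null, and differential / novel loop
calling.

A loop table is a DataFrame with the BEDPE anchor columns (anchor1 left of
anchor2 on the same chromosome) plus arbitrary count columns. Loops are
identified by ``name`` = "chrom:start1-end1|chrom:start2-end2".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hubweaver import intervals
from hubweaver.defs import (
    LOOP_ANCHOR_COLS,
    MOTIF_ORDER,
    anchor_id,
    loop_key,
)


def add_loop_names(loops: pd.DataFrame) -> pd.DataFrame:
    loops = loops.copy()
    loops["name"] = [
        loop_key(*row)
        for row in zip(*(loops[c] for c in LOOP_ANCHOR_COLS))
    ]
    return loops


def loop_lengths(loops: pd.DataFrame) -> np.ndarray:
    """Midpoint-to-midpoint genomic span of each loop (bp)."""
    mid1 = (loops["start1"].to_numpy() + loops["end1"].to_numpy()) // 2
    mid2 = (loops["start2"].to_numpy() + loops["end2"].to_numpy()) // 2
    return np.abs(mid2 - mid1).astype(np.int64)


def anchor_table(loops: pd.DataFrame) -> pd.DataFrame:
    """Unique anchors of a loop table (chrom, start, end, anchor_id)."""
    a1 = loops[["chrom1", "start1", "end1"]].rename(
        columns={"chrom1": "chrom", "start1": "start", "end1": "end"}
    )
    a2 = loops[["chrom2", "start2", "end2"]].rename(
        columns={"chrom2": "chrom", "start2": "start", "end2": "end"}
    )
    anchors = pd.concat([a1, a2]).drop_duplicates().reset_index(drop=True)
    anchors["anchor_id"] = [
        anchor_id(c, s, e) for c, s, e in zip(anchors["chrom"], anchors["start"], anchors["end"])
    ]
    return anchors


# ------------------------------------------------------- reproducibility

def filter_reproducible_loops(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    min_count: int = 5,
    count_col: str = "score",
    strict: bool = False,
) -> pd.DataFrame:
    """Keep loops detected in both replicates above the count threshold.

    A loop is kept iff it has count > 0 in both replicates and its count
    exceeds ``min_count`` (strictly) in at least one replicate; with
    ``strict=True`` the threshold must be exceeded in both. Output carries
    ``count_rep1``/``count_rep2`` columns; it is a subset of the
    intersection of the replicate loop sets and the filter is idempotent.
    """
    r1 = add_loop_names(rep1)[LOOP_ANCHOR_COLS + ["name", count_col]].rename(
        columns={count_col: "count_rep1"}
    )
    r2 = add_loop_names(rep2)[["name", count_col]].rename(columns={count_col: "count_rep2"})
    merged = r1.merge(r2, on="name", how="outer")
    for c in ("count_rep1", "count_rep2"):
        merged[c] = merged[c].fillna(0)
    present = (merged["count_rep1"] > 0) & (merged["count_rep2"] > 0)
    if strict:
        above = (merged["count_rep1"] > min_count) & (merged["count_rep2"] > min_count)
    else:
        above = np.maximum(merged["count_rep1"], merged["count_rep2"]) > min_count
    kept = merged[present & above].dropna(subset=["chrom1"]).reset_index(drop=True)
    kept[["start1", "end1", "start2", "end2"]] = kept[
        ["start1", "end1", "start2", "end2"]
    ].astype(np.int64)
    return kept


# --------------------------------------------------------- normalization

def normalize_loop_counts(
    loops: pd.DataFrame, count_cols: list[str], prefix: str = "norm_"
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Total-count size-factor normalization across samples.

    Each sample's size factor is its total loop count divided by the mean
    total across samples; normalized counts are raw / factor, so totals are
    equalized across samples while within-sample rank order is preserved.
    Raises on a sample with zero total counts.
    """
    totals = {c: float(loops[c].sum()) for c in count_cols}
    if any(t == 0 for t in totals.values()):
        zero = [c for c, t in totals.items() if t == 0]
        raise ValueError(f"sample(s) with zero total loop counts: {zero}")
    mean_total = np.mean(list(totals.values()))
    factors = {c: t / mean_total for c, t in totals.items()}
    out = loops.copy()
    for c in count_cols:
        out[prefix + c] = loops[c] / factors[c]
    return out, factors


# -------------------------------------------------------- classification

def _pair_class(m1: str, m2: str) -> str:
    a, b = sorted((m1, m2), key=MOTIF_ORDER.index)
    return f"{a}-{b}"


def classify_loops(
    loops: pd.DataFrame,
    peaks: pd.DataFrame,
    tf_peaks: pd.DataFrame,
    repeat_annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Annotate loops with element class, TF association and anchor-pair class.

    ``peaks`` must carry a ``location_class`` column (see tracks module); an
    anchor is promoter-class iff it overlaps a promoter peak, else enhancer.
    ``tf_associated`` is true iff at least one anchor overlaps a TF peak;
    the anchor-pair class is the order-independent pair of per-anchor motif
    classes and yields six categories that partition any loop set.
    """
    from hubweaver.tracks import annotate_anchor_class

    anchors = anchor_table(loops)
    prom_peaks = peaks[peaks["location_class"] == "promoter"]
    prom_trees = intervals.build_trees(prom_peaks)
    anchors["is_promoter"] = intervals.overlaps_any(anchors, prom_trees)
    anchors["motif_class"] = annotate_anchor_class(anchors, tf_peaks, repeat_annotation)
    amap = anchors.set_index("anchor_id")

    out = add_loop_names(loops) if "name" not in loops.columns else loops.copy()
    id1 = [anchor_id(c, s, e) for c, s, e in zip(out["chrom1"], out["start1"], out["end1"])]
    id2 = [anchor_id(c, s, e) for c, s, e in zip(out["chrom2"], out["start2"], out["end2"])]
    p1 = amap.loc[id1, "is_promoter"].to_numpy()
    p2 = amap.loc[id2, "is_promoter"].to_numpy()
    m1 = amap.loc[id1, "motif_class"].to_numpy()
    m2 = amap.loc[id2, "motif_class"].to_numpy()

    letters = np.where(p1, "p", "e"), np.where(p2, "p", "e")
    out["element_class"] = ["-".join(sorted((a, b))) for a, b in zip(*letters)]
    out["anchor_pair_class"] = [_pair_class(a, b) for a, b in zip(m1, m2)]
    out["tf_associated"] = (m1 != "none") | (m2 != "none")
    out["anchor1_id"] = id1
    out["anchor2_id"] = id2
    return out


# ---------------------------------------------------------- connectivity

def anchor_connectivity(loops: pd.DataFrame, count_col: str) -> pd.DataFrame:
    """Per-anchor loop degree and summed counts, with motif class if present."""
    rows = []
    for side in ("1", "2"):
        cols = {f"anchor{side}_id": "anchor_id", count_col: "count"}
        sub = loops[list(cols)].rename(columns=cols)
        rows.append(sub)
    stacked = pd.concat(rows)
    stats = stacked.groupby("anchor_id").agg(
        loop_number=("count", "size"), total_counts=("count", "sum")
    )
    return stats.reset_index()


def connectivity_by_motif(
    loops: pd.DataFrame,
    anchor_classes: pd.Series,
    count_col: str,
) -> pd.DataFrame:
    """Group-median degree and counts per anchor motif class.

    ``anchor_classes`` maps anchor_id -> motif class (index = anchor_id).
    """
    stats = anchor_connectivity(loops, count_col).set_index("anchor_id")
    stats["motif_class"] = anchor_classes.reindex(stats.index).fillna("none")
    return (
        stats.groupby("motif_class")
        .agg(
            n_anchors=("loop_number", "size"),
            median_degree=("loop_number", "median"),
            median_counts=("total_counts", "median"),
        )
        .reset_index()
        .set_index("motif_class")
    )


def loop_length_stats(loops: pd.DataFrame, class_col: str = "anchor_pair_class") -> pd.DataFrame:
    """Mean/median loop span per anchor-pair class."""
    df = loops.copy()
    df["length"] = loop_lengths(df)
    return df.groupby(class_col)["length"].agg(["count", "mean", "median"])


# ------------------------------------------------------- shuffled null

def expected_loop_length_null(
    loops: pd.DataFrame,
    anchors: pd.DataFrame,
    n_shuffles: int = 100,
    seed: int = 0,
    class_col: str | None = "anchor_pair_class",
) -> pd.DataFrame:
    """Null loop-length distribution from shuffling one anchor per loop.

    For every shuffle round, each loop has its left or right anchor
    (probability 1/2 each) replaced by an anchor drawn uniformly from the
    same chromosome; the class label travels with the loop. Returns the
    per-class null mean with its Monte-Carlo standard error. Loops on
    chromosomes with fewer than 2 anchors are skipped.
    """
    rng = np.random.default_rng(seed)
    mids_by_chrom = {
        chrom: intervals.midpoints(sub)
        for chrom, sub in anchors.groupby("chrom")
    }
    mid1 = (loops["start1"].to_numpy() + loops["end1"].to_numpy()) // 2
    mid2 = (loops["start2"].to_numpy() + loops["end2"].to_numpy()) // 2
    chroms = loops["chrom1"].to_numpy()
    usable = np.array([len(mids_by_chrom.get(c, ())) >= 2 for c in chroms])
    classes = (
        loops[class_col].to_numpy()
        if class_col and class_col in loops.columns
        else np.array(["all"] * len(loops))
    )
    per_class_rounds: dict[str, list[float]] = {c: [] for c in np.unique(classes[usable])}
    for _ in range(n_shuffles):
        null_len = np.empty(int(usable.sum()), dtype=float)
        pick_left = rng.random(len(loops)) < 0.5
        k = 0
        for i in np.where(usable)[0]:
            pool = mids_by_chrom[chroms[i]]
            new_mid = pool[rng.integers(len(pool))]
            if pick_left[i]:
                null_len[k] = abs(mid2[i] - new_mid)
            else:
                null_len[k] = abs(new_mid - mid1[i])
            k += 1
        sub_classes = classes[usable]
        for c in per_class_rounds:
            per_class_rounds[c].append(float(null_len[sub_classes == c].mean()))
    rows = []
    for c, means in sorted(per_class_rounds.items()):
        means = np.asarray(means)
        rows.append(
            dict(anchor_pair_class=c, null_mean=float(means.mean()),
                 mc_se=float(means.std(ddof=1) / np.sqrt(len(means))) if len(means) > 1 else 0.0,
                 n_shuffles=n_shuffles)
        )
    return pd.DataFrame(rows).set_index("anchor_pair_class")


# ------------------------------------------------ differential / novel loops

def differential_loops(
    loops: pd.DataFrame,
    norm_on_col: str,
    norm_off_col: str,
    fold_threshold: float = 2.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-loop log2 fold change (off vs on) and gained/lost/stable labels.

    log2FC = log2((off + pc) / (on + pc)); 'gained' iff the fold ratio is at
    least ``fold_threshold``, 'lost' iff at most 1/threshold, else 'stable'.
    """
    on = loops[norm_on_col].to_numpy(float)
    off = loops[norm_off_col].to_numpy(float)
    ratio = (off + pseudocount) / (on + pseudocount)
    out = loops.copy()
    out["log2fc"] = np.log2(ratio)
    status = np.where(ratio >= fold_threshold, "gained",
                      np.where(ratio <= 1.0 / fold_threshold, "lost", "stable"))
    out["status"] = status
    return out


def differential_summary(diff: pd.DataFrame, class_col: str = "anchor_pair_class") -> pd.DataFrame:
    """Gained/lost/stable counts per anchor-pair class."""
    return (
        diff.groupby([class_col, "status"]).size().unstack(fill_value=0).reindex(
            columns=["gained", "lost", "stable"], fill_value=0
        )
    )


def call_novel_loops(
    loops: pd.DataFrame,
    norm_on_col: str,
    norm_off_col: str,
    fold_min: float = 4.0,
    baseline_max: float = 2.0,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Mask of loops gained de novo after TF depletion.

    Kept iff the TF-off normalized count exceeds ``fold_min`` times the
    TF-on count, strictly, with the shared pseudocount policy, and the
    TF-on normalized count is below ``baseline_max``.
    """
    on = loops[norm_on_col].to_numpy(float)
    off = loops[norm_off_col].to_numpy(float)
    fold = (off + pseudocount) / (on + pseudocount)
    return pd.Series((fold > fold_min) & (on < baseline_max), index=loops.index, name="novel")
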