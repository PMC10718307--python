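"""TF-to-promoter connectivity modes and target-gene selection.

A gene is "connected" to the TF through one or more of three looping modes:

* ``tss_direct`` - a TF peak lies within the closed ±1 kb TSS window;
* ``e_p``        - a loop joins a TF-bound anchor to the gene's promoter
                   anchor;
* ``e_b_p``      - the promoter loops to a bridge anchor B, where B is a
                   distal (enhancer-class) anchor itself connected by a loop
                   to a TF-bound anchor, and the B-promoter loop weakens at
                   least two-fold after TF depletion.

``mixed`` marks genes supported by two or more modes. Target genes are
connected genes whose expression drops at least 1.5-fold after depletion in
at least one cellular context; novel-loop targets are genes whose promoter
anchor joins a de-novo loop and whose expression rises more than 1.5-fold.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd

from hubweaver import intervals
from hubweaver.tracks import promoter_windows

logger = logging.getLogger(__name__)

MODES = ("tss_direct", "e_p", "e_b_p")


def _promoter_anchor_map(anchors: pd.DataFrame, genes: pd.DataFrame, window_bp: int):
    """gene_id -> set of anchor_ids overlapping the gene's promoter window."""
    win = promoter_windows(genes, window_bp)
    trees = intervals.build_trees(anchors)
    out: dict[str, set[str]] = defaultdict(set)
    ids = anchors["anchor_id"].to_numpy()
    for chrom, start, end, gene in zip(win["chrom"], win["start"], win["end"], win["gene_id"]):
        for hit in intervals.query(trees, chrom, int(start), int(end)):
            out[gene].add(ids[hit])
    return out


def identify_connected_genes(
    loops: pd.DataFrame,
    tf_peaks: pd.DataFrame,
    genes: pd.DataFrame,
    peaks: pd.DataFrame,
    norm_on_col: str,
    norm_off_col: str,
    window_bp: int = 1000,
    bridge_decrease: float = 2.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Connectivity modes per gene from a classified union loop table.

    ``loops`` must carry anchor ids and per-condition normalized counts;
    ``peaks`` must carry ``location_class`` (to decide which anchors are
    enhancer-class and thus eligible bridges). Returns one row per gene with
    a nonempty mode set: gene_id, modes (sorted tuple), mixed, bridge
    anchors and supporting loop names.
    """
    from hubweaver.loops import anchor_table

    anchors = anchor_table(loops)
    tf_trees = intervals.build_trees(tf_peaks)
    anchors["tf_bound"] = intervals.overlaps_any(anchors, tf_trees)
    prom_peaks = peaks[peaks["location_class"] == "promoter"]
    anchors["is_enhancer"] = ~intervals.overlaps_any(
        anchors, intervals.build_trees(prom_peaks)
    )
    tf_bound = set(anchors.loc[anchors["tf_bound"], "anchor_id"])
    enhancer = set(anchors.loc[anchors["is_enhancer"], "anchor_id"])

    prom_map = _promoter_anchor_map(anchors, genes, window_bp)

    # adjacency: anchor -> list of (partner, loop_name, norm_on, norm_off)
    adj: dict[str, list[tuple]] = defaultdict(list)
    for row in loops.itertuples(index=False):
        on = getattr(row, norm_on_col)
        off = getattr(row, norm_off_col)
        adj[row.anchor1_id].append((row.anchor2_id, row.name, on, off))
        adj[row.anchor2_id].append((row.anchor1_id, row.name, on, off))

    # bridges: enhancer anchors connected by any loop to a TF-bound anchor
    bridge_eligible = {
        a for a in enhancer
        if any(p in tf_bound for p, _, _, _ in adj.get(a, ()))
    }

    # TF peaks inside promoter windows -> tss_direct
    win = promoter_windows(genes, window_bp)
    win_trees = intervals.build_trees(win)
    tss_direct_genes: set[str] = set()
    gene_ids = win["gene_id"].to_numpy()
    for chrom, start, end in zip(tf_peaks["chrom"], tf_peaks["start"], tf_peaks["end"]):
        for hit in intervals.query(win_trees, chrom, int(start), int(end)):
            tss_direct_genes.add(gene_ids[hit])

    known = set(genes["gene_id"])
    rows = []
    for gene in sorted(known):
        modes: set[str] = set()
        support: list[str] = []
        bridges: list[str] = []
        if gene in tss_direct_genes:
            modes.add("tss_direct")
        for p_anchor in sorted(prom_map.get(gene, ())):
            for partner, lname, on, off in adj.get(p_anchor, ()):
                if partner in tf_bound:
                    modes.add("e_p")
                    support.append(lname)
                elif partner in bridge_eligible:
                    fold_down = (on + pseudocount) / (off + pseudocount)
                    if fold_down >= bridge_decrease:
                        modes.add("e_b_p")
                        bridges.append(partner)
                        support.append(lname)
        if modes:
            rows.append(
                dict(gene_id=gene, modes=tuple(sorted(modes)), mixed=len(modes) >= 2,
                     n_support=len(set(support)), bridges=tuple(sorted(set(bridges))))
            )
    return pd.DataFrame(rows, columns=["gene_id", "modes", "mixed", "n_support", "bridges"])


def _context_fold(expr, gene, on_col, off_col, pseudocount):
    on = expr.at[gene, on_col] + pseudocount
    off = expr.at[gene, off_col] + pseudocount
    return on, off


def select_target_genes(
    connected: pd.DataFrame,
    expression: pd.DataFrame,
    contexts: dict[str, tuple[str, str]],
    min_fold_down: float = 1.5,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Connected genes down at least ``min_fold_down`` in >= 1 context.

    ``contexts`` maps context name -> (on_column, off_column) of the
    expression table. Genes missing from the table are excluded and logged.
    Output is a subset of the connected set.
    """
    rows = []
    missing = 0
    for row in connected.itertuples(index=False):
        if row.gene_id not in expression.index:
            missing += 1
            continue
        hits = []
        for ctx, (on_col, off_col) in contexts.items():
            on, off = _context_fold(expression, row.gene_id, on_col, off_col, pseudocount)
            if on >= min_fold_down * off:
                hits.append(ctx)
        if hits:
            rows.append(dict(gene_id=row.gene_id, modes=row.modes, mixed=row.mixed,
                             contexts=tuple(hits)))
    if missing:
        logger.info("select_target_genes: %d connected gene(s) lacked expression", missing)
    return pd.DataFrame(rows, columns=["gene_id", "modes", "mixed", "contexts"])


def select_novel_loop_targets(
    novel_loops: pd.DataFrame,
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    contexts: dict[str, tuple[str, str]],
    min_fold_up: float = 1.5,
    pseudocount: float = 0.1,
    window_bp: int = 1000,
) -> pd.DataFrame:
    """Genes whose promoter anchor joins a novel loop and expression rises
    more than ``min_fold_up``-fold (strict) after TF depletion."""
    from hubweaver.loops import anchor_table

    if not len(novel_loops):
        return pd.DataFrame(columns=["gene_id", "contexts"])
    anchors = anchor_table(novel_loops)
    prom_map = _promoter_anchor_map(anchors, genes, window_bp)
    rows = []
    for gene in sorted(prom_map):
        if gene not in expression.index:
            continue
        hits = []
        for ctx, (on_col, off_col) in contexts.items():
            on, off = _context_fold(expression, gene, on_col, off_col, pseudocount)
            if off > min_fold_up * on:
                hits.append(ctx)
        if hits:
            rows.append(dict(gene_id=gene, contexts=tuple(hits)))
    return pd.DataFrame(rows, columns=["gene_id", "contexts"])


def b_compartment_expression(
    genes: pd.DataFrame,
    profiles: dict[str, "object"],
    change_scores: dict[str, np.ndarray],
    tf_target_genes: set[str],
    expression: pd.DataFrame,
    on_col: str,
    off_col: str,
) -> dict:
    """Mean expression per condition for non-target genes in strengthening
    B compartments.

    Selects genes whose TSS bin is B-labeled with a positive interaction-
    change score (e.g. the Repress ratio) and which are not direct TF
    targets; returns per-condition means with the gene count.
    """
    selected = []
    for row in genes.itertuples(index=False):
        prof = profiles.get(row.chrom)
        score = change_scores.get(row.chrom)
        if prof is None or score is None:
            continue
        b = prof.bin_of(row.tss)
        if not (0 <= b < len(prof.labels)):
            continue
        if prof.labels[b] != "B" or not np.isfinite(score[b]) or score[b] <= 0:
            continue
        if row.gene_id in tf_target_genes or row.gene_id not in expression.index:
            continue
        selected.append(row.gene_id)
    if not selected:
        return dict(n_genes=0, mean_on=float("nan"), mean_off=float("nan"), genes=[])
    sub = expression.loc[selected]
    return dict(
        n_genes=len(selected),
        mean_on=float(sub[on_col].mean()),
        mean_off=float(sub[off_col].mean()),
        genes=selected,
    )


def gene_set_score(expression: pd.DataFrame, gene_set, ddof: int = 1) -> pd.Series:
    """Per-sample mean of per-gene z-scores over a gene set.

    Standardization is across samples (sample SD, ddof=1); genes with zero
    variance contribute 0. Location-scale invariant: shifting or scaling
    every expression value leaves the scores unchanged. Raises if the gene
    set is disjoint from the matrix.
    """
    present = [g for g in gene_set if g in expression.index]
    if not present:
        raise ValueError("gene set disjoint from expression matrix")
    sub = expression.loc[present].astype(float)
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=ddof)
    z = sub.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return z.mean(axis=0)
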