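"""Paired-condition synthetic datasets with planted ground truth.

The generator emulates the data structure of a TF-depletion 3D-genomics
study: two conditions (TF-on "shGFP", TF-off "shFLI1"), H3K27ac peaks and
signal tracks, TF binding sites split into GGAA-repeat and single-GGAA
motif classes, replicated H3K27ac-anchored loop tables in which
repeat-anchored "hub" anchors carry more partners, higher counts and longer
spans, binned contact matrices with distance decay, TAD blocks and an A/B
checkerboard whose segregation strengthens when the TF is depleted, and an
expression table coupled to the planted looping changes.

Every planted effect is recorded in a ground-truth manifest so downstream
detectors can be scored for recovery. Fixing the seed makes the dataset --
including all files written by :func:`write_fixture` -- byte-identical
across runs.

Distributional choices (negative-binomial counts around distance-decayed
means, exponential span draws, lognormal signals) are the generator's own:
they are exposed through :class:`SimulationConfig` rather than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hubweaver.defs import (
    COND_OFF,
    COND_ON,
    CONDITIONS,
    COUNT_COLS,
    MOTIF_REPEAT,
    MOTIF_SINGLE,
    anchor_id,
    loop_key,
)
from hubweaver.matrix import ContactMatrix

_STAGE_FEATURES, _STAGE_LOOPS, _STAGE_MATRIX_ON, _STAGE_MATRIX_OFF, _STAGE_EXPR = range(5)


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic experiment.

    Defaults describe a desk-scale toy genome (2 chromosomes x 40 Mb at
    40-kb bins) with strong planted hub and compartment effects; the
    ``mixing_*`` parameters control A/B intermixing per condition
    (1 = fully mixed, 0 = fully segregated), with the TF-on state more
    mixed than the TF-off state.
    """

    genome_spec: tuple = (("chr1", 40_000_000), ("chr2", 40_000_000))
    bin_size: int = 40_000
    n_tf_peaks: int = 200
    repeat_fraction: float = 0.3
    hub_degree_boost: float = 5.0
    hub_count_boost: float = 3.0
    hub_span_scale: int = 1_000_000
    decay_exponent: float = 1.0
    n_tads: int = 25                  # per chromosome
    compartment_block_size: int = 25  # bins per A/B block
    mixing_on: float = 0.5
    mixing_off: float = 0.2
    knockdown_loss_fraction: float = 0.8
    n_de_novo_peaks: int = 40
    expression_effect: float = 1.0    # |log2FC| planted on coupled genes
    seed: int = 0

    # generator-level knobs (stand-in distributional choices, config-exposed)
    n_genes: int = 400
    n_distal_anchors: int = 1200
    base_degree: float = 2.0
    base_span_scale: int = 70_000
    base_count_mean: float = 12.0
    nb_dispersion: float = 0.2
    count_decay_scale: int = 200_000
    count_decay_exponent: float = 0.5
    segregation: float = 0.6
    tad_boost: float = 0.8
    contact_depth: float = 200.0
    diagonal_factor: float = 4.0
    switch_fraction: float = 0.05     # of bins planted to switch A/B labels
    switch_damp: float = 0.5          # local segregation damping at switches
    n_ep_targets: int = 15
    n_ebp_targets: int = 10
    site_spacing: int = 6000
    edge_margin: int = 100_000

    def __post_init__(self):
        for name, lo, hi in (
            ("repeat_fraction", 0, 1), ("mixing_on", 0, 1), ("mixing_off", 0, 1),
            ("knockdown_loss_fraction", 0, 1), ("switch_fraction", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.mixing_off > self.mixing_on:
            raise ValueError("mixing_off must not exceed mixing_on")
        if self.hub_degree_boost < 1 or self.hub_count_boost < 1:
            raise ValueError("hub boosts must be >= 1")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        for chrom, length in self.genome_spec:
            if length % self.bin_size:
                raise ValueError(f"{chrom} length {length} not divisible by bin_size")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: int(l) for c, l in self.genome_spec}

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stage])


@dataclass
class SyntheticDataset:
    """Generated tables plus the planted ground-truth manifest."""

    config: SimulationConfig
    genes: pd.DataFrame = None
    tf_peaks: pd.DataFrame = None
    repeat_annotation: pd.DataFrame = None
    peaks: pd.DataFrame = None
    tracks: dict = field(default_factory=dict)      # condition -> bedGraph df
    loops: pd.DataFrame = None
    matrices: dict = field(default_factory=dict)    # condition -> {chrom: ContactMatrix}
    expression: pd.DataFrame = None
    truth: dict = field(default_factory=dict)


def _split_counts(total: int, weights: np.ndarray) -> list[int]:
    """Largest-remainder apportionment of ``total`` across weights."""
    frac = weights / weights.sum() * total
    base = np.floor(frac).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(frac - base), kind="stable")
    base[order[:rem]] += 1
    return base.tolist()


def _negbin(rng: np.random.Generator, mu, dispersion: float, size=None):
    """NB draws with var = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mu, size=size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion, size=size if size is not None else mu.shape)
    return rng.poisson(lam)


# ----------------------------------------------------------------- features

def simulate_features(config: SimulationConfig) -> SyntheticDataset:
    """Place genes, TF peaks, H3K27ac peaks and tracks; plant TADs and A/B.

    TAD boundaries partition each chromosome; A/B blocks are unions of
    consecutive TADs of roughly ``compartment_block_size`` bins, so
    compartment edges coincide with TAD boundaries (as in real genomes).
    De novo peaks get a TF-on signal below 5 relative units and a TF-off
    signal at least four-fold higher; all other peaks have TF-on signal
    of at least 5, so the de-novo rule recovers exactly the planted set.
    """
    rng = config.rng(_STAGE_FEATURES)
    chroms = [c for c, _ in config.genome_spec]
    sizes = config.chrom_sizes
    n_bins = {c: sizes[c] // config.bin_size for c in chroms}

    # --- TADs and compartments -------------------------------------------
    tad_bounds: dict[str, list[int]] = {}
    tad_id: dict[str, np.ndarray] = {}
    labels_on: dict[str, np.ndarray] = {}
    min_tad = 10
    for chrom in chroms:
        nb = n_bins[chrom]
        k = config.n_tads
        if nb < k * min_tad:
            raise ValueError(f"{chrom}: too few bins ({nb}) for {k} TADs")
        w = rng.dirichlet(np.full(k, 3.0))
        extra = _split_counts(nb - k * min_tad, w)
        tsizes = np.array([min_tad + e for e in extra])
        starts = np.concatenate([[0], np.cumsum(tsizes)[:-1]])
        tad_bounds[chrom] = starts[1:].tolist()
        tid = np.repeat(np.arange(k), tsizes)
        tad_id[chrom] = tid
        lab = np.empty(nb, dtype="<U1")
        cur, acc = "A", 0
        for t in range(k):
            lab[tid == t] = cur
            acc += tsizes[t]
            if acc >= config.compartment_block_size:
                cur = "B" if cur == "A" else "A"
                acc = 0
        labels_on[chrom] = lab

    # planted A/B switches: whole TADs flipped in the TF-off condition,
    # with locally damped segregation so switching sites score weakly
    labels_off = {c: labels_on[c].copy() for c in chroms}
    damp = {c: np.ones(n_bins[c]) for c in chroms}
    switched_bins: dict[str, list[int]] = {c: [] for c in chroms}
    for chrom in chroms:
        target = config.switch_fraction * n_bins[chrom]
        if target <= 0:
            continue
        got = 0
        for t in rng.permutation(config.n_tads):
            sel = np.where(tad_id[chrom] == t)[0]
            if got + len(sel) > 1.5 * target and got > 0:
                continue
            flip = labels_on[chrom][sel[0]]
            labels_off[chrom][sel] = "B" if flip == "A" else "A"
            damp[chrom][sel] = config.switch_damp
            switched_bins[chrom].extend(int(b) for b in sel)
            got += len(sel)
            if got >= target:
                break

    # --- site placement ---------------------------------------------------
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    counts = {
        "gene": _split_counts(config.n_genes, weights),
        "tf": _split_counts(config.n_tf_peaks, weights),
        "distal": _split_counts(config.n_distal_anchors, weights),
        "denovo": _split_counts(config.n_de_novo_peaks, weights),
    }
    n_tss_direct = max(1, config.n_tf_peaks // 20) if config.n_tf_peaks else 0

    gene_rows, tf_rows, peak_rows = [], [], []
    gi = ti = pi = 0
    for ci, chrom in enumerate(chroms):
        lattice = np.arange(
            config.edge_margin, sizes[chrom] - config.edge_margin, config.site_spacing
        )
        n_gene, n_tf, n_dist, n_dn = (counts[k][ci] for k in ("gene", "tf", "distal", "denovo"))
        n_tf_tss = min(n_tss_direct if ci == 0 else 0, n_tf, n_gene)
        need = n_gene + (n_tf - n_tf_tss) + n_dist + n_dn
        if need > len(lattice):
            raise ValueError(
                f"{chrom}: genome too small for requested features "
                f"({need} sites > {len(lattice)} available)"
            )
        sites = np.sort(rng.choice(lattice, size=need, replace=False))
        sites = sites + rng.integers(-800, 801, size=need)
        sites = rng.permutation(sites)
        cursor = 0

        # genes with promoter H3K27ac peaks
        tss_list = np.sort(sites[cursor: cursor + n_gene]); cursor += n_gene
        chrom_genes = []
        for tss in tss_list:
            gid = f"g{gi:05d}"; gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((chrom, int(tss), strand, gid))
            peak_rows.append((chrom, int(tss) - 1000, int(tss) + 1000,
                              f"peak_{pi:05d}", "promoter", gid)); pi += 1
            chrom_genes.append(gid)

        # TF peaks: a few planted directly at gene TSSs, the rest on sites
        tf_centers = []
        if n_tf_tss:
            tss_genes = rng.choice(len(chrom_genes), size=n_tf_tss, replace=False)
            for gidx in tss_genes:
                tss = int(tss_list[gidx])
                tf_centers.append((tss + int(rng.integers(-400, 401)), chrom_genes[gidx]))
        for c in sites[cursor: cursor + (n_tf - n_tf_tss)]:
            tf_centers.append((int(c), ""))
        cursor += n_tf - n_tf_tss
        for center, at_gene in tf_centers:
            name = f"tf_{ti:04d}"; ti += 1
            tf_rows.append((chrom, center - 500, center + 500, name, at_gene))
            if not at_gene:  # TSS-planted TF sites reuse the promoter peak
                peak_rows.append((chrom, center - 1000, center + 1000,
                                  f"peak_{pi:05d}", "tf_anchor", name)); pi += 1

        for c in sites[cursor: cursor + n_dist]:
            peak_rows.append((chrom, int(c) - 1000, int(c) + 1000,
                              f"peak_{pi:05d}", "distal", "")); pi += 1
        cursor += n_dist
        for c in sites[cursor: cursor + n_dn]:
            peak_rows.append((chrom, int(c) - 1000, int(c) + 1000,
                              f"peak_{pi:05d}", "de_novo", "")); pi += 1
        cursor += n_dn

    genes = pd.DataFrame(gene_rows, columns=["chrom", "tss", "strand", "gene_id"])
    tf_peaks = pd.DataFrame(tf_rows, columns=["chrom", "start", "end", "name", "at_gene"])
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "name", "kind", "link"])

    # motif classes and the repeat annotation
    n_rep = int(round(config.repeat_fraction * len(tf_peaks)))
    motif = np.array([MOTIF_SINGLE] * len(tf_peaks), dtype=object)
    rep_idx = rng.choice(len(tf_peaks), size=n_rep, replace=False) if n_rep else []
    motif[list(rep_idx)] = MOTIF_REPEAT
    tf_peaks["motif_class"] = motif
    rep = tf_peaks[tf_peaks["motif_class"] == MOTIF_REPEAT]
    centers = (rep["start"].to_numpy() + rep["end"].to_numpy()) // 2
    repeat_annotation = pd.DataFrame(
        {"chrom": rep["chrom"].to_numpy(), "start": centers - 300, "end": centers + 300,
         "name": [f"ggaa_{i:04d}" for i in range(len(rep))]}
    )

    # --- signals ----------------------------------------------------------
    # hub anchors: H3K27ac peaks overlapping a repeat-class TF peak
    tf_by_name = tf_peaks.set_index("name")
    is_hub = np.zeros(len(peaks), dtype=bool)
    for i, (kind, link) in enumerate(zip(peaks["kind"], peaks["link"])):
        if kind == "tf_anchor" and tf_by_name.at[link, "motif_class"] == MOTIF_REPEAT:
            is_hub[i] = True
    tss_tf = tf_peaks[tf_peaks["at_gene"] != ""].set_index("at_gene")["motif_class"]
    for i, (kind, link) in enumerate(zip(peaks["kind"], peaks["link"])):
        if kind == "promoter" and link in tss_tf.index:
            if tss_tf.loc[link] == MOTIF_REPEAT:
                is_hub[i] = True
    peaks["is_hub_anchor"] = is_hub
    peaks["is_de_novo"] = peaks["kind"] == "de_novo"

    n_pk = len(peaks)
    base = 5.0 + rng.lognormal(1.5, 0.6, size=n_pk)
    sig_on = np.where(peaks["kind"] == "tf_anchor", base * 1.5, base)
    off_mult = rng.uniform(0.85, 1.18, size=n_pk)
    tf_like = (peaks["kind"] == "tf_anchor").to_numpy() | is_hub
    off_mult[tf_like] = rng.uniform(0.3, 0.7, size=int(tf_like.sum()))
    sig_off = sig_on * off_mult
    dn = peaks["is_de_novo"].to_numpy()
    dn_on = rng.uniform(0.3, 1.5, size=int(dn.sum()))
    sig_on[dn] = dn_on
    sig_off[dn] = (dn_on + 0.5) * rng.uniform(5.0, 8.0, size=int(dn.sum())) - 0.5
    peaks[f"signal_{COND_ON}"] = np.round(sig_on, 4)
    peaks[f"signal_{COND_OFF}"] = np.round(sig_off, 4)

    # --- signal tracks ----------------------------------------------------
    tracks = {}
    for cond in CONDITIONS:
        rows = []
        sig_col = f"signal_{cond}"
        for chrom in chroms:
            nb = n_bins[chrom]
            bg = np.where(labels_on[chrom] == "A", 1.0, 0.2) + rng.uniform(0, 0.15, nb)
            sub = peaks[peaks["chrom"] == chrom].sort_values("start")
            pos = 0
            events = list(zip(sub["start"], sub["end"], sub[sig_col]))
            events.append((sizes[chrom], sizes[chrom], 0.0))
            for pstart, pend, val in events:
                while pos < pstart:  # background up to the peak, split per bin
                    b = pos // config.bin_size
                    seg_end = min((b + 1) * config.bin_size, pstart)
                    rows.append((chrom, pos, seg_end, round(float(bg[b]), 4)))
                    pos = seg_end
                if pend > pstart:
                    rows.append((chrom, pstart, pend, float(val)))
                    pos = pend
        tracks[cond] = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    truth = {
        "bin_size": config.bin_size,
        "chromosomes": {c: int(n_bins[c]) for c in chroms},
        "tad_boundaries": {c: [int(b) for b in tad_bounds[c]] for c in chroms},
        "ab_labels": {
            COND_ON: {c: "".join(labels_on[c]) for c in chroms},
            COND_OFF: {c: "".join(labels_off[c]) for c in chroms},
        },
        "switched_bins": {c: sorted(switched_bins[c]) for c in chroms},
        "de_novo_peaks": peaks.loc[peaks["is_de_novo"], "name"].tolist(),
        "hub_anchors": [
            anchor_id(c, s, e)
            for c, s, e in peaks.loc[peaks["is_hub_anchor"], ["chrom", "start", "end"]].itertuples(index=False)
        ],
        "tss_direct_genes": sorted(tf_peaks.loc[tf_peaks["at_gene"] != "", "at_gene"].unique()),
    }
    ds = SyntheticDataset(config=config, genes=genes, tf_peaks=tf_peaks,
                          repeat_annotation=repeat_annotation, peaks=peaks,
                          tracks=tracks, truth=truth)
    ds.truth["_internal"] = {"tad_id": tad_id, "damp": damp,
                             "labels": {COND_ON: labels_on, COND_OFF: labels_off}}
    return ds


# -------------------------------------------------------------------- loops

def simulate_loops(dataset: SyntheticDataset, config: SimulationConfig) -> SyntheticDataset:
    """Generate replicated loop tables for both conditions.

    Hub (repeat-TF) anchors initiate ``hub_degree_boost`` times more loops,
    with spans drawn at scale ``hub_span_scale`` and count means multiplied
    by ``hub_count_boost``; per-loop means decay mildly with span. The
    TF-off condition removes ``knockdown_loss_fraction`` of hub loops,
    weakens planted bridge-promoter loops and adds planted novel loops
    (TF-on mean near zero, TF-off mean well above the four-fold rule).
    Replicates share each loop's mean; counts are negative-binomial.
    """
    rng = config.rng(_STAGE_LOOPS)
    peaks = dataset.peaks.reset_index(drop=True)
    kd_active = config.knockdown_loss_fraction > 0

    by_chrom = {
        chrom: sub.sort_values("start").reset_index()
        for chrom, sub in peaks.groupby("chrom")
    }
    loop_records: dict[tuple[int, int], dict] = {}

    def add_loop(i: int, j: int, mu_on: float, mu_off: float, **flags):
        # planted loops are added first and win over later baseline duplicates
        if i == j:
            return None
        key = (min(i, j), max(i, j))
        if key in loop_records:
            return None
        rec = dict(mu_on=mu_on, mu_off=mu_off, is_hub=False, is_novel=False,
                   is_bridge_bp=False)
        rec.update(flags)
        loop_records[key] = rec
        return key

    mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy()

    def count_mu(span: float, hub: bool) -> float:
        decay = (config.count_decay_scale / (config.count_decay_scale + span)) ** config.count_decay_exponent
        boost = config.hub_count_boost if hub else 1.0
        return config.base_count_mean * boost * decay * rng.uniform(0.7, 1.4)

    # ---- planted connectivity: e-p, e-b-p, mixed -------------------------
    gene_prom_anchor = {}  # gene_id -> global peak index of its promoter peak
    for idx, row in peaks.iterrows():
        if row["kind"] == "promoter":
            gene_prom_anchor[row["link"]] = idx
    hub_idx_by_chrom = {
        chrom: sub.loc[sub["is_hub_anchor"], "index"].to_numpy()
        for chrom, sub in by_chrom.items()
    }
    tss_direct = list(dataset.truth["tss_direct_genes"])
    reserved = set(tss_direct)
    genes_df = dataset.genes

    gene_chrom = genes_df.set_index("gene_id")["chrom"]

    def pick_genes(n: int) -> list[str]:
        pool = [
            g for g in genes_df["gene_id"]
            if g not in reserved and len(hub_idx_by_chrom.get(gene_chrom[g], ())) > 0
        ]
        if not pool or n <= 0:
            return []
        chosen = [pool[k] for k in rng.choice(len(pool), size=min(n, len(pool)), replace=False)]
        reserved.update(chosen)
        return chosen

    ep_genes = pick_genes(config.n_ep_targets)
    ebp_genes = pick_genes(config.n_ebp_targets)
    mixed_genes = tss_direct[: max(1, len(tss_direct) // 2)]

    def nearest(pool: np.ndarray, around: int) -> int:
        return int(pool[np.argmin(np.abs(mids[pool] - mids[around]))])

    def planted_mu() -> float:
        # planted regulatory loops are strong by construction: well above the
        # reproducibility filter regardless of span
        return config.base_count_mean * config.hub_count_boost * rng.uniform(0.9, 1.3)

    for g in ep_genes + mixed_genes:
        chrom = gene_chrom[g]
        if len(hub_idx_by_chrom.get(chrom, ())) == 0:
            continue
        p = gene_prom_anchor[g]
        h = nearest(hub_idx_by_chrom[chrom], p)
        add_loop(h, p, planted_mu(), 0.0, is_hub=True)

    bridge_pool = {
        chrom: sub.loc[(sub["kind"] == "distal") & ~sub["is_de_novo"], "index"].to_numpy()
        for chrom, sub in by_chrom.items()
    }
    ebp_bridge_loops = []
    for g in ebp_genes:
        chrom = gene_chrom[g]
        if len(hub_idx_by_chrom.get(chrom, ())) == 0 or len(bridge_pool[chrom]) == 0:
            continue
        p = gene_prom_anchor[g]
        b = nearest(bridge_pool[chrom], p)
        h = nearest(hub_idx_by_chrom[chrom], b)
        add_loop(h, b, planted_mu(), 0.0, is_hub=True)
        mu_bp = config.base_count_mean * 2.0 * rng.uniform(0.9, 1.1)
        key = add_loop(b, p, mu_bp, mu_bp / 6.0 if kd_active else mu_bp, is_bridge_bp=True)
        if key is not None:
            ebp_bridge_loops.append(key)

    # ---- baseline + hub loops (de novo anchors are silent when TF is on) --
    for chrom, sub in by_chrom.items():
        active = sub[~sub["is_de_novo"]]
        order = np.argsort(active["start"].to_numpy())
        local_idx = active["index"].to_numpy()[order]
        local_mid = mids[local_idx]
        n_local = len(local_idx)
        if n_local < 2:
            continue
        for pos in range(n_local):
            gidx = local_idx[pos]
            hub = bool(peaks.at[gidx, "is_hub_anchor"])
            lam = config.base_degree * (config.hub_degree_boost if hub else 1.0)
            k = rng.poisson(lam)
            for _ in range(k):
                scale = config.hub_span_scale if hub else config.base_span_scale
                span = rng.exponential(scale) + config.site_spacing
                target = local_mid[pos] + (span if rng.random() < 0.5 else -span)
                j = int(np.clip(np.searchsorted(local_mid, target), 0, n_local - 1))
                if local_idx[j] == gidx:
                    j = j + 1 if j + 1 < n_local else j - 1
                pidx = local_idx[j]
                d = abs(local_mid[pos] - mids[pidx])
                add_loop(gidx, pidx, count_mu(d, hub), 0.0, is_hub=hub)

    # ---- TF-off fate of hub loops ---------------------------------------
    hub_keys = [k for k, r in loop_records.items() if r["is_hub"]]
    n_lost = int(round(config.knockdown_loss_fraction * len(hub_keys)))
    lost = set()
    if n_lost:
        sel = rng.choice(len(hub_keys), size=n_lost, replace=False)
        lost = {hub_keys[s] for s in sel}
    for key, rec in loop_records.items():
        if rec["is_bridge_bp"]:
            continue
        rec["mu_off"] = 0.0 if key in lost else rec["mu_on"]

    # ---- planted novel loops --------------------------------------------
    novel_keys = []
    novel_targets = []
    prom_by_chrom = {
        chrom: sub.loc[sub["kind"] == "promoter", "index"].to_numpy()
        for chrom, sub in by_chrom.items()
    }
    for idx, row in peaks[peaks["is_de_novo"]].iterrows():
        chrom = row["chrom"]
        proms = prom_by_chrom.get(chrom, np.array([]))
        cands = [p for p in proms if peaks.at[p, "link"] not in reserved]
        if not len(cands):
            continue
        dists = np.abs(mids[np.array(cands)] - mids[idx])
        p = int(np.array(cands)[np.argmin(dists)])
        mu_off = 12.0 * rng.uniform(0.9, 1.3)
        key = add_loop(idx, p, 0.15, mu_off, is_novel=True)
        if key is not None:
            novel_keys.append(key)
            g = peaks.at[p, "link"]
            reserved.add(g)
            novel_targets.append(g)
        if rng.random() < 0.5 and len(bridge_pool[chrom]):
            b = int(bridge_pool[chrom][rng.integers(len(bridge_pool[chrom]))])
            key2 = add_loop(idx, b, 0.15, 12.0 * rng.uniform(0.9, 1.3), is_novel=True)
            if key2 is not None:
                novel_keys.append(key2)

    # ---- replicate count draws ------------------------------------------
    keys = sorted(loop_records)
    rows = []
    for (i, j) in keys:
        rec = loop_records[(i, j)]
        a, b = peaks.iloc[i], peaks.iloc[j]
        if a["start"] > b["start"]:
            a, b = b, a
        row = dict(
            chrom1=a["chrom"], start1=int(a["start"]), end1=int(a["end"]),
            chrom2=b["chrom"], start2=int(b["start"]), end2=int(b["end"]),
        )
        row["name"] = loop_key(row["chrom1"], row["start1"], row["end1"],
                               row["chrom2"], row["start2"], row["end2"])
        for cond, mu in ((COND_ON, rec["mu_on"]), (COND_OFF, rec["mu_off"])):
            for r in (1, 2):
                row[f"{cond}_rep{r}"] = int(_negbin(rng, np.array(mu), config.nb_dispersion))
        row.update(
            mu_on=rec["mu_on"], mu_off=rec["mu_off"], is_hub=rec["is_hub"],
            is_novel=rec["is_novel"], is_bridge_bp=rec["is_bridge_bp"],
        )
        rows.append(row)
    loops = pd.DataFrame(rows)

    key_to_name = {}
    for (i, j), row in zip(keys, rows):
        key_to_name[(i, j)] = row["name"]
    dataset.loops = loops
    dataset.truth.update(
        hub_loops=sorted(key_to_name[k] for k in hub_keys),
        lost_hub_loops=sorted(key_to_name[k] for k in lost),
        novel_loops=sorted(key_to_name[k] for k in novel_keys),
        bridge_bp_loops=sorted(key_to_name[k] for k in ebp_bridge_loops),
        target_genes=dict(
            tss_direct=sorted(tss_direct),
            e_p=sorted(set(ep_genes) | set(mixed_genes)),
            e_b_p=sorted(ebp_genes),
            mixed=sorted(mixed_genes),
        ),
        novel_loop_targets=sorted(set(novel_targets)),
    )
    return dataset


# --------------------------------------------------------------- expression

def simulate_expression(dataset: SyntheticDataset, config: SimulationConfig) -> SyntheticDataset:
    """FPKM-like expression per condition, coupled to the planted loops.

    Planted TF-target genes (all modes) lose ``expression_effect`` log2
    units after depletion; novel-loop targets gain the same amount; a set
    of non-target genes inside B compartments loses half that amount,
    emulating repression by strengthened B-B contacts. Planted-effect genes
    get high baselines so the fold-change gates are meaningful.
    """
    rng = config.rng(_STAGE_EXPR)
    genes = dataset.genes
    truth = dataset.truth
    targets = set()
    for mode_genes in truth["target_genes"].values():
        targets.update(mode_genes)
    novel = set(truth["novel_loop_targets"])

    labels_on = truth["_internal"]["labels"][COND_ON]
    b_candidates = []
    for row in genes.itertuples(index=False):
        lab = labels_on[row.chrom]
        b = row.tss // config.bin_size
        if 0 <= b < len(lab) and lab[b] == "B" and row.gene_id not in targets | novel:
            b_candidates.append(row.gene_id)
    n_b = min(30, len(b_candidates))
    b_repressed = sorted(
        np.array(b_candidates)[rng.choice(len(b_candidates), size=n_b, replace=False)]
    ) if n_b else []

    base = rng.lognormal(2.0, 1.0, size=len(genes))
    planted = targets | novel | set(b_repressed)
    for i, g in enumerate(genes["gene_id"]):
        if g in planted:
            base[i] = rng.uniform(5.0, 50.0)
    delta = np.zeros(len(genes))
    gene_ids = genes["gene_id"].to_numpy()
    delta[np.isin(gene_ids, list(targets))] = -config.expression_effect
    delta[np.isin(gene_ids, list(novel))] = config.expression_effect
    delta[np.isin(gene_ids, b_repressed)] = -0.5 * config.expression_effect
    if config.knockdown_loss_fraction == 0:
        delta[:] = 0.0

    on = base * rng.uniform(0.95, 1.05, size=len(genes))
    off = base * (2.0 ** delta) * rng.uniform(0.95, 1.05, size=len(genes))
    expr = pd.DataFrame({COND_ON: np.round(on, 4), COND_OFF: np.round(off, 4)},
                        index=pd.Index(gene_ids, name="gene_id"))
    dataset.expression = expr
    dataset.truth["b_repressed_genes"] = list(b_repressed)
    return dataset


# ---------------------------------------------------------- contact matrix

def simulate_contact_matrix(
    dataset: SyntheticDataset, config: SimulationConfig, condition: str
) -> dict[str, ContactMatrix]:
    """Poisson contact maps: power-law decay x A/B checkerboard x TAD blocks.

    Expected count at bin distance d is proportional to d^-decay_exponent;
    same-compartment pairs are multiplied by 1 + s_eff and cross-compartment
    pairs by 1 - s_eff, with s_eff = segregation * (1 - mixing) damped
    locally at planted switch sites; within-TAD pairs get an extra
    (1 + tad_boost) factor. Matrices are symmetric by construction.
    """
    stage = _STAGE_MATRIX_ON if condition == COND_ON else _STAGE_MATRIX_OFF
    rng = config.rng(stage)
    mixing = config.mixing_on if condition == COND_ON else config.mixing_off
    internal = dataset.truth["_internal"]
    labels = internal["labels"][condition]
    out = {}
    for chrom, nb in dataset.truth["chromosomes"].items():
        if nb < 4:
            raise ValueError(f"{chrom}: fewer than 4 bins")
        idx = np.arange(nb)
        d = np.abs(idx[:, None] - idx[None, :]).astype(float)
        base = config.contact_depth * np.maximum(d, 1.0) ** (-config.decay_exponent)
        np.fill_diagonal(base, config.contact_depth * config.diagonal_factor)
        lab = np.asarray(labels[chrom])
        same = lab[:, None] == lab[None, :]
        damp = internal["damp"][chrom]
        s_eff = config.segregation * (1.0 - mixing) * np.outer(damp, damp)
        comp = np.where(same, 1.0 + s_eff, 1.0 - s_eff)
        tid = internal["tad_id"][chrom]
        tadm = np.where(tid[:, None] == tid[None, :], 1.0 + config.tad_boost, 1.0)
        mu = base * comp * tadm
        iu, ju = np.triu_indices(nb)
        counts = rng.poisson(mu[iu, ju])
        m = np.zeros((nb, nb))
        m[iu, ju] = counts
        m[ju, iu] = counts
        out[chrom] = ContactMatrix(chrom=chrom, bin_size=config.bin_size, matrix=m)
    dataset.matrices[condition] = out
    return out


# ------------------------------------------------------------ orchestration

def simulate_dataset(config: SimulationConfig | None = None, **kwargs) -> SyntheticDataset:
    """Full dataset: features, loops, expression and both contact maps."""
    if config is None:
        config = SimulationConfig(**kwargs)
    ds = simulate_features(config)
    simulate_loops(ds, config)
    simulate_expression(ds, config)
    for cond in CONDITIONS:
        simulate_contact_matrix(ds, config, cond)
    return ds


def write_fixture(dataset: SyntheticDataset, directory) -> None:
    """Write the dataset as plain-text files plus a ground-truth manifest.

    Per-replicate BEDPE files list the loops with a nonzero count in that
    replicate. Deterministic float formatting makes two writes of the same
    dataset byte-identical.
    """
    from hubweaver import io as hio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cond in CONDITIONS:
        hio.write_narrowpeak(dataset.peaks, directory / f"peaks_{cond}.narrowPeak",
                             signal_col=f"signal_{cond}")
        hio.write_bedgraph(dataset.tracks[cond], directory / f"h3k27ac_{cond}.bedGraph")
        for r in (1, 2):
            col = f"{cond}_rep{r}"
            sub = dataset.loops[dataset.loops[col] > 0]
            hio.write_bedpe(sub, directory / f"loops_{cond}_rep{r}.bedpe", count_col=col)
        hio.write_triplet_matrices(
            dataset.matrices[cond], directory / f"matrix_{cond}.tsv",
            directory / "bins.tsv" if cond == COND_ON else None,
        )
    tf = dataset.tf_peaks.copy()
    tf["name"] = tf["name"] + "|" + tf["motif_class"]
    hio.write_bed(tf, directory / "tf_peaks.bed")
    hio.write_bed(dataset.repeat_annotation, directory / "repeats.bed")
    hio.write_gene_table(dataset.genes, directory / "genes.bed")
    hio.write_expression(dataset.expression, directory / "expression.tsv")
    truth = {k: v for k, v in dataset.truth.items() if not k.startswith("_")}
    hio.write_json(truth, directory / "truth.json")
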