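"""End-to-end orchestration: tracks -> loops -> compartments/TADs ->
targets -> networks, from a fixture-style input directory to TSV/bedGraph
outputs plus a machine-readable JSON run report.

The pipeline is a pure function of (inputs, thresholds, seed): rerunning
with the same configuration produces byte-identical text outputs. Stage
failures abort with the stage name; partial outputs are retained.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from hubweaver import io as hio
from hubweaver import loops as hloops
from hubweaver import matrix as hmatrix
from hubweaver import network as hnetwork
from hubweaver import targets as htargets
from hubweaver import tracks as htracks
from hubweaver.defs import COND_OFF, COND_ON, CONDITIONS, COUNT_COLS

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Input paths and every analysis threshold, with the study defaults."""

    input_dir: str
    out_dir: str
    # thresholds (defaults follow the analysis recipe the package implements)
    min_count: int = 5
    strict_reproducibility: bool = False
    denovo_fold: float = 4.0
    denovo_baseline: float = 5.0
    novel_fold: float = 4.0
    novel_baseline: float = 2.0
    diff_fold: float = 2.0
    bridge_decrease: float = 2.0
    expression_fold: float = 1.5
    promoter_window: int = 1000
    signal_window: int = 2000
    bin_size: int = 40_000
    insulation_window: int = 12
    boundary_prominence: float = 0.1
    exclusion_radius: int = 1
    n_quantiles: int = 10
    n_shuffles: int = 20
    pseudocount: float = 0.5
    expression_pseudocount: float = 0.1
    seed: int = 0

    def path(self, name: str) -> Path:
        return Path(self.input_dir) / name

    def input_files(self) -> list[Path]:
        files = [
            "tf_peaks.bed", "repeats.bed", "genes.bed", "expression.tsv", "bins.tsv",
        ]
        for cond in CONDITIONS:
            files += [
                f"peaks_{cond}.narrowPeak", f"h3k27ac_{cond}.bedGraph",
                f"matrix_{cond}.tsv", f"loops_{cond}_rep1.bedpe", f"loops_{cond}_rep2.bedpe",
            ]
        return [self.path(f) for f in files]

    def validate(self) -> None:
        missing = [str(p) for p in self.input_files() if not p.exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        for name, v in (("min_count", self.min_count), ("denovo_fold", self.denovo_fold),
                        ("novel_fold", self.novel_fold), ("diff_fold", self.diff_fold),
                        ("expression_fold", self.expression_fold)):
            if v <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        section = data.get("run", data)
        return cls(**section)


def _read_tf_peaks(path) -> pd.DataFrame:
    tf = hio.read_bed(path)
    split = tf["name"].str.rsplit("|", n=1, expand=True)
    tf["name"] = split[0]
    tf["motif_class"] = split[1].fillna("single") if split.shape[1] > 1 else "single"
    return tf


def _condition_norm_cols():
    return {cond: f"norm_{cond}" for cond in CONDITIONS}


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the JSON-serializable run report."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {k: v for k, v in asdict(config).items()}}
    stage = "load"
    try:
        genes = hio.read_gene_table(config.path("genes.bed"))
        tf_peaks = _read_tf_peaks(config.path("tf_peaks.bed"))
        repeats = hio.read_bed(config.path("repeats.bed"))
        expression = hio.read_expression(config.path("expression.tsv"))
        tracks = {c: hio.read_bedgraph(config.path(f"h3k27ac_{c}.bedGraph")) for c in CONDITIONS}
        peak_tables = {c: hio.read_narrowpeak(config.path(f"peaks_{c}.narrowPeak")) for c in CONDITIONS}

        stage = "tracks"
        union_peaks = (
            pd.concat([peak_tables[c][["chrom", "start", "end", "name"]] for c in CONDITIONS])
            .drop_duplicates()
            .sort_values(["chrom", "start", "name"])
            .reset_index(drop=True)
        )
        for cond in CONDITIONS:
            union_peaks[f"signal_{cond}"] = htracks.quantify_signal(
                tracks[cond], union_peaks, window_bp=config.signal_window
            )
        union_peaks["location_class"] = htracks.classify_peak_locations(
            union_peaks, genes, window_bp=config.promoter_window
        )
        denovo_mask = htracks.call_de_novo_peaks(
            union_peaks, f"signal_{COND_ON}", f"signal_{COND_OFF}",
            fold_min=config.denovo_fold, baseline_max=config.denovo_baseline,
            pseudocount=config.pseudocount,
        )
        denovo = union_peaks[denovo_mask]
        hio.write_bed(denovo.assign(score=0, strand="."), out_dir / "denovo_peaks.bed")
        report["tracks"] = {
            "n_union_peaks": int(len(union_peaks)),
            "n_promoter_peaks": int((union_peaks["location_class"] == "promoter").sum()),
            "n_de_novo_peaks": int(len(denovo)),
            "de_novo_peaks": denovo["name"].tolist(),
        }

        stage = "loops"
        reps = {
            (cond, r): hio.read_bedpe(config.path(f"loops_{cond}_rep{r}.bedpe"))
            for cond in CONDITIONS for r in (1, 2)
        }
        retained = {
            cond: hloops.filter_reproducible_loops(
                reps[(cond, 1)], reps[(cond, 2)], min_count=config.min_count,
                strict=config.strict_reproducibility,
            )
            for cond in CONDITIONS
        }
        union = (
            pd.concat([retained[c][hloops.LOOP_ANCHOR_COLS + ["name"]] for c in CONDITIONS])
            .drop_duplicates("name")
            .sort_values("name")
            .reset_index(drop=True)
        )
        for cond in CONDITIONS:
            names = set(retained[cond]["name"])
            union[f"retained_{cond}"] = union["name"].isin(names)
            for r in (1, 2):
                rep = hloops.add_loop_names(reps[(cond, r)])
                cmap = rep.set_index("name")["score"]
                union[f"{cond}_rep{r}"] = union["name"].map(cmap).fillna(0).astype(float)
        union, size_factors = hloops.normalize_loop_counts(union, COUNT_COLS)
        for cond in CONDITIONS:
            union[f"norm_{cond}"] = union[[f"norm_{cond}_rep1", f"norm_{cond}_rep2"]].mean(axis=1)
        union = hloops.classify_loops(union, union_peaks, tf_peaks, repeats)
        union = hloops.differential_loops(
            union, f"norm_{COND_ON}", f"norm_{COND_OFF}",
            fold_threshold=config.diff_fold, pseudocount=config.pseudocount,
        )
        union["novel"] = hloops.call_novel_loops(
            union, f"norm_{COND_ON}", f"norm_{COND_OFF}",
            fold_min=config.novel_fold, baseline_max=config.novel_baseline,
            pseudocount=config.pseudocount,
        )
        loops_on = union[union[f"retained_{COND_ON}"]].reset_index(drop=True)
        anchors = hloops.anchor_table(union)
        anchors["motif_class"] = htracks.annotate_anchor_class(anchors, tf_peaks, repeats)
        anchor_classes = anchors.set_index("anchor_id")["motif_class"]
        connectivity = hloops.connectivity_by_motif(loops_on, anchor_classes, f"norm_{COND_ON}")
        length_stats = hloops.loop_length_stats(loops_on)
        null_stats = hloops.expected_loop_length_null(
            loops_on, anchors, n_shuffles=config.n_shuffles, seed=config.seed
        )
        report["loops"] = {
            "n_retained": {c: int(len(retained[c])) for c in CONDITIONS},
            "n_union": int(len(union)),
            "size_factors": {k: round(v, 6) for k, v in size_factors.items()},
            "n_tf_associated_on": int(loops_on["tf_associated"].sum()),
            "status_counts": union["status"].value_counts().to_dict(),
            "n_novel": int(union["novel"].sum()),
            "novel_loops": sorted(union.loc[union["novel"], "name"]),
            "connectivity_by_motif": connectivity.reset_index().to_dict(orient="records"),
            "length_stats": length_stats.reset_index().to_dict(orient="records"),
            "length_null": null_stats.reset_index().to_dict(orient="records"),
        }

        stage = "compartments_tads"
        matrices = {
            c: hio.read_triplet_matrices(config.path(f"matrix_{c}.tsv"), config.path("bins.tsv"))
            for c in CONDITIONS
        }
        chroms = sorted(matrices[COND_ON])
        oe, profiles, segs, strengths = {}, {}, {}, {}
        for cond in CONDITIONS:
            oe[cond], profiles[cond], segs[cond], strengths[cond] = {}, {}, {}, {}
            for chrom in chroms:
                cm = matrices[cond][chrom]
                oe_cm = hmatrix.observed_over_expected(cm)
                oe[cond][chrom] = oe_cm
                sig = htracks.bin_track(
                    tracks[cond][tracks[cond]["chrom"] == chrom], cm.n_bins, cm.bin_size, cm.start
                )
                profiles[cond][chrom] = hmatrix.call_compartments(oe_cm, sig)
                segs[cond][chrom] = hmatrix.insulation_profile(
                    oe_cm, window_bins=config.insulation_window,
                    prominence=config.boundary_prominence,
                )
                strengths[cond][chrom] = hmatrix.compartment_strength(
                    oe_cm, profiles[cond][chrom].labels, exclusion_radius=config.exclusion_radius
                )
        repress = {
            chrom: hmatrix.repress_ratio(
                oe[COND_ON][chrom], oe[COND_OFF][chrom], profiles[COND_ON][chrom].labels,
                exclusion_radius=config.exclusion_radius,
            )
            for chrom in chroms
        }
        saddles = {
            cond: {
                chrom: hmatrix.saddle_statistics(
                    oe[cond][chrom], profiles[cond][chrom].e1,
                    n_quantiles=config.n_quantiles,
                    exclusion_radius=config.exclusion_radius,
                )
                for chrom in chroms
            }
            for cond in CONDITIONS
        }
        changes = {
            chrom: hmatrix.interaction_change_test(
                oe[COND_ON][chrom], oe[COND_OFF][chrom], profiles[COND_ON][chrom].labels,
                labels_off=profiles[COND_OFF][chrom].labels,
                exclusion_radius=config.exclusion_radius,
            )
            for chrom in chroms
        }
        ins_corr = float(np.mean([
            hmatrix.insulation_concordance(segs[COND_ON][c], segs[COND_OFF][c]) for c in chroms
        ]))
        tf_trees = None
        switch_tables = {}
        from hubweaver import intervals as hintervals

        tf_trees = hintervals.build_trees(tf_peaks)
        for chrom in chroms:
            prof = profiles[COND_ON][chrom]
            nb = len(prof.labels)
            tf_bins = np.zeros(nb, dtype=bool)
            for b in range(nb):
                s = prof.start + b * prof.bin_size
                if hintervals.query(tf_trees, chrom, s, s + prof.bin_size):
                    tf_bins[b] = True
            switch_tables[chrom] = hmatrix.compartment_switch_table(
                profiles[COND_ON][chrom], profiles[COND_OFF][chrom], tf_bins
            )
        switch_all = pd.concat(switch_tables.values(), keys=switch_tables.keys())
        union = hmatrix.classify_loop_topology(union, segs[COND_ON], profiles[COND_ON])
        crossing = hmatrix.crossing_summary(union[union[f"retained_{COND_ON}"]])

        def _pooled_switch(stratum):
            rows = [t.loc[stratum] for t in switch_tables.values()]
            n = sum(r["n_bins"] for r in rows)
            sw = sum(r["frac_switch"] * r["n_bins"] for r in rows)
            return float(sw / n) if n else float("nan")

        report["compartments_tads"] = {
            "insulation_correlation": round(ins_corr, 6),
            "n_boundaries": {
                cond: {c: int(len(segs[cond][c].boundaries)) for c in chroms}
                for cond in CONDITIONS
            },
            "boundaries": {
                cond: {c: segs[cond][c].boundaries.tolist() for c in chroms}
                for cond in CONDITIONS
            },
            "ab_labels": {
                cond: {c: "".join(np.where(profiles[cond][c].labels == "", ".",
                                           profiles[cond][c].labels)) for c in chroms}
                for cond in CONDITIONS
            },
            "mean_strength": {
                cond: float(np.nanmean(np.concatenate(list(strengths[cond].values()))))
                for cond in CONDITIONS
            },
            "saddle_corners": {
                cond: {c: dict(aa=saddles[cond][c].aa_corner, bb=saddles[cond][c].bb_corner,
                               ab=saddles[cond][c].ab_corner) for c in chroms}
                for cond in CONDITIONS
            },
            "interaction_changes": {
                c: changes[c].reset_index().to_dict(orient="records") for c in chroms
            },
            "switch_fraction": {
                "tf_bound": _pooled_switch("tf_bound"), "tf_free": _pooled_switch("tf_free"),
            },
            "crossing_summary": crossing.reset_index().to_dict(orient="records"),
        }

        stage = "targets"
        contexts = {"A673": (COND_ON, COND_OFF)}
        connected = htargets.identify_connected_genes(
            loops_on, tf_peaks, genes, union_peaks,
            f"norm_{COND_ON}", f"norm_{COND_OFF}",
            window_bp=config.promoter_window, bridge_decrease=config.bridge_decrease,
            pseudocount=config.pseudocount,
        )
        target_df = htargets.select_target_genes(
            connected, expression, contexts, min_fold_down=config.expression_fold,
            pseudocount=config.expression_pseudocount,
        )
        novel_targets = htargets.select_novel_loop_targets(
            union[union["novel"]], genes, expression, contexts,
            min_fold_up=config.expression_fold, pseudocount=config.expression_pseudocount,
            window_bp=config.promoter_window,
        )
        b_expr = htargets.b_compartment_expression(
            genes, profiles[COND_ON], repress, set(target_df["gene_id"]),
            expression, COND_ON, COND_OFF,
        )
        scores = (
            htargets.gene_set_score(expression, list(target_df["gene_id"]))
            if len(target_df) else pd.Series(dtype=float)
        )
        report["targets"] = {
            "n_connected": int(len(connected)),
            "modes": {g: list(m) for g, m in zip(connected["gene_id"], connected["modes"])},
            "n_targets": int(len(target_df)),
            "target_genes": sorted(target_df["gene_id"]),
            "target_modes": {g: list(m) for g, m in zip(target_df["gene_id"], target_df["modes"])},
            "n_novel_targets": int(len(novel_targets)),
            "novel_target_genes": sorted(novel_targets["gene_id"]),
            "b_compartment_expression": {k: v for k, v in b_expr.items() if k != "genes"},
            "target_set_score": {k: round(float(v), 6) for k, v in scores.items()},
        }

        stage = "networks"
        graphs = {}
        for cond in CONDITIONS:
            sub = union[union[f"retained_{cond}"]]
            g = hnetwork.build_network(sub, f"norm_{cond}")
            hnetwork.set_node_motifs(g, anchor_classes)
            graphs[cond] = g
        frac = hnetwork.compare_fractionation(graphs[COND_ON], graphs[COND_OFF])
        decomp = {c: hnetwork.module_decomposition(graphs[c]) for c in CONDITIONS}
        report["networks"] = {
            "on": frac["on"], "off": frac["off"], "delta": frac["delta"],
        }

        stage = "write"
        union_out = union.drop(columns=["anchors"], errors="ignore")
        union_out.to_csv(out_dir / "loops_annotated.tsv", sep="\t", index=False,
                         float_format="%.6g")
        connectivity.to_csv(out_dir / "anchor_connectivity.tsv", sep="\t", float_format="%.6g")
        length_stats.to_csv(out_dir / "loop_length_stats.tsv", sep="\t", float_format="%.6g")
        target_df.to_csv(out_dir / "targets.tsv", sep="\t", index=False)
        novel_targets.to_csv(out_dir / "novel_targets.tsv", sep="\t", index=False)
        switch_all.to_csv(out_dir / "switch_table.tsv", sep="\t", float_format="%.6g")
        for cond in CONDITIONS:
            rows = []
            for chrom in chroms:
                p = profiles[cond][chrom]
                for b in range(len(p.e1)):
                    if np.isfinite(p.e1[b]):
                        s = p.start + b * p.bin_size
                        rows.append((chrom, s, s + p.bin_size, p.e1[b]))
            hio.write_bedgraph(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]),
                               out_dir / f"e1_{cond}.bedGraph")
            decomp[cond].drop(columns=["anchors"]).to_csv(
                out_dir / f"components_{cond}.tsv", sep="\t", float_format="%.6g"
            )
        rows = []
        for chrom in chroms:
            r = repress[chrom]
            p = profiles[COND_ON][chrom]
            for b in range(len(r)):
                if np.isfinite(r[b]):
                    s = p.start + b * p.bin_size
                    rows.append((chrom, s, s + p.bin_size, r[b]))
        hio.write_bedgraph(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]),
                           out_dir / "repress_ratio.bedGraph")
        hio.write_json(report, out_dir / "report.json")
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    return report


# --------------------------------------------------------------- validation

def _precision_recall(predicted: set, truth: set) -> dict:
    tp = len(predicted & truth)
    return dict(
        n_predicted=len(predicted), n_truth=len(truth), n_tp=tp,
        precision=tp / len(predicted) if predicted else float("nan"),
        recall=tp / len(truth) if truth else float("nan"),
    )


def validate_against_truth(report: dict, truth: dict) -> dict:
    """Precision/recall of every detector against the planted ground truth.

    Compares de novo peaks, novel loops, target genes per connectivity
    mode, A/B labels (per-bin agreement, over bins labeled in both) and TAD
    boundaries (recall within ±1 bin).
    """
    out = {}
    out["de_novo_peaks"] = _precision_recall(
        set(report["tracks"]["de_novo_peaks"]), set(truth["de_novo_peaks"])
    )
    out["novel_loops"] = _precision_recall(
        set(report["loops"]["novel_loops"]), set(truth["novel_loops"])
    )
    modes_detected = report["targets"]["target_modes"]
    per_mode = {}
    for mode, genes in truth["target_genes"].items():
        if mode == "mixed":
            hit = {g for g in genes if len(modes_detected.get(g, [])) >= 2}
        else:
            hit = {g for g in genes if mode in modes_detected.get(g, [])}
        per_mode[mode] = dict(
            n_truth=len(genes), n_recovered=len(hit),
            recall=len(hit) / len(genes) if genes else float("nan"),
        )
    out["target_genes_by_mode"] = per_mode
    out["novel_loop_targets"] = _precision_recall(
        set(report["targets"]["novel_target_genes"]), set(truth["novel_loop_targets"])
    )

    ab = {}
    for cond, by_chrom in report["compartments_tads"]["ab_labels"].items():
        agree = total = 0
        for chrom, called in by_chrom.items():
            planted = truth["ab_labels"][cond][chrom]
            if len(called) != len(planted):
                raise ValueError(f"{chrom}: bin count mismatch between report and truth")
            for a, b in zip(called, planted):
                if a in "AB":
                    total += 1
                    agree += a == b
        ab[cond] = dict(n_bins=total, agreement=agree / total if total else float("nan"))
    out["ab_labels"] = ab

    tads = {}
    for cond, by_chrom in report["compartments_tads"]["boundaries"].items():
        found = n_truth = 0
        for chrom, called in by_chrom.items():
            planted = truth["tad_boundaries"][chrom]
            called_arr = np.asarray(called)
            for b in planted:
                n_truth += 1
                if len(called_arr) and np.min(np.abs(called_arr - b)) <= 1:
                    found += 1
        tads[cond] = dict(n_truth=n_truth, n_recovered=found,
                          recall=found / n_truth if n_truth else float("nan"))
    out["tad_boundaries"] = tads
    return out
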