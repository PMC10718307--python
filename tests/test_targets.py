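"""Connectivity modes, target-gene gates and gene-set scoring."""

import numpy as np
import pandas as pd
import pytest

from hubweaver import targets as ht
from tests.conftest import toy_loops


def build_inputs(bp_on=25.0, bp_off=10.0, with_tss_tf=False, with_ep=False, with_ebp=False):
    """A 1-gene universe: promoter P at 100 kb, TF enhancer E at 300 kb,
    bridge B at 500 kb. Loops are added per requested mode."""
    genes = pd.DataFrame({"chrom": ["chr1"], "tss": [100_000], "strand": ["+"],
                          "gene_id": ["g1"]})
    tf_rows = [("chr1", 300_400, 301_400, "tf1")]
    if with_tss_tf:
        tf_rows.append(("chr1", 100_300, 100_700, "tf2"))  # inside the TSS window
    tf_peaks = pd.DataFrame(tf_rows, columns=["chrom", "start", "end", "name"])
    peaks = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "start": [99_000, 300_000, 500_000],
            "end": [101_000, 302_000, 502_000],
            "location_class": ["promoter", "distal", "distal"],
        }
    )
    rows = []
    if with_ep:
        rows.append(("chr1", 99_000, 101_000, 300_000, 302_000, {"on": 30.0, "off": 5.0}))
    if with_ebp:
        rows.append(("chr1", 300_000, 302_000, 500_000, 502_000, {"on": 40.0, "off": 8.0}))
        rows.append(("chr1", 99_000, 101_000, 500_000, 502_000, {"on": bp_on, "off": bp_off}))
    loops = toy_loops(rows)
    if len(loops):
        from hubweaver.loops import add_loop_names, anchor_table

        loops = add_loop_names(loops)
        loops["anchor1_id"] = [f"chr1:{s}-{e}" for s, e in zip(loops["start1"], loops["end1"])]
        loops["anchor2_id"] = [f"chr1:{s}-{e}" for s, e in zip(loops["start2"], loops["end2"])]
    else:
        loops = loops.assign(name=[], anchor1_id=[], anchor2_id=[], on=[], off=[])
        for c in ("chrom1", "start1", "end1", "chrom2", "start2", "end2"):
            loops[c] = []
    return genes, tf_peaks, peaks, loops


def connect(**kw):
    genes, tf_peaks, peaks, loops = build_inputs(**kw)
    return ht.identify_connected_genes(loops, tf_peaks, genes, peaks, "on", "off")


class TestConnectivityModes:
    def test_tss_direct(self):
        out = connect(with_tss_tf=True)
        assert out.iloc[0]["modes"] == ("tss_direct",)

    def test_enhancer_promoter_chain(self):
        out = connect(with_ep=True)
        assert out.iloc[0]["modes"] == ("e_p",)

    def test_bridge_chain_fires_on_decrease(self):
        out = connect(with_ebp=True, bp_on=25.0, bp_off=10.0)  # 2.5-fold down
        assert "e_b_p" in out.iloc[0]["modes"]
        assert out.iloc[0]["bridges"]

    def test_bridge_chain_silent_when_stable(self):
        out = connect(with_ebp=True, bp_on=12.0, bp_off=10.0)  # 1.2-fold
        assert len(out) == 0 or "e_b_p" not in out.iloc[0]["modes"]

    def test_mixed_flag(self):
        out = connect(with_tss_tf=True, with_ep=True)
        row = out.iloc[0]
        assert row["mixed"]
        assert set(row["modes"]) == {"tss_direct", "e_p"}

    def test_modes_monotone_in_loops(self):
        # adding loops can only add modes
        base = connect(with_ep=True)
        more = connect(with_ep=True, with_ebp=True)
        assert set(base.iloc[0]["modes"]) <= set(more.iloc[0]["modes"])


EXPR = pd.DataFrame({"on": [30.0, 10.0, 5.0], "off": [10.0, 9.0, 50.0]},
                    index=pd.Index(["g1", "g2", "g3"], name="gene_id"))
CONTEXTS = {"A673": ("on", "off")}


class TestTargetSelection:
    def connected(self, gene):
        return pd.DataFrame({"gene_id": [gene], "modes": [("e_p",)], "mixed": [False],
                             "n_support": [1], "bridges": [()]})

    def test_three_fold_down_selected(self):
        out = ht.select_target_genes(self.connected("g1"), EXPR, CONTEXTS)
        assert list(out["gene_id"]) == ["g1"]

    def test_weak_decrease_rejected(self):
        out = ht.select_target_genes(self.connected("g2"), EXPR, CONTEXTS)
        assert len(out) == 0  # 1.11-fold is below the 1.5-fold gate

    def test_connectivity_gates_selection(self):
        # g1-level decrease but the gene is not in the connected set
        out = ht.select_target_genes(self.connected("g3"), EXPR, CONTEXTS)
        assert "g1" not in set(out["gene_id"])

    def test_output_subset_of_connected(self):
        conn = pd.concat([self.connected(g) for g in ("g1", "g2", "g3")])
        out = ht.select_target_genes(conn, EXPR, CONTEXTS)
        assert set(out["gene_id"]) <= set(conn["gene_id"])


class TestNovelLoopTargets:
    def novel(self, gene_tss=100_000):
        genes = pd.DataFrame({"chrom": ["chr1"], "tss": [gene_tss], "strand": ["+"],
                              "gene_id": ["g1"]})
        loops = toy_loops([("chr1", 99_000, 101_000, 500_000, 502_000, {})])
        return genes, loops

    def run(self, on, off, gene_tss=100_000):
        genes, loops = self.novel(gene_tss)
        expr = pd.DataFrame({"on": [on], "off": [off]},
                            index=pd.Index(["g1"], name="gene_id"))
        return ht.select_novel_loop_targets(loops, genes, expr, {"A673": ("on", "off")})

    def test_two_fold_up_selected(self):
        assert list(self.run(10.0, 20.5)["gene_id"]) == ["g1"]

    def test_weak_increase_rejected(self):
        assert len(self.run(10.0, 14.0)) == 0  # 1.4-fold

    def test_no_novel_loop_at_promoter(self):
        # promoter far from every novel-loop anchor
        assert len(self.run(10.0, 100.0, gene_tss=5_000_000)) == 0


class TestBCompartmentExpression:
    def run(self, label, score, gene="g1", targets=()):
        from hubweaver.matrix import CompartmentProfile

        genes = pd.DataFrame({"chrom": ["chr1"], "tss": [150], "strand": ["+"],
                              "gene_id": [gene]})
        prof = CompartmentProfile(
            chrom="chr1", bin_size=100, e1=np.array([0.1, -0.1]),
            labels=np.array(["A", label]), signal=np.zeros(2),
        )
        expr = pd.DataFrame({"on": [8.0], "off": [4.0]},
                            index=pd.Index([gene], name="gene_id"))
        return ht.b_compartment_expression(
            genes, {"chr1": prof}, {"chr1": np.array([np.nan, score])},
            set(targets), expr, "on", "off",
        )

    def test_selected_gene_means(self):
        out = self.run("B", 0.5)
        assert out["n_genes"] == 1
        assert out["mean_off"] < out["mean_on"]

    def test_a_compartment_excluded(self):
        assert self.run("A", 0.5)["n_genes"] == 0

    def test_direct_target_excluded(self):
        assert self.run("B", 0.5, targets=("g1",))["n_genes"] == 0

    def test_negative_change_score_excluded(self):
        assert self.run("B", -0.2)["n_genes"] == 0


class TestGeneSetScore:
    def test_identical_samples_score_zero(self):
        expr = pd.DataFrame({"s1": [5.0, 2.0], "s2": [5.0, 2.0], "s3": [5.0, 2.0]},
                            index=["g1", "g2"])
        scores = ht.gene_set_score(expr, ["g1", "g2"])
        assert np.allclose(scores, 0.0)

    def test_single_gene_z_scores(self):
        expr = pd.DataFrame({"s1": [10.0], "s2": [20.0], "s3": [30.0]}, index=["g1"])
        scores = ht.gene_set_score(expr, ["g1"])
        # oracle: sample-SD standardization of (10, 20, 30) gives (-1, 0, 1)
        assert np.allclose(scores.to_numpy(), [-1.0, 0.0, 1.0])

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.uniform(1, 50, (4, 5)),
                            index=list("abcd"), columns=[f"s{i}" for i in range(5)])
        base = ht.gene_set_score(expr, list("abcd"))
        shifted = ht.gene_set_score(expr * 2 + 7, list("abcd"))
        assert np.allclose(base, shifted)

    def test_disjoint_gene_set_raises(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["g1"])
        with pytest.raises(ValueError):
            ht.gene_set_score(expr, ["zz"])
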