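"""O/E transform, compartment calling, strength, Repress ratio, saddle,
insulation and topology operations on hand-constructed matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hubweaver import matrix as hm
from tests.conftest import symmetric_matrix, toy_loops


def block_matrix(n_per_block, hi, lo):
    """Two-block symmetric matrix: within-block hi, between-block lo."""
    n = 2 * n_per_block
    m = np.full((n, n), lo)
    m[:n_per_block, :n_per_block] = hi
    m[n_per_block:, n_per_block:] = hi
    return m


class TestObservedOverExpected:
    def test_constant_matrix_all_ones(self):
        cm = symmetric_matrix(np.full((6, 6), 7.0))
        oe = hm.observed_over_expected(cm)
        assert np.allclose(oe.matrix, 1.0)

    def test_diagonal_mean_arithmetic(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 2.0
        m[1, 2] = m[2, 1] = 4.0
        np.fill_diagonal(m, 5.0)
        oe = hm.observed_over_expected(symmetric_matrix(m))
        assert oe.matrix[0, 1] == pytest.approx(2 / 3)
        assert oe.matrix[1, 2] == pytest.approx(4 / 3)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = rng.poisson(5, (10, 10)).astype(float)
        m = (m + m.T) / 2
        oe1 = hm.observed_over_expected(symmetric_matrix(m))
        oe2 = hm.observed_over_expected(oe1)
        assert np.allclose(np.nan_to_num(oe1.matrix), np.nan_to_num(oe2.matrix))

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_every_diagonal_has_mean_one(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.poisson(4, (8, 8)).astype(float)
        m = m + m.T
        cm = symmetric_matrix(m)
        oe = hm.observed_over_expected(cm)
        assert np.allclose(np.nan_to_num(oe.matrix), np.nan_to_num(oe.matrix.T))
        for d in range(1, 8):
            vals = np.diagonal(oe.matrix, d)
            ok = np.isfinite(vals)
            valid = cm.mask[: 8 - d] & cm.mask[d:]
            if (ok & valid).any():
                assert np.nanmean(vals[ok & valid]) == pytest.approx(1.0)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            hm.observed_over_expected(symmetric_matrix(np.zeros((4, 4))))


class TestCompartments:
    def oe_two_block(self, n_per_block=10):
        return symmetric_matrix(block_matrix(n_per_block, 2.0, 0.5))

    def test_two_block_separation(self):
        oe = self.oe_two_block()
        signal = np.r_[np.full(10, 5.0), np.full(10, 0.5)]  # first block active
        prof = hm.call_compartments(oe, signal)
        assert (prof.labels[:10] == "A").all()
        assert (prof.labels[10:] == "B").all()

    def test_signal_flip_inverts_labels(self):
        oe = self.oe_two_block()
        signal = np.r_[np.full(10, 0.5), np.full(10, 5.0)]
        prof = hm.call_compartments(oe, signal)
        assert (prof.labels[:10] == "B").all()
        assert (prof.labels[10:] == "A").all()

    def test_scale_invariance(self):
        oe = self.oe_two_block()
        signal = np.r_[np.full(10, 5.0), np.full(10, 0.5)]
        p1 = hm.call_compartments(oe, signal)
        p2 = hm.call_compartments(
            symmetric_matrix(oe.matrix * 17.0), signal
        )
        assert (p1.labels == p2.labels).all()

    def test_too_few_bins_raises(self):
        with pytest.raises(ValueError):
            hm.call_compartments(symmetric_matrix(np.ones((3, 3))), np.ones(3))


class TestCompartmentStrength:
    def test_uniform_two_level_equals_four(self):
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        m = np.where(labels[:, None] == labels[None, :], 2.0, 0.5)
        s = hm.compartment_strength(symmetric_matrix(m), labels, exclusion_radius=0)
        assert np.allclose(s, 4.0)

    def test_label_blind_matrix_is_one(self):
        labels = np.array(["A", "B"] * 4)
        s = hm.compartment_strength(symmetric_matrix(np.ones((8, 8))), labels,
                                    exclusion_radius=0)
        assert np.allclose(s, 1.0)

    def test_no_opposite_partner_masked(self):
        labels = np.array(["A"] * 5)
        s = hm.compartment_strength(symmetric_matrix(np.ones((5, 5))), labels)
        assert np.isnan(s).all()


class TestRepressRatio:
    def build(self, on_val, off_val):
        # bins: 0 = focal B, 1 = B partner (varies), 2 = A partner (constant)
        on = np.ones((3, 3))
        off = np.ones((3, 3))
        on[0, 1] = on[1, 0] = on_val
        off[0, 1] = off[1, 0] = off_val
        labels = np.array(["B", "B", "A"])
        return symmetric_matrix(on), symmetric_matrix(off), labels

    def test_hand_computed_two_partner_case(self):
        on, off, labels = self.build(1.0, 3.0)
        score = hm.repress_ratio(on, off, labels, exclusion_radius=0)
        # term over B partners: log2(3+1) - log2(1+1) = 1; A partners unchanged
        assert score[0] == pytest.approx(1.0)

    def test_identity_is_zero(self):
        on, off, labels = self.build(2.0, 2.0)
        score = hm.repress_ratio(on, off, labels, exclusion_radius=0)
        assert np.allclose(score[~np.isnan(score)], 0.0)

    def test_condition_swap_negates(self):
        on, off, labels = self.build(1.0, 3.0)
        fwd = hm.repress_ratio(on, off, labels, exclusion_radius=0)
        rev = hm.repress_ratio(off, on, labels, exclusion_radius=0)
        ok = np.isfinite(fwd)
        assert np.allclose(fwd[ok], -rev[ok])

    def test_defined_only_for_b_bins(self):
        on, off, labels = self.build(1.0, 3.0)
        score = hm.repress_ratio(on, off, labels, exclusion_radius=0)
        assert np.isnan(score[2])  # A-labeled focal bin


class TestSaddle:
    def test_label_blind_matrix_flat(self):
        oe = symmetric_matrix(np.ones((20, 20)))
        e1 = np.linspace(-1, 1, 20)
        res = hm.saddle_statistics(oe, e1, n_quantiles=5, exclusion_radius=0)
        assert np.allclose(res.saddle[np.isfinite(res.saddle)], 1.0)

    def test_two_block_corners_equal_block_means(self):
        m = block_matrix(10, 2.0, 0.5)
        e1 = np.r_[np.full(10, -1.0), np.full(10, 1.0)]  # first block is B
        res = hm.saddle_statistics(symmetric_matrix(m), e1, n_quantiles=2,
                                   exclusion_radius=0)
        assert res.bb_corner == pytest.approx(2.0)
        assert res.aa_corner == pytest.approx(2.0)
        assert res.ab_corner == pytest.approx(0.5)

    def test_too_many_quantiles_raises(self):
        with pytest.raises(ValueError):
            hm.saddle_statistics(symmetric_matrix(np.ones((4, 4))), np.arange(4.0),
                                 n_quantiles=10)


class TestInsulation:
    def test_uniform_matrix_no_boundaries(self):
        seg = hm.insulation_profile(symmetric_matrix(np.ones((60, 60))), window_bins=6)
        assert len(seg.boundaries) == 0
        core = seg.insulation[np.isfinite(seg.insulation)]
        assert np.allclose(core, 0.0)

    def test_two_blocks_minimum_at_junction(self):
        m = block_matrix(20, 2.0, 0.5)
        seg = hm.insulation_profile(symmetric_matrix(m), window_bins=6)
        core = np.where(np.isfinite(seg.insulation), seg.insulation, np.inf)
        # the junction lies between bins 19 and 20; the square window makes
        # the minimum a two-bin plateau
        assert int(np.argmin(core)) in (19, 20)
        assert len(seg.boundaries) == 1
        assert abs(seg.boundaries[0] - 20) <= 1
        assert seg.strengths[0] > 0.1

    def test_short_chromosome_raises(self):
        with pytest.raises(ValueError):
            hm.insulation_profile(symmetric_matrix(np.ones((20, 20))), window_bins=12)


class TestInsulationConcordance:
    def make_seg(self, values):
        return hm.TadSegmentation(
            chrom="chr1", bin_size=40_000, insulation=np.asarray(values, float),
            boundaries=np.array([], dtype=int), strengths=np.array([]),
            window_bins=2,
        )

    def test_identity(self):
        v = np.sin(np.arange(50) / 3)
        assert hm.insulation_concordance(self.make_seg(v), self.make_seg(v)) == pytest.approx(1.0)

    def test_negation(self):
        v = np.sin(np.arange(50) / 3)
        assert hm.insulation_concordance(self.make_seg(v), self.make_seg(-v)) == pytest.approx(-1.0)

    def test_noise_attenuation(self):
        # r should approach var(signal) / (var(signal) + sigma^2)
        rng = np.random.default_rng(7)
        n = 20_000
        signal = rng.normal(0, 1, n)
        sigma = 0.5
        a = signal + rng.normal(0, sigma, n)
        b = signal + rng.normal(0, sigma, n)
        r = hm.insulation_concordance(self.make_seg(a), self.make_seg(b))
        assert r == pytest.approx(1 / (1 + sigma**2), abs=0.03)


class TestTopologyAndSwitches:
    def profile(self, labels, e1=None):
        labels = np.asarray(labels)
        if e1 is None:
            e1 = np.where(labels == "A", 0.5, -0.5)
        return hm.CompartmentProfile(
            chrom="chr1", bin_size=100, e1=np.asarray(e1, float), labels=labels,
            signal=np.zeros(len(labels)),
        )

    def seg(self, boundaries):
        return hm.TadSegmentation(
            chrom="chr1", bin_size=100, insulation=np.zeros(10),
            boundaries=np.asarray(boundaries, int), strengths=np.ones(len(boundaries)),
            window_bins=2,
        )

    def test_intra_everything(self):
        lp = toy_loops([("chr1", 0, 100, 200, 300, {})])
        out = hm.classify_loop_topology(lp, {"chr1": self.seg([8])},
                                        {"chr1": self.profile(["A"] * 10)})
        assert not out["inter_tad"].iloc[0]
        assert out["inter_compartment"].iloc[0] is False

    def test_crossing_loop(self):
        labels = ["A"] * 5 + ["B"] * 5
        lp = toy_loops([("chr1", 0, 100, 800, 900, {})])
        out = hm.classify_loop_topology(lp, {"chr1": self.seg([5])},
                                        {"chr1": self.profile(labels)})
        assert out["inter_tad"].iloc[0]
        assert out["inter_compartment"].iloc[0] is True

    def test_switch_table_identity_and_flip(self):
        labels = np.array(["A"] * 5 + ["B"] * 5)
        p = self.profile(labels)
        tf = np.zeros(10, bool)
        tf[:3] = True
        same = hm.compartment_switch_table(p, p, tf)
        assert (same["frac_switch"] == 0).all()
        flipped = self.profile(np.where(labels == "A", "B", "A"))
        both = hm.compartment_switch_table(p, flipped, tf)
        assert (both["frac_switch"] == 1.0).all()

    def test_switches_at_weak_bins(self):
        labels_on = np.array(["A"] * 5 + ["B"] * 5)
        labels_off = labels_on.copy()
        labels_off[4] = "B"  # the weakest A bin switches
        e1 = np.array([0.9, 0.8, 0.7, 0.6, 0.05, -0.6, -0.7, -0.8, -0.9, -1.0])
        p_on = self.profile(labels_on, e1)
        p_off = self.profile(labels_off, e1)
        table = hm.compartment_switch_table(p_on, p_off, np.zeros(10, bool))
        row = table.loc["tf_free"]
        assert row["mean_abs_e1_switching"] < row["mean_abs_e1_stable"]
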