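"""Contact-matrix analytics: O/E transform, A/B compartments, compartment
strength, Repress ratio, saddle summaries, insulation-score TADs.

A :class:`ContactMatrix` is a dense symmetric per-chromosome map of binned
contact counts (or O/E values) with a validity mask; bins with zero marginal
count are masked before any statistic is computed.

The compartment caller follows the standard eigenvector recipe: pairwise
correlation of the O/E matrix columns, leading eigenvector of that
correlation matrix, sign oriented so that positive values coincide with the
higher active-chromatin (H3K27ac) signal; A = positive, B = negative.

Compartment strength for a bin is the ratio of its mean same-compartment
O/E contacts to its mean cross-compartment O/E contacts. The Repress ratio
contrasts, for each B-compartment bin b, the knockdown-induced change in
log2(O/E + 1) toward B partners against the change toward A partners:

    R(b) = mean_m[log2(I_bm^off + 1) - log2(I_bm^on + 1)]
         - mean_n[log2(I_bn^off + 1) - log2(I_bn^on + 1)]

with m ranging over B-labeled partner bins and n over A-labeled ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as scipy_signal
from scipy import stats as scipy_stats


@dataclass
class ContactMatrix:
    """Symmetric binned contact map for one chromosome."""

    chrom: str
    bin_size: int
    matrix: np.ndarray  # (n, n) float; counts or O/E values; NaN = undefined
    start: int = 0
    mask: np.ndarray | None = None  # True = valid bin

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(np.nan_to_num(m), np.nan_to_num(m.T), rtol=1e-8, atol=1e-8):
            raise ValueError(f"{self.chrom}: contact matrix not symmetric")
        self.matrix = m
        if self.mask is None:
            with np.errstate(invalid="ignore"):
                marg = np.nansum(m, axis=0)
            self.mask = marg > 0
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of(self, position: int) -> int:
        return int((position - self.start) // self.bin_size)


@dataclass
class CompartmentProfile:
    """Per-bin leading eigenvector (E1) and A/B labels for one chromosome."""

    chrom: str
    bin_size: int
    e1: np.ndarray          # NaN where undefined
    labels: np.ndarray      # 'A', 'B', or '' (masked / E1 == 0)
    signal: np.ndarray      # binned active-chromatin signal used for the sign
    start: int = 0

    def bin_of(self, position: int) -> int:
        return int((position - self.start) // self.bin_size)


@dataclass
class TadSegmentation:
    """Insulation profile and boundary calls for one chromosome.

    ``boundaries`` are bin indices of insulation-score local minima whose
    prominence (the boundary strength) exceeds the calling threshold; a
    boundary at bin b separates the TAD ending at b-1 from the one starting
    at b (up to the one-bin ambiguity inherent to the square-window score).
    """

    chrom: str
    bin_size: int
    insulation: np.ndarray
    boundaries: np.ndarray
    strengths: np.ndarray
    window_bins: int
    start: int = 0


# ------------------------------------------------------------------- O / E

def observed_over_expected(cm: ContactMatrix) -> ContactMatrix:
    """Divide each entry by the mean of its distance stratum (diagonal).

    Means are taken over entries whose two bins are both unmasked; diagonals
    with zero mean become NaN. The result keeps symmetry and the mask, and
    every diagonal of the output has mean 1 over valid entries.
    """
    m = cm.matrix
    n = cm.n_bins
    valid = cm.mask
    if not valid.any() or np.nansum(np.abs(m)) == 0:
        raise ValueError(f"{cm.chrom}: all-zero or fully masked matrix")
    oe = np.full_like(m, np.nan, dtype=float)
    pair_ok = np.outer(valid, valid)
    for d in range(n):
        idx = np.arange(n - d)
        vals = m[idx, idx + d]
        ok = pair_ok[idx, idx + d] & np.isfinite(vals)
        if not ok.any():
            continue
        mean = vals[ok].mean()
        if mean == 0:
            continue
        oe[idx[ok], idx[ok] + d] = vals[ok] / mean
        oe[idx[ok] + d, idx[ok]] = vals[ok] / mean
    return ContactMatrix(cm.chrom, cm.bin_size, oe, start=cm.start, mask=cm.mask.copy())


# ------------------------------------------------------------ compartments

def call_compartments(
    oe: ContactMatrix,
    binned_signal: np.ndarray,
    degeneracy_tol: float = 1e-10,
) -> CompartmentProfile:
    """A/B compartments from the leading eigenvector of the O/E correlation.

    NaN O/E entries (empty distance strata) are replaced with the neutral
    value 1.0 before computing correlations. Raises if fewer than 4 bins are
    valid or if the two leading eigenvalues are tied within tolerance.
    """
    valid = oe.mask.copy()
    n = oe.n_bins
    if valid.sum() < 4:
        raise ValueError(f"{oe.chrom}: fewer than 4 unmasked bins")
    sub = oe.matrix[np.ix_(valid, valid)].copy()
    sub[~np.isfinite(sub)] = 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    w, v = np.linalg.eigh(corr)
    if (w[-1] - w[-2]) <= degeneracy_tol * max(abs(w[-1]), 1.0):
        raise ValueError(
            f"{oe.chrom}: degenerate leading eigenvalues "
            f"({w[-1]:.6g} vs {w[-2]:.6g}); compartments undetermined"
        )
    e1_valid = v[:, -1]

    sig = np.asarray(binned_signal, dtype=float)
    sig_valid = sig[valid]
    pos, neg = e1_valid > 0, e1_valid < 0
    if pos.any() and neg.any():
        if np.nanmean(sig_valid[pos]) < np.nanmean(sig_valid[neg]):
            e1_valid = -e1_valid
    elif np.nansum(sig_valid * e1_valid) < 0:  # one-sided fallback
        e1_valid = -e1_valid

    e1 = np.full(n, np.nan)
    e1[valid] = e1_valid
    labels = np.full(n, "", dtype="<U1")
    labels[valid & (e1 > 0)] = "A"
    labels[valid & (e1 < 0)] = "B"
    return CompartmentProfile(
        chrom=oe.chrom, bin_size=oe.bin_size, e1=e1, labels=labels,
        signal=sig, start=oe.start,
    )


def _label_masks(labels: np.ndarray):
    return labels == "A", labels == "B"


def _partner_means(oe_mat, row_ok, col_masks, exclusion_radius):
    """Row-wise nanmeans of ``oe_mat`` over each column mask, excluding the
    diagonal band |i-j| <= exclusion_radius."""
    n = oe_mat.shape[0]
    m = oe_mat.copy()
    for d in range(exclusion_radius + 1):
        idx = np.arange(n - d)
        m[idx, idx + d] = np.nan
        m[idx + d, idx] = np.nan
    out = []
    for cmask in col_masks:
        sub = m[:, cmask]
        with np.errstate(invalid="ignore"):
            counts = np.isfinite(sub).sum(axis=1)
            sums = np.nansum(sub, axis=1)
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        mean[~row_ok] = np.nan
        out.append(mean)
    return out


def compartment_strength(
    oe: ContactMatrix,
    labels: np.ndarray,
    exclusion_radius: int = 1,
) -> np.ndarray:
    """Per-bin same-compartment / cross-compartment mean O/E ratio.

    Bins without opposite-label partners (or masked) are NaN. The focal bin
    and its immediate neighbors are excluded from the partner sets
    (``exclusion_radius`` bins) so self-interaction does not dominate.
    """
    a_mask, b_mask = _label_masks(labels)
    labeled = a_mask | b_mask
    mean_a, mean_b = _partner_means(
        oe.matrix, labeled & oe.mask, (a_mask, b_mask), exclusion_radius
    )
    same = np.where(a_mask, mean_a, mean_b)
    other = np.where(a_mask, mean_b, mean_a)
    with np.errstate(invalid="ignore", divide="ignore"):
        strength = same / other
    strength[~labeled] = np.nan
    strength[~np.isfinite(strength)] = np.nan
    return strength


def repress_ratio(
    oe_on: ContactMatrix,
    oe_off: ContactMatrix,
    labels: np.ndarray,
    exclusion_radius: int = 1,
) -> np.ndarray:
    """Per-B-bin Repress ratio (log2 units); NaN for A-labeled/masked bins.

    Antisymmetric under swapping the two conditions and identically zero
    when they are equal. Labels are taken by the caller, conventionally from
    the TF-on (reference) profile.
    """
    if oe_on.matrix.shape != oe_off.matrix.shape:
        raise ValueError("condition matrices differ in shape")
    a_mask, b_mask = _label_masks(labels)
    with np.errstate(invalid="ignore"):
        delta = np.log2(oe_off.matrix + 1.0) - np.log2(oe_on.matrix + 1.0)
    row_ok = b_mask & oe_on.mask & oe_off.mask
    mean_b, mean_a = _partner_means(delta, row_ok, (b_mask, a_mask), exclusion_radius)
    score = mean_b - mean_a
    score[~row_ok] = np.nan
    return score


# ----------------------------------------------------------------- saddle

@dataclass
class SaddleResult:
    saddle: np.ndarray       # (q, q) mean O/E between E1-ranked groups
    bb_corner: float         # extreme low-E1 (top-left) corner mean
    aa_corner: float         # extreme high-E1 (bottom-right) corner mean
    ab_corner: float
    n_quantiles: int


def saddle_statistics(
    oe: ContactMatrix,
    e1: np.ndarray,
    n_quantiles: int = 10,
    corner_frac: float = 0.2,
    exclusion_radius: int = 1,
) -> SaddleResult:
    """Mean O/E between E1-ranked bin groups (rank ascending: B first)."""
    valid = oe.mask & np.isfinite(e1)
    idx = np.where(valid)[0]
    if n_quantiles > len(idx):
        raise ValueError("more quantiles than unmasked bins")
    order = idx[np.argsort(e1[idx], kind="stable")]
    groups = np.array_split(order, n_quantiles)
    m = oe.matrix.copy()
    n = m.shape[0]
    for d in range(exclusion_radius + 1):
        ii = np.arange(n - d)
        m[ii, ii + d] = np.nan
        m[ii + d, ii] = np.nan
    saddle = np.full((n_quantiles, n_quantiles), np.nan)
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            sub = m[np.ix_(gi, gj)]
            if np.isfinite(sub).any():
                saddle[i, j] = np.nanmean(sub)
    k = max(1, int(round(corner_frac * n_quantiles)))
    bb = np.nanmean(saddle[:k, :k])
    aa = np.nanmean(saddle[-k:, -k:])
    ab = np.nanmean(np.concatenate([saddle[:k, -k:].ravel(), saddle[-k:, :k].ravel()]))
    return SaddleResult(saddle=saddle, bb_corner=float(bb), aa_corner=float(aa),
                        ab_corner=float(ab), n_quantiles=n_quantiles)


def compartment_interaction_summary(
    oe: ContactMatrix, labels: np.ndarray, exclusion_radius: int = 1
) -> dict[str, float]:
    """Mean O/E over the A-A, A-B and B-B bin-pair strata."""
    a_mask, b_mask = _label_masks(labels)
    row_ok = (a_mask | b_mask) & oe.mask
    mean_a, mean_b = _partner_means(oe.matrix, row_ok, (a_mask, b_mask), exclusion_radius)
    out = {
        "AA": float(np.nanmean(mean_a[a_mask & row_ok])),
        "BB": float(np.nanmean(mean_b[b_mask & row_ok])),
        "AB": float(
            np.nanmean(np.concatenate([mean_b[a_mask & row_ok], mean_a[b_mask & row_ok]]))
        ),
    }
    return out


def interaction_change_test(
    oe_on: ContactMatrix,
    oe_off: ContactMatrix,
    labels: np.ndarray,
    labels_off: np.ndarray | None = None,
    exclusion_radius: int = 1,
) -> pd.DataFrame:
    """Per-stratum paired comparison of per-bin mean O/E between conditions.

    For each stratum (A-A, A-B, B-B) the pairing unit is a bin: its mean O/E
    to partners of the stratum's other label, computed in each condition.
    When both conditions' labels are given, strata are restricted to
    label-concordant bins (same compartment in both conditions), so
    compartment-switching bins do not dilute the comparison. Returns
    mean_on, mean_off, delta (off - on) and a Wilcoxon signed-rank p-value
    per stratum.
    """
    if labels_off is not None:
        concordant = np.asarray(labels) == np.asarray(labels_off)
        labels = np.where(concordant, labels, "")
    a_mask, b_mask = _label_masks(labels)
    rows = []
    for name, rmask, cmask in (
        ("AA", a_mask, a_mask), ("AB", a_mask, b_mask), ("BB", b_mask, b_mask),
    ):
        vals = []
        for oe in (oe_on, oe_off):
            (mean,) = _partner_means(oe.matrix, rmask & oe.mask, (cmask,), exclusion_radius)
            vals.append(mean)
        on, off = vals
        ok = np.isfinite(on) & np.isfinite(off)
        delta = off[ok] - on[ok]
        if len(delta) >= 3 and np.any(delta != 0):
            p = float(scipy_stats.wilcoxon(delta).pvalue)
        else:
            p = float("nan")
        rows.append(
            dict(stratum=name, n_bins=int(ok.sum()),
                 mean_on=float(np.mean(on[ok])) if ok.any() else float("nan"),
                 mean_off=float(np.mean(off[ok])) if ok.any() else float("nan"),
                 delta=float(np.mean(delta)) if ok.any() else float("nan"),
                 pvalue=p)
        )
    return pd.DataFrame(rows).set_index("stratum")


# -------------------------------------------------------------- insulation

def insulation_profile(
    oe: ContactMatrix,
    window_bins: int = 12,
    prominence: float = 0.1,
) -> TadSegmentation:
    """Insulation score and boundary calls from an O/E matrix.

    insulation(b) = log2( mean O/E of the window x window square touching
    the diagonal at b / chromosome-wide mean of such squares ). Boundaries
    are local minima whose prominence exceeds ``prominence`` (log2 units);
    the prominence is reported as the boundary strength.
    """
    n = oe.n_bins
    w = window_bins
    if n < 3 * w:
        raise ValueError(f"{oe.chrom}: chromosome shorter than 3 windows")
    raw = np.full(n, np.nan)
    m = oe.matrix
    for b in range(w, n - w):
        sq = m[b - w: b, b + 1: b + w + 1]
        if np.isfinite(sq).any():
            raw[b] = np.nanmean(sq)
    ok = np.isfinite(raw) & (raw > 0)
    if not ok.any():
        raise ValueError(f"{oe.chrom}: insulation undefined everywhere")
    norm = np.nanmean(raw[ok])
    ins = np.full(n, np.nan)
    ins[ok] = np.log2(raw[ok] / norm)

    # boundary detection on the defined core; interior NaNs neutralized to 0
    core = ins[w: n - w].copy()
    core[~np.isfinite(core)] = 0.0
    minima, props = scipy_signal.find_peaks(-core, prominence=prominence)
    boundaries = minima + w
    strengths = props["prominences"]
    return TadSegmentation(
        chrom=oe.chrom, bin_size=oe.bin_size, insulation=ins,
        boundaries=np.asarray(boundaries, dtype=int),
        strengths=np.asarray(strengths, dtype=float),
        window_bins=w, start=oe.start,
    )


def insulation_concordance(p1: TadSegmentation, p2: TadSegmentation) -> float:
    """Pearson correlation of two insulation profiles over shared bins."""
    if len(p1.insulation) != len(p2.insulation):
        raise ValueError("profiles are on different bin grids")
    ok = np.isfinite(p1.insulation) & np.isfinite(p2.insulation)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 jointly defined bins")
    r, _ = scipy_stats.pearsonr(p1.insulation[ok], p2.insulation[ok])
    return float(r)


# ----------------------------------------------- loop topology, A/B switches

def classify_loop_topology(
    loops: pd.DataFrame,
    tads: dict[str, TadSegmentation],
    profiles: dict[str, CompartmentProfile],
) -> pd.DataFrame:
    """Label each cis loop as TAD-crossing and/or compartment-crossing.

    A loop crosses a TAD iff a boundary bin start lies strictly between its
    two anchor midpoints; it crosses compartments iff its anchor bins carry
    different A/B labels. Loops with an anchor in a masked bin get NA for
    the compartment call.
    """
    inter_tad = np.zeros(len(loops), dtype=bool)
    inter_comp = np.full(len(loops), np.nan, dtype=object)
    mid1 = (loops["start1"].to_numpy() + loops["end1"].to_numpy()) // 2
    mid2 = (loops["start2"].to_numpy() + loops["end2"].to_numpy()) // 2
    for i, (chrom, m1, m2) in enumerate(zip(loops["chrom1"], mid1, mid2)):
        lo, hi = (m1, m2) if m1 <= m2 else (m2, m1)
        seg = tads.get(chrom)
        if seg is not None and len(seg.boundaries):
            bpos = seg.start + seg.boundaries * seg.bin_size
            inter_tad[i] = bool(np.any((bpos > lo) & (bpos < hi)))
        prof = profiles.get(chrom)
        if prof is not None:
            b1, b2 = prof.bin_of(m1), prof.bin_of(m2)
            if 0 <= b1 < len(prof.labels) and 0 <= b2 < len(prof.labels):
                l1, l2 = prof.labels[b1], prof.labels[b2]
                if l1 and l2:
                    inter_comp[i] = bool(l1 != l2)
    out = loops.copy()
    out["inter_tad"] = inter_tad
    out["inter_compartment"] = inter_comp
    return out


def crossing_summary(loops: pd.DataFrame, class_col: str = "anchor_pair_class") -> pd.DataFrame:
    """Percentage of TAD- and compartment-crossing loops per anchor class."""
    rows = []
    for cls, sub in loops.groupby(class_col):
        comp = sub["inter_compartment"].dropna()
        rows.append(
            dict(anchor_pair_class=cls, n_loops=len(sub),
                 pct_inter_tad=100.0 * sub["inter_tad"].mean() if len(sub) else float("nan"),
                 pct_inter_compartment=100.0 * comp.astype(bool).mean() if len(comp) else float("nan"))
        )
    return pd.DataFrame(rows).set_index("anchor_pair_class")


def compartment_switch_table(
    prof_on: CompartmentProfile,
    prof_off: CompartmentProfile,
    tf_bound_bins: np.ndarray,
) -> pd.DataFrame:
    """A/B switch fractions stratified by TF occupancy of the bin.

    Denominator per stratum: bins labeled in both conditions. Also reports
    the mean |E1| (TF-on) of switching vs stable bins, to expose whether
    switches concentrate at weakly scoring sites.
    """
    lab_on, lab_off = prof_on.labels, prof_off.labels
    both = (lab_on != "") & (lab_off != "")
    tf = np.asarray(tf_bound_bins, dtype=bool)
    rows = []
    for name, stratum in (("tf_bound", tf), ("tf_free", ~tf)):
        sel = both & stratum
        n = int(sel.sum())
        ab = int(((lab_on == "A") & (lab_off == "B") & sel).sum())
        ba = int(((lab_on == "B") & (lab_off == "A") & sel).sum())
        switching = sel & (lab_on != lab_off)
        stable = sel & (lab_on == lab_off)
        rows.append(
            dict(stratum=name, n_bins=n,
                 frac_a_to_b=ab / n if n else float("nan"),
                 frac_b_to_a=ba / n if n else float("nan"),
                 frac_switch=(ab + ba) / n if n else float("nan"),
                 mean_abs_e1_switching=float(np.nanmean(np.abs(prof_on.e1[switching])))
                 if switching.any() else float("nan"),
                 mean_abs_e1_stable=float(np.nanmean(np.abs(prof_on.e1[stable])))
                 if stable.any() else float("nan"))
        )
    return pd.DataFrame(rows).set_index("stratum")
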