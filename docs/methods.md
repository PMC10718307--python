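# Methods

## Scope and model

hubweaver implements the downstream statistics of a paired-condition
(TF-on / TF-off) 3D-genomics experiment. The central biological model is
that a sequence-specific transcription factor bound at a distinctive motif
class (here: GGAA microsatellite repeats, as opposed to single canonical
ETS sites) nucleates *enhancer hubs* — anchors with elevated loop degree,
contact intensity and span — and that depleting the factor (i) disassembles
those hubs, (ii) strengthens A/B compartment segregation, and (iii) permits
a new set of enhancers and loops to form, coupled to expression changes.
Every operation is a deterministic function of its inputs plus an explicit
seed where randomness is involved.

Coordinates are 0-based half-open throughout (BED convention); the
promoter window around a TSS is *closed* at both ends (±1 kb by default),
converted to half-open form internally. Overlap means ≥ 1 shared base
everywhere; no minimum-overlap fractions are used.

## Loop analysis

Reproducibility filter: a loop is kept iff it has nonzero count in both
replicates and count strictly greater than `min_count` (5) in at least one;
a strict mode requires the threshold in both replicates. The default
follows the more permissive of the two published phrasings of this rule;
both are implemented.

Normalization is a total-count size factor: factor_s = total_s / mean of
totals, normalized = raw / factor. This equalizes library totals and
preserves within-sample ranks. It deliberately does not model
distance-dependent or loop-specific dispersion; alternatives can be
plugged in by replacing `normalize_loop_counts`.

Fold changes use a shared pseudocount (0.5 on loop counts and track
signal, 0.1 on expression) added to both numerator and denominator; the
sources state thresholds but no zero-handling, so the pseudocounts are
package choices, config-exposed. Differential labels: gained/lost at fold
≥ 2 (configurable); novel loops: off > 4 × on with on < 2 normalized
counts; de novo peaks: off ≥ 4 × on with on < 5 relative units.

Loop span is midpoint-to-midpoint (edge-to-edge would differ by at most
one anchor width). The shuffled-anchor null replaces the left or right
anchor (probability ½ each) with a uniform draw from the same chromosome's
anchors, preserving cis-only topology; its Monte-Carlo mean converges to
the enumerable expectation (tested against full enumeration).

## Target-gene connectivity

A gene is TF-connected through any of: `tss_direct` (TF peak inside the
closed TSS window), `e_p` (loop joining a TF-bound anchor to a promoter
anchor), `e_b_p` (promoter loops to a distal *bridge* anchor that is
itself loop-connected to a TF-bound anchor, with the bridge→promoter loop
decreasing ≥ 2-fold after depletion). Bridges must be enhancer-class
(not overlapping any promoter peak); chains are limited to one bridge
level. `mixed` = two or more modes. The 2-fold decrease applies only to
the bridge→promoter loop, not to `e_p` loops. Target genes are connected
genes down ≥ 1.5-fold in at least one cellular context; novel-loop targets
are genes whose promoter anchor joins a novel loop and rise > 1.5-fold.
Gene-set scores are per-sample means of per-gene z-scores (sample SD,
ddof = 1); genes with zero variance contribute 0.

## Contact-matrix analytics

O/E divides each entry by its diagonal (distance-stratum) mean over
unmasked bins; bins with zero marginal count are masked first. Compartments
come from the leading eigenvector of the pairwise correlation matrix of
O/E columns (per chromosome, not per arm — the toy genome has no
centromeres), sign-oriented so positive-E1 bins carry the higher mean
H3K27ac; A = positive, B = negative; a tied leading eigenpair raises a
diagnostic error. NaN O/E entries are set to the neutral value 1.0 before
correlation.

Compartment strength and the Repress ratio exclude the focal bin and its
immediate neighbors (|Δbin| ≤ 1, configurable) from partner sets to avoid
self-interaction dominance. Repress-ratio labels come from the TF-on
(reference) profile. The A-A/A-B/B-B change test pairs per-bin stratum
means across conditions and, when both conditions' labels are supplied,
restricts strata to label-concordant bins so switching bins do not dilute
the comparison; significance is a Wilcoxon signed-rank over the paired
per-bin values.

Insulation(b) = log2(mean O/E of the `window × window` square touching the
diagonal at b ÷ chromosome mean of such squares); window 12 bins (480 kb
at 40 kb), matching common insulation-tool defaults. Boundaries are local
minima with prominence > 0.1 log2 units (the prominence is the reported
boundary strength). Because the square excludes the focal row/column, a
sharp domain junction produces a two-bin minimum plateau; boundary
positions are therefore compared within ±1 bin.

Saddle matrices rank unmasked bins by E1 ascending (most-B first) into 10
groups; corners average the extreme 20 % of groups, so B-B sits top-left
and A-A bottom-right.

## Synthetic data generator

The generator emulates the *structure* of the study data, not its
sequence-level detail. Per chromosome (default 2 × 40 Mb at 40-kb bins):
TADs partition the bins (25 per chromosome, Dirichlet-distributed sizes,
minimum 10 bins); A/B blocks are unions of consecutive TADs of ≈ 25 bins,
so compartment edges coincide with TAD boundaries as in real genomes.
Features (genes, TF peaks, distal and de novo H3K27ac peaks) sit on a
jittered 6-kb lattice, guaranteeing non-overlap; a twentieth of TF peaks
are planted inside gene TSS windows (the `tss_direct` truth set) and
`repeat_fraction` (0.3) are repeat-class, each with a repeat-annotation
interval.

Loops: every anchor initiates Poisson(base_degree = 2) partners (hub
anchors: × hub_degree_boost = 5), with target spans Exponential(70 kb;
hubs: 1 Mb) resolved to the nearest anchor. Counts are negative-binomial
(var = μ + 0.2 μ²) around a mean of 12 (hubs × hub_count_boost = 3) with a
mild span decay; replicates share the mean with independent noise, which
is what the reproducibility filter exploits. The hub boosts were set from
the target per-anchor statistics (median degree ~10 vs ~2-3; median
summed counts ~175 vs ~30): note the intensity contrast is per-anchor, so
it factors into degree × per-loop count. TF-off removes
`knockdown_loss_fraction` (0.8) of hub loops, weakens planted
bridge→promoter loops 6-fold, and activates planted novel loops
(on-mean 0.15, off-mean ~12) anchored at de novo peaks. Planted
regulatory chains (e_p, e_b_p) use strong span-independent means and
nearest-neighbor hub/bridge placement so that planted effects exceed the
detection thresholds by construction rather than by luck.

Signals: non-de-novo peaks have TF-on signal ≥ 5 relative units
(5 + lognormal); de novo peaks draw on ∈ (0.3, 1.5) and
off = (on + 0.5)·U(5, 8) − 0.5, so the 4-fold/baseline-5 rule recovers
exactly the planted set. Tracks are piecewise-constant: the planted signal
inside each peak footprint (peak width equals the 2-kb quantification
window, so window means return the planted values exactly) and an
A-vs-B background (≈1.0 vs ≈0.2) elsewhere, which drives the eigenvector
sign rule.

Contact maps: expected count = depth · d^(−1) (depth 200 per adjacent-bin
pair — per-bin marginals ≈ 3,000 contacts, conservative for 40-kb-binned
maps but deep enough that per-bin strength estimates resolve the planted
contrast), times a compartment factor 1 ± s·(1 − mixing) (s = 0.6;
mixing_on = 0.5, mixing_off = 0.2, so segregation strengthens after
depletion), times (1 + 0.8) within TADs; Poisson counts, symmetric.
A `switch_fraction` (5 %) of bins — whole TADs — flip compartment in the
TF-off condition with locally damped segregation, so planted switches are
weak-|E1| sites. Expression is lognormal FPKM-like with planted ±1 log2
shifts for target / novel-target genes (high baselines, so the 1.5-fold
gates are meaningful) and −0.5 log2 for a set of B-compartment bystander
genes.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: sequencing-level biases (GC, mappability,
restriction-fragment structure), trans contacts, distance-dependent count
dispersion, peak-calling uncertainty, correlated replicate artifacts, and
genuinely continuous compartment scores. Recovery rates on fixtures are
upper bounds for real-data performance.

## Numerical choices and degenerate inputs

Seeds: every random stage derives its generator from (seed, stage-index),
so staged and full runs agree and all outputs are byte-stable (floats are
serialized at %.6g). All-zero matrices, < 4 unmasked bins, chromosomes
shorter than 3 insulation windows, zero-total samples and gene sets
disjoint from the expression matrix raise errors rather than degrade.
Bins with no opposite-label partner get NaN strength; B bins without both
partner classes get NaN Repress ratio. Ties between promoter and distal
resolve to promoter.

## Limitations

Modules are connected components, not community detection; in dense loop
sets short-range loops percolate, so global component medians can move
against the hub signal — hub fractionation is read from components that
contain repeat-class anchors. The diffloop-style size factor is the
total-count variant; no per-loop statistical test is attached to
differential calls (fold thresholds only, as in the analysis recipe this
package follows). Compartment calling is per chromosome and two-state;
sub-compartments and arm-level eigenvectors are out of scope.
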