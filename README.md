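# hubweaver

Analysis toolkit for asking how a single transcription factor shapes 3D
chromatin organization, modeled on TF-depletion experiments in tumor cells:
two conditions (control `shGFP`, TF-depleted `shFLI1`), H3K27ac-anchored
chromatin loops (HiChIP-style BEDPE tables with replicate counts), binned
contact matrices (HiC-style), ChIP peaks and signal tracks, and expression
tables. It is written for computational genomicists who have such paired
datasets — or who want a controlled synthetic stand-in with planted ground
truth — and need the downstream statistics, not the read processing.

## What it computes

**Loops** (`hubweaver.loops`): reproducibility filtering (a loop is kept if
present in both replicates with count > 5 in at least one), total-count
size-factor normalization, six-way anchor-pair classification by TF motif
class (GGAA-repeat / single-GGAA / unbound), per-anchor degree and contact
intensity, loop-span statistics with a shuffled-anchor null, differential
(gained/lost at |fold| ≥ 2) and novel-loop calling (off > 4 × on with
on < 2 normalized counts).

**Compartments and TADs** (`hubweaver.matrix`): O/E transform
(per-diagonal expected), A/B calling from the leading eigenvector of the
O/E correlation matrix with the sign oriented by H3K27ac signal,
per-bin compartment strength

        strength(b) = mean same-compartment O/E / mean cross-compartment O/E,

the per-B-bin **Repress ratio**

        R(b) = mean_m[ log2(I_bm^off + 1) − log2(I_bm^on + 1) ]
             − mean_n[ log2(I_bn^off + 1) − log2(I_bn^on + 1) ],

(m over B partners, n over A partners, I = O/E contacts), saddle matrices,
A-A/A-B/B-B change tests (Wilcoxon signed-rank), insulation-score TAD
boundaries, loop TAD/compartment-crossing rates and A/B switch tables.

**Targets** (`hubweaver.targets`): the four TF-to-promoter connectivity
modes — direct TSS binding (±1 kb), enhancer→promoter loops,
enhancer→bridge→promoter chains (bridge loop must weaken ≥ 2-fold after
depletion), and mixed — with 1.5-fold expression gates for target and
novel-loop-target selection, plus z-score gene-set scoring.

**Networks** (`hubweaver.network`): anchor-loop graphs, connected-component
modules and their fractionation between conditions.

**Synthetic data** (`hubweaver.simulate`): a paired-condition generator
that plants hub anchors, de novo peaks, novel loops, per-mode target genes,
A/B blocks, TADs and expression coupling, and records everything in a
ground-truth manifest so each detector can be scored.

## Worked example

```sh
hubweaver simulate --out fixture --seed 1
hubweaver all --input-dir fixture --out run
hubweaver validate --report run/report.json --truth fixture/truth.json
```

prints (seed 1):

```
wrote fixture with 3167 loops to fixture
report -> run/report.json
loops retained: {'shGFP': 2934, 'shFLI1': 2550}; targets: 37; insulation corr: 0.983
de_novo_peaks: recall=1.000 precision=1.000
novel_loops: recall=0.984 precision=0.851
novel_loop_targets: recall=0.975 precision=1.000
A/B agreement (shFLI1): 1.000
A/B agreement (shGFP): 1.000
```

Reading: of the 3,167 simulated loops, 2,934 survive the reproducibility
filter in the control; all 40 planted de novo peaks and 63/64 planted novel
loops are recalled; compartment labels agree with the planted A/B blocks at
99.5 %/100 % of bins. `run/report.json` carries the full summaries —
e.g. repeat-anchored hubs show median degree 10 vs 3 at unbound anchors,
and compartment strength rises from 1.80 to 2.61 after TF loss.

The same operations run on real data given the standard text formats
(narrowPeak, bedGraph, BEDPE, sparse-triplet matrix + bin table, TSV);
see `hubweaver all --help` and `RunConfig` for the thresholds.

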