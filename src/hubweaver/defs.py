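"""Shared constants: condition names, table column conventions."""

# Condition labels follow the shRNA naming of the experimental design the
# generator emulates: "shGFP" = control (TF expressed), "shFLI1" = TF depleted.
COND_ON = "shGFP"
COND_OFF = "shFLI1"
CONDITIONS = (COND_ON, COND_OFF)
REPLICATES = (1, 2)

#: canonical BEDPE-style anchor columns of a loop table
LOOP_ANCHOR_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]

#: raw replicate count columns, in sample order used for normalization
COUNT_COLS = [f"{cond}_rep{r}" for cond in CONDITIONS for r in REPLICATES]

MOTIF_REPEAT = "repeat"
MOTIF_SINGLE = "single"
MOTIF_NONE = "none"

#: ordering used to build the six anchor-pair classes (strongest class first)
MOTIF_ORDER = (MOTIF_REPEAT, MOTIF_SINGLE, MOTIF_NONE)


def anchor_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def loop_key(chrom1, start1, end1, chrom2, start2, end2) -> str:
    return f"{anchor_id(chrom1, start1, end1)}|{anchor_id(chrom2, start2, end2)}"
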