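"""Published summary counts from the mouse prefrontal-cortex ethanol-withdrawal
study whose downstream analysis this package implements.

These are *inputs*: printed per-support-level region counts and direction
tallies that the arithmetic layers (`summarize_overlap_fractions`,
`summarize_directions`, `summarize_annotation`, `percent`) can be checked
against.  The genome-scale counts themselves derive from deposited raw
sequencing data and are not recomputed here.
"""

from __future__ import annotations

#: H3K27me3 consensus regions of each condition, tallied by how many
#: replicates of the other condition overlap them (index = support 0..4).
CONTROL_SUPPORT_COUNTS = [131, 939, 1769, 3972, 23072]   # total 29,883
ETHANOL_SUPPORT_COUNTS = [640, 3268, 4570, 5755, 21477]  # total 35,710

#: condition-exclusive H3K27me3 peaks (support 0 above)
K27_EXCLUSIVE_ETHANOL = 640
K27_EXCLUSIVE_CONTROL = 131

#: gene-associated differential H3K4me3 peaks by direction
K4_PEAKS_INCREASE = 112
K4_PEAKS_DECREASE = 196

#: H3K4me3 differential peaks by genomic region of association
K4_TSS_PEAKS = 33
K4_PROMOTER_PEAKS = 59

#: genes with differential H3K27me3 peaks, and the treatment-only subset
K27_GENES_TOTAL = 245
K27_GENES_TREATMENT_ONLY = 209
#: of those genes, previously reported as ethanol-regulated
K27_GENES_IN_LITERATURE = 98

#: expression-table spot checks: (gene, log fold-change, unadjusted p)
EXPRESSION_SPOT_CHECKS = [
    ("Ezr", 0.208, 0.0003),
    ("Pard3", -0.302, 0.0084),
]

#: genes with concurrent H3K4me3 loss and treatment-only H3K27me3 gain
DUAL_MARK_GENES = ["Trp63", "Wnt5a", "Lhfpl3"]
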