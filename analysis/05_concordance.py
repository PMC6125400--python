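#!/usr/bin/env python
"""Integrate the two marks with differential expression into the concordance
matrix: gene-level H3K4me3 status x H3K27me3 status x expression direction.

A treatment-only peak of the active mark predicts expression up; a
treatment-only domain of the repressive mark predicts expression down.
Writes the three cross-tabulations, the concordant-gene report and the
conflicts list under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd
from common import K4, K27, P_CUT, RESULTS, SIM_DIR, require

from markconcord.concordance import (
    assemble_gene_status,
    build_concordance_matrix,
    collapse_gene_status,
    find_concordant_genes,
    select_de_genes,
)
from markconcord.differential import (
    DifferentialPeak,
    GAIN_IN_CONTROL,
    GAIN_IN_TREATMENT,
    INCREASE,
    DECREASE,
)
from markconcord.io_formats import read_expression_table


def gene_directions(mark: str, translate: dict | None) -> tuple[dict, list]:
    diff = pd.read_csv(RESULTS / f"diff_{mark}.tsv", sep="\t")
    annot = pd.read_csv(RESULTS / f"annot_{mark}.tsv", sep="\t")
    genic = annot[annot["region_class"] != "intergenic"]
    directions = {
        (r.chrom, r.start, r.end): r.direction for r in diff.itertuples(index=False)
    }
    peaks_by_gene: dict[str, list[DifferentialPeak]] = {}
    for r in genic.itertuples(index=False):
        d = DifferentialPeak(
            r.chrom, r.start, r.end, mark=mark,
            direction=directions[(r.chrom, r.start, r.end)],
        )
        peaks_by_gene.setdefault(r.gene_id, []).append(d)
    status, conflicts = collapse_gene_status(peaks_by_gene)
    if translate:
        status = {g: translate[s] for g, s in status.items()}
    return status, conflicts


def main() -> None:
    require(RESULTS / f"annot_{K4}.tsv", "04_annotate_peaks.py")
    k4, conf4 = gene_directions(
        K4, {GAIN_IN_TREATMENT: INCREASE, GAIN_IN_CONTROL: DECREASE}
    )
    k27, conf27 = gene_directions(K27, None)
    expr = read_expression_table(SIM_DIR / "expression.tsv")
    de = select_de_genes(expr, p_cut=P_CUT)
    matrix = build_concordance_matrix(k4, k27, de, conflicts=[*conf4, *conf27])
    matrix.k4_by_k27.to_csv(RESULTS / "matrix_k4_by_k27.tsv", sep="\t")
    matrix.k4_by_expr.to_csv(RESULTS / "matrix_k4_by_expr.tsv", sep="\t")
    matrix.k27_by_expr.to_csv(RESULTS / "matrix_k27_by_expr.tsv", sep="\t")
    verdicts = find_concordant_genes(assemble_gene_status(k4, k27, de))
    verdicts.to_csv(RESULTS / "concordant_genes.tsv", sep="\t", index=False)
    (RESULTS / "conflicts.tsv").write_text("".join(f"{g}\n" for g in matrix.conflicts))
    n_conc = int(verdicts["concordant"].sum()) if len(verdicts) else 0
    print(f"gene statuses: {len(k4)} with {K4} changes, {len(k27)} with {K27} "
          f"changes, {len(de)} differentially expressed at p<{P_CUT}")
    print(f"dual-mark genes: {len(matrix.dual_mark_genes)}; "
          f"conflicted genes excluded: {len(matrix.conflicts)}")
    print(f"concordance: {n_conc}/{len(verdicts)} testable genes match the "
          f"direction predicted from their marks")


if __name__ == "__main__":
    main()
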