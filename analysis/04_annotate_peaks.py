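#!/usr/bin/env python
"""Associate the differential peaks with genes and classify each association.

Each peak is linked to every gene whose TSS neighbourhood (±100 bp),
proximal promoter (2 kb upstream to 200 bp into the gene, strand-aware) or
gene body it overlaps; peaks touching none are assigned to the nearest gene
as intergenic.  Writes results/annot_<mark>.tsv and a class summary.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import json

import pandas as pd
from common import K4, K27, RESULTS, SIM_DIR, require

from markconcord.annotation import (
    associate_peaks_to_genes,
    association_table,
    summarize_annotation,
)
from markconcord.io_formats import read_gene_models
from markconcord.synthetic import TruthTable


def main() -> None:
    genes = read_gene_models(require(SIM_DIR / "genes.tsv", "01_simulate_experiment.py"))
    summaries = {}
    for mark in (K4, K27):
        diff = pd.read_csv(
            require(RESULTS / f"diff_{mark}.tsv", "03_differential_peaks.py"), sep="\t"
        )
        peaks = [(r.chrom, int(r.start), int(r.end)) for r in diff.itertuples(index=False)]
        assocs = associate_peaks_to_genes(peaks, genes)
        association_table(assocs).to_csv(
            RESULTS / f"annot_{mark}.tsv", sep="\t", index=False
        )
        summary = summarize_annotation(assocs)
        summaries[mark] = summary
        truth = TruthTable.from_tsv(SIM_DIR / f"truth_{mark}.tsv")
        planted_promoter = len(truth.linked)
        print(
            f"{mark}: {summary['n_associations']} associations for {len(peaks)} "
            f"differential peaks; {summary['tss_proximal']} TSS-proximal "
            f"({summary['tss']} TSS + {summary['promoter']} promoter; "
            f"{planted_promoter} planted in promoters), "
            f"{summary['gene_body']} gene-body, {summary['intergenic']} intergenic; "
            f"{summary['n_multi_gene_peaks']} peaks hit >1 gene"
        )
    (RESULTS / "annotation_summary.json").write_text(
        json.dumps(summaries, indent=2, sort_keys=True) + "\n"
    )


if __name__ == "__main__":
    main()
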