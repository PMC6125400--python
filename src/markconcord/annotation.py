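"""Peak-to-gene association and genomic region classification.

Each (peak, gene) pair is classified into exactly one region class with the
precedence tss > promoter > gene_body > intergenic:

* ``tss``       — some peak base lies within 100 bp of the TSS base;
* ``promoter``  — the peak overlaps the strand-aware proximal-promoter window
                  (2,000 bp upstream of the TSS through 200 bp into the gene);
* ``gene_body`` — the peak overlaps the gene interval;
* ``intergenic``— none of the above.

A peak is associated with every gene whose tss/promoter/gene-body window it
touches (nearest first, up to ``max_multi``); a peak touching no window is
assigned to its single nearest gene as intergenic.  Distances are signed in
gene orientation: negative upstream of the TSS, positive downstream, 0 when
the peak covers the TSS base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneModel

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int]

TSS = "tss"
PROMOTER = "promoter"
GENE_BODY = "gene_body"
INTERGENIC = "intergenic"

REGION_CLASSES = (TSS, PROMOTER, GENE_BODY, INTERGENIC)

#: default windows (bp)
TSS_WINDOW = 100
PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 200


@dataclass(frozen=True)
class PeakGeneAssociation:
    chrom: str
    start: int
    end: int
    gene_id: str
    region_class: str
    distance_bp: int  # signed TSS distance in gene orientation

    @property
    def interval(self) -> Interval:
        return (self.chrom, self.start, self.end)


def signed_tss_distance(peak: Interval, gene: GeneModel) -> int:
    """Signed distance (bp) from the nearest peak base to the TSS base.

    0 when the peak covers the TSS base; otherwise the gap to the nearest
    peak base, negative when the peak lies upstream of the TSS in the gene's
    orientation and positive downstream.
    """
    chrom, start, end = peak
    if chrom != gene.chrom:
        raise ValueError(
            f"peak chromosome {chrom} differs from gene {gene.gene_id} "
            f"chromosome {gene.chrom}"
        )
    t = gene.tss
    if start <= t < end:
        return 0
    if end <= t:  # peak entirely left of TSS on the genome
        genomic = end - 1 - t  # negative
    else:  # start > t
        genomic = start - t  # positive
    return genomic if gene.strand == "+" else -genomic


def classify_region(
    peak: Interval,
    gene: GeneModel,
    tss_window: int = TSS_WINDOW,
    promoter_upstream: int = PROMOTER_UPSTREAM,
    promoter_downstream: int = PROMOTER_DOWNSTREAM,
) -> str:
    """Region class of a (peak, gene) pair under the tss > promoter >
    gene_body > intergenic precedence.  Raises on a chromosome mismatch."""
    chrom, start, end = peak
    if chrom != gene.chrom:
        raise ValueError(
            f"cannot classify across chromosomes ({chrom} vs {gene.chrom})"
        )
    if abs(signed_tss_distance(peak, gene)) <= tss_window:
        return TSS
    ps, pe = gene.promoter_window(promoter_upstream, promoter_downstream)
    if min(end, pe) - max(start, ps) >= 1:
        return PROMOTER
    if min(end, gene.end) - max(start, gene.start) >= 1:
        return GENE_BODY
    return INTERGENIC


def _association_window(
    gene: GeneModel, tss_window: int, promoter_upstream: int, promoter_downstream: int
) -> tuple[int, int]:
    """Maximal genomic extent within which a peak can classify non-intergenic."""
    ps, pe = gene.promoter_window(promoter_upstream, promoter_downstream)
    lo = min(gene.start, ps, gene.tss - tss_window)
    hi = max(gene.end, pe, gene.tss + tss_window + 1)
    return lo, hi


def associate_peaks_to_genes(
    peaks: Iterable[Interval],
    genes: Sequence[GeneModel],
    max_multi: int = 3,
    tss_window: int = TSS_WINDOW,
    promoter_upstream: int = PROMOTER_UPSTREAM,
    promoter_downstream: int = PROMOTER_DOWNSTREAM,
) -> list[PeakGeneAssociation]:
    """Associate every peak with its overlapping gene windows, else nearest gene.

    For each peak, the genes whose tss/promoter/gene-body windows it touches
    are reported (nearest TSS first, at most ``max_multi``).  A peak touching
    no window is reported once, as intergenic, for the nearest gene on its
    chromosome (ties broken by smaller gene start, then gene_id).  Peaks on a
    chromosome with no annotated gene are skipped with a warning.
    """
    if not genes:
        raise ValueError("empty gene annotation")
    by_chrom: dict[str, list[GeneModel]] = {}
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
        lo, hi = _association_window(g, tss_window, promoter_upstream, promoter_downstream)
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g)

    def sort_key(peak: Interval, g: GeneModel) -> tuple[int, int, str]:
        return (abs(signed_tss_distance(peak, g)), g.start, g.gene_id)

    out: list[PeakGeneAssociation] = []
    for peak in peaks:
        chrom, start, end = peak
        if chrom not in by_chrom:
            logger.warning("no genes on chromosome %s; peak %s skipped", chrom, peak)
            continue
        candidates = [iv.data for iv in trees[chrom].overlap(start, end)]
        hits = []
        for g in candidates:
            cls = classify_region(
                peak, g, tss_window, promoter_upstream, promoter_downstream
            )
            if cls != INTERGENIC:
                hits.append(g)
        if hits:
            hits.sort(key=lambda g: sort_key(peak, g))
            for g in hits[:max_multi]:
                out.append(
                    PeakGeneAssociation(
                        chrom, start, end, g.gene_id,
                        classify_region(
                            peak, g, tss_window, promoter_upstream, promoter_downstream
                        ),
                        signed_tss_distance(peak, g),
                    )
                )
        else:
            nearest = min(by_chrom[chrom], key=lambda g: sort_key(peak, g))
            out.append(
                PeakGeneAssociation(
                    chrom, start, end, nearest.gene_id, INTERGENIC,
                    signed_tss_distance(peak, nearest),
                )
            )
    return out


def summarize_annotation(assocs: Sequence[PeakGeneAssociation]) -> dict[str, int]:
    """Counts per region class, TSS-proximal total (tss + promoter), and
    multi-gene-peak / multi-peak-gene tallies."""
    class_counts = {cls: 0 for cls in REGION_CLASSES}
    peak_genes: dict[Interval, set[str]] = {}
    gene_peaks: dict[str, set[Interval]] = {}
    for a in assocs:
        class_counts[a.region_class] += 1
        peak_genes.setdefault(a.interval, set()).add(a.gene_id)
        gene_peaks.setdefault(a.gene_id, set()).add(a.interval)
    return {
        **class_counts,
        "tss_proximal": class_counts[TSS] + class_counts[PROMOTER],
        "n_associations": len(assocs),
        "n_multi_gene_peaks": sum(1 for gs in peak_genes.values() if len(gs) > 1),
        "n_multi_peak_genes": sum(1 for ps in gene_peaks.values() if len(ps) > 1),
    }


def association_table(assocs: Sequence[PeakGeneAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.chrom, a.start, a.end, a.gene_id, a.region_class, a.distance_bp)
            for a in assocs
        ],
        columns=["chrom", "start", "end", "gene_id", "region_class", "distance_bp"],
    )
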