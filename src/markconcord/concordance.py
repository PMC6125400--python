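"""Integration of the two histone marks with differential expression.

Gene-level statuses: a gene's H3K4me3 status is {none, increase, decrease}
(count-based calls), its H3K27me3 status is {none, gain_treatment,
gain_control} (exclusive occupancy calls), and its expression status is
{none, up, down} (p-value filter on the expression table).  The biological
reading direction: H3K4me3 marks active promoters, so more H3K4me3 predicts
more transcription; H3K27me3 is repressive, so a treatment-only H3K27me3
domain predicts less transcription.  ``predict_direction`` encodes exactly
that, and ``find_concordant_genes`` compares prediction with observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .differential import (
    DECREASE,
    GAIN_IN_CONTROL,
    GAIN_IN_TREATMENT,
    INCREASE,
    DifferentialPeak,
)
from .io_formats import ExpressionRecord

logger = logging.getLogger(__name__)

NONE = "none"
UP = "up"
DOWN = "down"
AMBIGUOUS = "ambiguous"

K4_STATUSES = (NONE, INCREASE, DECREASE)
K27_STATUSES = (NONE, GAIN_IN_TREATMENT, GAIN_IN_CONTROL)
EXPR_STATUSES = (NONE, UP, DOWN)

#: expression direction implied by each single-mark change
_K4_PREDICTION = {NONE: NONE, INCREASE: UP, DECREASE: DOWN}
_K27_PREDICTION = {NONE: NONE, GAIN_IN_TREATMENT: DOWN, GAIN_IN_CONTROL: UP}


@dataclass(frozen=True)
class GeneMarkStatus:
    gene_id: str
    k4: str = NONE
    k27: str = NONE
    expr: str = NONE

    @property
    def predicted_expr(self) -> str:
        return predict_direction(self.k4, self.k27)

    @property
    def concordant(self) -> bool | None:
        """True/False when testable (expression observed and an unambiguous
        prediction exists), else None."""
        pred = self.predicted_expr
        if self.expr == NONE or pred not in (UP, DOWN):
            return None
        return self.expr == pred


def select_de_genes(
    expression: Sequence[ExpressionRecord], p_cut: float = 0.01
) -> dict[str, str]:
    """Differentially expressed genes at unadjusted p < ``p_cut``; direction
    from the sign of log_fc.  Genes with log_fc exactly 0 below the cut are
    direction-less and excluded with a warning."""
    out: dict[str, str] = {}
    for rec in expression:
        if rec.p_value >= p_cut:
            continue
        if rec.log_fc == 0:
            logger.warning(
                "gene %s significant (p=%g) but log_fc=0; excluded", rec.gene_id, rec.p_value
            )
            continue
        out[rec.gene_id] = UP if rec.log_fc > 0 else DOWN
    return out


def predict_direction(k4: str, k27: str) -> str:
    """Expression direction predicted from the two mark statuses.

    Single-mark changes predict their own direction; two marks agreeing give
    that direction; two marks disagreeing give ``ambiguous``; no change in
    either mark gives ``none``.
    """
    if k4 not in _K4_PREDICTION:
        raise ValueError(f"unknown H3K4me3 status {k4!r}")
    if k27 not in _K27_PREDICTION:
        raise ValueError(f"unknown H3K27me3 status {k27!r}")
    p4, p27 = _K4_PREDICTION[k4], _K27_PREDICTION[k27]
    if p4 == NONE:
        return p27
    if p27 == NONE:
        return p4
    return p4 if p4 == p27 else AMBIGUOUS


def collapse_gene_status(
    peaks_by_gene: Mapping[str, Sequence[DifferentialPeak]],
) -> tuple[dict[str, str], list[str]]:
    """Collapse per-gene differential peaks of one mark to one gene status.

    Multiple peaks with the same direction collapse to that direction; a gene
    with conflicting directions for the one mark goes to the conflicts list
    and receives no status.
    """
    status: dict[str, str] = {}
    conflicts: list[str] = []
    for gene, peaks in peaks_by_gene.items():
        directions = {p.direction for p in peaks}
        if len(directions) == 1:
            status[gene] = directions.pop()
        elif directions:
            conflicts.append(gene)
            logger.warning("gene %s has conflicting mark directions %s", gene, directions)
    return status, sorted(conflicts)


def assemble_gene_status(
    k4_genes: Mapping[str, str],
    k27_genes: Mapping[str, str],
    de_genes: Mapping[str, str],
) -> list[GeneMarkStatus]:
    """One GeneMarkStatus per gene appearing in any of the three input maps."""
    all_genes = sorted(set(k4_genes) | set(k27_genes) | set(de_genes))
    return [
        GeneMarkStatus(
            g,
            k4=k4_genes.get(g, NONE),
            k27=k27_genes.get(g, NONE),
            expr=de_genes.get(g, NONE),
        )
        for g in all_genes
    ]


@dataclass
class ConcordanceMatrix:
    """Gene-level contingency tables linking the two marks and expression.

    ``k4_by_k27``, ``k4_by_expr`` and ``k27_by_expr`` are pandas crosstabs
    over the full status alphabets (zero-filled), counting every gene with at
    least one non-``none`` status.  ``dual_mark_genes`` lists genes changed in
    both marks; ``conflicts`` lists genes dropped for mixed same-mark
    directions upstream.
    """

    k4_by_k27: pd.DataFrame
    k4_by_expr: pd.DataFrame
    k27_by_expr: pd.DataFrame
    dual_mark_genes: list[str] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)

    def marginal(self, axis: str) -> pd.Series:
        """Gene counts per status for one axis ('k4', 'k27' or 'expr')."""
        if axis == "k4":
            return self.k4_by_k27.sum(axis=1)
        if axis == "k27":
            return self.k4_by_k27.sum(axis=0)
        if axis == "expr":
            return self.k4_by_expr.sum(axis=0)
        raise ValueError(f"unknown axis {axis!r}")


def build_concordance_matrix(
    k4_genes: Mapping[str, str],
    k27_genes: Mapping[str, str],
    de_genes: Mapping[str, str],
    conflicts: Sequence[str] = (),
) -> ConcordanceMatrix:
    """Cross-tabulate gene-level H3K4me3, H3K27me3 and expression statuses.

    Inputs are gene -> status maps (see module constants for alphabets);
    genes named in ``conflicts`` are excluded.  Every cell is a plain set
    intersection count and is recomputable by filtering the status table.
    """
    for g, s in k4_genes.items():
        if s not in (INCREASE, DECREASE):
            raise ValueError(f"bad H3K4me3 status {s!r} for {g}")
    for g, s in k27_genes.items():
        if s not in (GAIN_IN_TREATMENT, GAIN_IN_CONTROL):
            raise ValueError(f"bad H3K27me3 status {s!r} for {g}")
    drop = set(conflicts)
    statuses = [
        s
        for s in assemble_gene_status(k4_genes, k27_genes, de_genes)
        if s.gene_id not in drop
    ]
    df = pd.DataFrame(
        [(s.gene_id, s.k4, s.k27, s.expr) for s in statuses],
        columns=["gene_id", "k4", "k27", "expr"],
    )

    def crosstab(rows: str, cols: str, row_order, col_order) -> pd.DataFrame:
        if df.empty:
            tab = pd.DataFrame(0, index=list(row_order), columns=list(col_order))
        else:
            tab = pd.crosstab(df[rows], df[cols])
            tab = tab.reindex(index=list(row_order), columns=list(col_order), fill_value=0)
        tab.index.name, tab.columns.name = rows, cols
        return tab

    dual = sorted(
        s.gene_id for s in statuses if s.k4 != NONE and s.k27 != NONE
    )
    return ConcordanceMatrix(
        k4_by_k27=crosstab("k4", "k27", K4_STATUSES, K27_STATUSES),
        k4_by_expr=crosstab("k4", "expr", K4_STATUSES, EXPR_STATUSES),
        k27_by_expr=crosstab("k27", "expr", K27_STATUSES, EXPR_STATUSES),
        dual_mark_genes=dual,
        conflicts=sorted(drop),
    )


def find_concordant_genes(
    statuses: Sequence[GeneMarkStatus],
) -> pd.DataFrame:
    """Genes whose concordance is testable (observed expression and an
    unambiguous prediction), with the verdict per gene."""
    rows = [
        {
            "gene_id": s.gene_id,
            "k4": s.k4,
            "k27": s.k27,
            "expr": s.expr,
            "predicted_expr": s.predicted_expr,
            "concordant": s.concordant,
        }
        for s in statuses
        if s.concordant is not None
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "k4", "k27", "expr", "predicted_expr", "concordant"],
    )
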