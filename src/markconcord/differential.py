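"""Differential peak calling.

Two routes, matching the two kinds of histone mark:

* ``call_exclusive_peaks`` — the stringent replicate-consistency rule for
  broad marks (H3K27me3): a region is differential only if it is a consensus
  region of one condition (peak in every replicate) and is overlapped by peaks
  from at most ``max_other`` (default 0) replicates of the other condition.

* ``score_differential_binding`` — a deliberately simple count-based test for
  narrow marks: per-region two-sample t-test on log2 counts-per-million with
  Benjamini–Hochberg correction.  This is transparent plumbing, not a
  negative-binomial differential-binding model, and is labelled as such.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import ConsensusRegion, support_histogram
from .io_formats import Peak
from .utils import round_half_up

#: direction labels for exclusive (occupancy) calls
GAIN_IN_TREATMENT = "gain_in_treatment"
GAIN_IN_CONTROL = "gain_in_control"
#: direction labels for count-based calls
INCREASE = "increase"
DECREASE = "decrease"

_UP_DIRECTIONS = {GAIN_IN_TREATMENT, INCREASE}
_DOWN_DIRECTIONS = {GAIN_IN_CONTROL, DECREASE}

_REGION_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass
class DifferentialPeak:
    """One differential region with its direction and supporting evidence.

    Exclusive calls carry replicate support counts; count-test calls carry
    (effect, p, fdr).  ``gene_associated`` is filled during annotation.
    """

    chrom: str
    start: int
    end: int
    mark: str = ""
    direction: str = ""
    support_own: int | None = None
    support_other: int | None = None
    effect: float | None = None
    p: float | None = None
    fdr: float | None = None
    gene_associated: bool | None = None

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def call_exclusive_peaks(
    consensus_own: Sequence[ConsensusRegion],
    replicates_other: Mapping[str, Sequence[Peak]],
    direction: str = GAIN_IN_TREATMENT,
    mark: str = "",
    max_other: int = 0,
    min_bp: int = 1,
) -> list[DifferentialPeak]:
    """Condition-exclusive differential peaks from one condition's consensus.

    Returns the consensus regions overlapped by peaks from at most
    ``max_other`` other-condition replicates.  With the default
    ``max_other=0`` this is the strict rule: present in all replicates of one
    condition and in none of the other.  Call once per direction, swapping
    roles, to obtain both gain-in-treatment and gain-in-control peaks.
    """
    if direction not in (GAIN_IN_TREATMENT, GAIN_IN_CONTROL):
        raise ValueError(f"unknown exclusive direction {direction!r}")
    support_histogram(consensus_own, replicates_other, min_bp=min_bp)
    return [
        DifferentialPeak(
            r.chrom,
            r.start,
            r.end,
            mark=mark,
            direction=direction,
            support_own=r.n_replicates,
            support_other=r.other_support,
        )
        for r in consensus_own
        if r.other_support is not None and r.other_support <= max_other
    ]


def score_differential_binding(
    counts: pd.DataFrame,
    design: Mapping[str, str],
    treatment: str = "treatment",
    control: str = "control",
    fdr_cut: float = 0.1,
    mark: str = "",
) -> list[DifferentialPeak]:
    """Simple count-based differential test over a region x sample matrix.

    Counts are library-size normalised to counts-per-million; the effect per
    region is mean log2(CPM + 0.5) in treatment minus control; p-values come
    from a two-sided two-sample t-test on log2 CPM, adjusted across regions by
    Benjamini–Hochberg.  Regions with FDR <= ``fdr_cut`` are returned, labelled
    increase/decrease by effect sign.

    Region ids of the form ``chrom:start-end`` are parsed into coordinates;
    other ids are kept as placeholder coordinates [0, 1) with the id retained
    via the DataFrame index order.
    """
    treat_cols = [s for s in counts.columns if design.get(s) == treatment]
    ctrl_cols = [s for s in counts.columns if design.get(s) == control]
    if len(treat_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError(
            f"need >=2 samples per condition, got {len(treat_cols)} {treatment} "
            f"and {len(ctrl_cols)} {control}"
        )
    if len(counts) < 2:
        raise ValueError("need >=2 regions for FDR correction")
    mat = counts[treat_cols + ctrl_cols].to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    libsize = mat.sum(axis=0)
    if (libsize == 0).any():
        zero = [c for c, t in zip(treat_cols + ctrl_cols, libsize) if t == 0]
        raise ValueError(f"sample(s) with zero total counts: {zero}")

    log_cpm = np.log2(mat / libsize * 1e6 + 0.5)
    t_block = log_cpm[:, : len(treat_cols)]
    c_block = log_cpm[:, len(treat_cols):]
    effect = t_block.mean(axis=1) - c_block.mean(axis=1)
    res = stats.ttest_ind(t_block, c_block, axis=1)
    pvals = np.nan_to_num(res.pvalue, nan=1.0)  # zero-variance ties -> no call
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")

    out: list[DifferentialPeak] = []
    for rid, eff, p, q in zip(counts.index, effect, pvals, fdr):
        if q > fdr_cut:
            continue
        m = _REGION_ID_RE.match(str(rid))
        chrom, start, end = (
            (m["chrom"], int(m["start"]), int(m["end"])) if m else (str(rid), 0, 1)
        )
        out.append(
            DifferentialPeak(
                chrom,
                start,
                end,
                mark=mark,
                direction=INCREASE if eff > 0 else DECREASE,
                effect=float(eff),
                p=float(p),
                fdr=float(q),
            )
        )
    return out


def summarize_directions(
    diff_table: Sequence[DifferentialPeak], gene_associated_only: bool = False
) -> tuple[int, int, int]:
    """Tally direction labels: (n_increase, n_decrease, pct_decrease).

    Gains in treatment and count-test increases count as "increase"; gains in
    control and count-test decreases count as "decrease".  ``pct_decrease`` is
    rounded half-up to the nearest integer.  With ``gene_associated_only`` the
    tally is restricted to peaks flagged as gene-associated.
    """
    peaks = [
        d
        for d in diff_table
        if not gene_associated_only or d.gene_associated
    ]
    n_inc = sum(1 for d in peaks if d.direction in _UP_DIRECTIONS)
    n_dec = sum(1 for d in peaks if d.direction in _DOWN_DIRECTIONS)
    if n_inc + n_dec == 0:
        raise ValueError("no direction-labelled peaks to summarize")
    pct_dec = int(round_half_up(100.0 * n_dec / (n_inc + n_dec)))
    return n_inc, n_dec, pct_dec


def differential_table(diffs: Sequence[DifferentialPeak]) -> pd.DataFrame:
    """Flat TSV-ready table of differential peaks."""
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "mark": d.mark,
                "direction": d.direction,
                "support_own": d.support_own,
                "support_other": d.support_other,
                "effect": d.effect,
                "p": d.p,
                "fdr": d.fdr,
            }
            for d in diffs
        ],
        columns=[
            "chrom", "start", "end", "mark", "direction",
            "support_own", "support_other", "effect", "p", "fdr",
        ],
    )
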