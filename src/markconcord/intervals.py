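"""Interval algebra: overlap, merging, replicate consensus, support histograms.

The central object is the *consensus region* of one condition: pooled peaks
from all replicates are merged into candidate regions and a candidate is kept
only if every replicate contributes at least one overlapping peak.  Against
the other condition, each consensus region is scored by its *support* — the
number of other-condition replicates with at least one overlapping peak —
yielding the 0..n support histogram that drives the condition-exclusive
differential criterion (support 0 under the default threshold).

All arithmetic is 0-based half-open; two intervals overlap when they share at
least ``min_bp`` bases, so abutting intervals ([0,10) and [10,20)) do not
overlap and are never merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .io_formats import Peak
from .utils import round_half_up

Interval = tuple[str, int, int]  # (chrom, start, end), half-open


def overlaps(a: Interval, b: Interval, min_bp: int = 1) -> bool:
    """True iff ``a`` and ``b`` are on the same chromosome and share >= min_bp bases."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if a[0] != b[0]:
        return False
    return min(a[2], b[2]) - max(a[1], b[1]) >= min_bp


def merge_intervals(peaks: Iterable[Peak | Interval]) -> list[Interval]:
    """Merge overlapping intervals into a disjoint, sorted list.

    Base coverage is preserved exactly: adjacent-but-not-overlapping intervals
    (zero shared bases) are kept separate.
    """
    ivals = sorted(
        p.interval if isinstance(p, Peak) else (p[0], p[1], p[2]) for p in peaks
    )
    merged: list[Interval] = []
    for chrom, start, end in ivals:
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            last = merged[-1]
            if end > last[2]:
                merged[-1] = (chrom, last[1], end)
        else:
            merged.append((chrom, start, end))
    return merged


@dataclass
class ConsensusRegion:
    """A merged interval supported by >=1 peak in every replicate of its condition."""

    chrom: str
    start: int
    end: int
    condition: str = ""
    contributing: dict[str, list[Peak]] = field(default_factory=dict)
    other_support: int | None = None

    @property
    def interval(self) -> Interval:
        return (self.chrom, self.start, self.end)

    @property
    def n_replicates(self) -> int:
        return len(self.contributing)


@dataclass
class SupportHistogram:
    """Counts of consensus regions by other-condition replicate support (0..n)."""

    condition: str
    counts: list[int]
    total: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("support counts must be non-negative")
        if sum(self.counts) != self.total:
            raise ValueError(
                f"support counts sum to {sum(self.counts)}, expected total {self.total}"
            )

    @property
    def n_other(self) -> int:
        return len(self.counts) - 1


def _replicate_trees(replicates: Mapping[str, Sequence[Peak]]) -> dict[str, dict[str, IntervalTree]]:
    """Per replicate, per chromosome interval trees for O(log n) overlap queries."""
    trees: dict[str, dict[str, IntervalTree]] = {}
    for rep, peaks in replicates.items():
        by_chrom: dict[str, IntervalTree] = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
        trees[rep] = by_chrom
    return trees


def _query(
    trees: dict[str, IntervalTree], region: Interval, min_bp: int
) -> list[Peak]:
    chrom, start, end = region
    tree = trees.get(chrom)
    if tree is None:
        return []
    hits = [
        iv.data
        for iv in tree.overlap(start, end)
        if min(iv.end, end) - max(iv.begin, start) >= min_bp
    ]
    hits.sort(key=lambda p: (p.start, p.end))
    return hits


def build_consensus(
    replicates: Mapping[str, Sequence[Peak]],
    condition: str = "",
    min_bp: int = 1,
) -> list[ConsensusRegion]:
    """Build consensus regions supported by every replicate of one condition.

    Pools all replicates' peaks, merges them into candidate regions, and keeps
    each candidate for which every replicate has >=1 peak overlapping it by
    >= ``min_bp`` bases.  Symmetric in replicate order and deterministic.
    """
    if not replicates:
        raise ValueError("build_consensus requires at least one replicate")
    pooled = [p for peaks in replicates.values() for p in peaks]
    candidates = merge_intervals(pooled)
    trees = _replicate_trees(replicates)

    out: list[ConsensusRegion] = []
    for cand in candidates:
        contributing: dict[str, list[Peak]] = {}
        for rep in replicates:
            hits = _query(trees[rep], cand, min_bp)
            if not hits:
                break
            contributing[rep] = hits
        else:
            out.append(
                ConsensusRegion(cand[0], cand[1], cand[2], condition, contributing)
            )
    return out


def support_histogram(
    consensus: Sequence[ConsensusRegion],
    replicates_other: Mapping[str, Sequence[Peak]],
    min_bp: int = 1,
) -> SupportHistogram:
    """Score each consensus region by its other-condition replicate support.

    Sets ``other_support`` on every region in place and returns the histogram
    ``counts[k]`` = number of regions overlapped by peaks from exactly ``k``
    of the other condition's replicates.
    """
    trees = _replicate_trees(replicates_other)
    n_other = len(replicates_other)
    counts = [0] * (n_other + 1)
    condition = consensus[0].condition if consensus else ""
    for region in consensus:
        support = sum(
            1 for rep in replicates_other if _query(trees[rep], region.interval, min_bp)
        )
        region.other_support = support
        counts[support] += 1
    return SupportHistogram(condition=condition, counts=counts, total=len(consensus))


def summarize_overlap_fractions(hist: SupportHistogram, ndigits: int = 2) -> list[float]:
    """Per-support-level percentages of the histogram, rounded half-up.

    ``percent[k] = 100 * counts[k] / total`` with half-up rounding to
    ``ndigits`` decimals (the convention of the printed report tables).
    """
    if hist.total == 0:
        raise ValueError("cannot compute fractions of an empty histogram")
    return [round_half_up(100.0 * c / hist.total, ndigits) for c in hist.counts]
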